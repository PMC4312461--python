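"""Built-in seed-and-extend read mapper and pileup genotype caller.

The mapper emulates the contract of a BWA-aln-style pipeline: exact k-mer
seeds (several per read, both strands) propose candidate loci; each
candidate is scored by banded edit-distance alignment of the whole read
against the local reference window (edlib); the unique best locus is kept
if its edit distance is within ``ceil(max_mismatch_frac * read_len)``, and
reads whose best score is tied between distinct loci are discarded
(multi-mapper policy). Called indels are left-aligned to a canonical
placement.

The caller computes diploid genotype likelihoods per pileup column over
{ref-hom, het, alt-hom} from per-base error rates, with weak non-reference
priors, emitting a call when a non-reference genotype maximises the
posterior; indels are called from consistent inserted/deleted observations
with the same machinery on support counts. Call quality is the Phred-scaled
posterior against the reference-homozygote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .read_sim import ReadRecord
from .seq import encode, left_align_indel, revcomp

__all__ = [
    "ReferenceIndex",
    "MappedRead",
    "CalledVariant",
    "build_index",
    "map_read",
    "map_pool",
    "pileup_and_call",
    "filter_calls",
    "write_sam",
    "write_calls_vcf",
]


@dataclass
class ReferenceIndex:
    """Exact k-mer -> sorted position index over the reference."""

    reference: str
    k: int
    positions: dict

    def lookup(self, kmer: str) -> list[int]:
        return self.positions.get(kmer, [])


def build_index(reference: str, k: int = 13) -> ReferenceIndex:
    if k < 4:
        raise ValueError("k must be >= 4")
    positions: dict[str, list[int]] = {}
    valid = set("ACGT")
    for i in range(len(reference) - k + 1):
        kmer = reference[i : i + k]
        if set(kmer) <= valid:
            positions.setdefault(kmer, []).append(i)
    return ReferenceIndex(reference, k, positions)


@dataclass(slots=True)
class MappedRead:
    """A read placed on the reference.

    ``aln_seq`` is the read sequence in reference-forward orientation;
    ``cigar`` is a list of (op, length) with ops M/I/D consuming the read
    and/or reference in the SAM sense. ``match_ref_pos``/``match_codes``
    cache the reference coordinate and read base code of every M column;
    ``indels`` holds left-aligned observations ``(ref_pos, kind, seq)``.
    """

    read: ReadRecord
    ref_start: int
    strand: str
    cigar: list
    edit_distance: int
    mapping_quality: int
    aln_seq: str
    match_ref_pos: np.ndarray = None
    match_codes: np.ndarray = None
    indels: list = field(default_factory=list)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.cigar if op in "MD")


def _parse_ext_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse edlib's extended cigar, merging =/X runs into M."""
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=X" else ch
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + int(num))
            else:
                ops.append((op, int(num)))
            num = ""
    return ops


def _seed_offsets(read_len: int, k: int) -> list[int]:
    # 7 evenly spaced seeds: on a 40 bp read no two edits can break all of
    # them, keeping the seeded search near-exhaustive within the edit budget
    span = read_len - k
    if span <= 0:
        return [0]
    return sorted({round(i * span / 6) for i in range(7)})


#: Extra cost charged per gap run on top of its length, emulating the
#: BWA-class scoring where opening a gap is much more expensive than a
#: mismatch; a 1 bp indel then consumes 2 units of the mismatch budget.
GAP_OPEN_EXTRA = 1

#: Longest gap run a mapped read may carry. The BWA-aln family defaults to
#: k-difference search without gap extensions, so reads spanning longer
#: indels fail to map rather than align with a multi-bp gap; raise this to
#: let the banded aligner (band 6) represent indels up to 5 bp.
MAX_GAP_LEN = 1


def _weighted_score(ext_cigar: str) -> int:
    """Mismatches + gap lengths + per-gap opening surcharge."""
    score = 0
    num = ""
    for ch in ext_cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "X":
                score += int(num)
            elif ch in "ID":
                score += int(num) + GAP_OPEN_EXTRA
            num = ""
    return score


def map_read(
    read: ReadRecord,
    index: ReferenceIndex,
    max_mismatch_frac: float = 0.05,
    band: int = 6,
    max_gap_len: int = MAX_GAP_LEN,
) -> MappedRead | None:
    """Map one read; returns None when unmapped (no locus or ambiguous)."""
    seq = read.sequence
    n = len(seq)
    if n == 0:
        raise ValueError("empty read")
    if n < index.k:
        return None
    ref = index.reference
    L = len(ref)
    max_edits = math.ceil(max_mismatch_frac * n)

    candidates: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for off in _seed_offsets(n, index.k):
            for pos in index.lookup(oriented[off : off + index.k]):
                cand = pos - off
                key = (strand, cand // (band + 1))
                if key in seen or (strand, cand // (band + 1) + 1) in seen:
                    continue
                seen.add(key)
                candidates.append((strand, cand))
    if not candidates:
        return None

    best = None  # (dist, strand, window_start, loc_pos)
    second_dist = None
    for strand, cand in candidates:
        ws = max(0, cand - band)
        we = min(L, cand + n + band)
        oriented = seq if strand == "+" else revcomp(seq)
        res = edlib.align(oriented, ref[ws:we], mode="HW", task="locations")
        dist = res["editDistance"]
        loc = ws + res["locations"][0][0]
        if best is None:
            best = (dist, strand, ws, we, loc)
        elif dist < best[0]:
            second_dist = best[0]
            best = (dist, strand, ws, we, loc)
        elif abs(loc - best[4]) > band:
            second_dist = dist if second_dist is None else min(second_dist, dist)

    dist, strand, ws, we, _ = best
    if dist > max_edits:
        return None
    if second_dist is not None and second_dist == dist:
        return None  # tied best at distinct loci: multi-mapper, discarded
    mapq = 60 if second_dist is None else max(0, min(60, 10 * (second_dist - dist)))

    oriented = seq if strand == "+" else revcomp(seq)
    res = edlib.align(oriented, ref[ws:we], mode="HW", task="path")
    w_path = _weighted_score(res["cigar"])
    # Prefer an ungapped placement whenever it is no more expensive than the
    # gapped path: with gap opening far above a mismatch, a BWA-class scorer
    # renders e.g. adjacent substitutions as 2 mismatches, never as an I/D
    # pair. Scan every diagonal of the window for the best Hamming score.
    h_best, h_off = _best_hamming(oriented, ref[ws:we])
    if h_best is not None and h_best <= w_path:
        if h_best > max_edits:
            return None
        m = MappedRead(
            read, ws + h_off, strand, [("M", n)], int(h_best), mapq, oriented
        )
    else:
        if w_path > max_edits:
            return None  # over budget once gap surcharges are applied
        loc_start, _ = res["locations"][0]
        cigar = _parse_ext_cigar(res["cigar"])
        if any(l > max_gap_len for op, l in cigar if op in "ID"):
            return None  # gap longer than the aligner's gap policy allows
        m = MappedRead(
            read, ws + loc_start, strand, cigar, res["editDistance"], mapq, oriented
        )
    _fill_alignment_caches(m, ref)
    return m


def _best_hamming(read: str, window: str) -> tuple[int | None, int | None]:
    """Best ungapped mismatch count of ``read`` over every window diagonal."""
    n = len(read)
    if len(window) < n:
        return None, None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    best, best_off = None, None
    for off in range(len(window) - n + 1):
        d = int(np.count_nonzero(w[off : off + n] != r))
        if best is None or d < best:
            best, best_off = d, off
    return best, best_off


def _fill_alignment_caches(m: MappedRead, ref: str) -> None:
    ref_pos_runs: list[np.ndarray] = []
    code_runs: list[np.ndarray] = []
    codes = encode(m.aln_seq)
    n = len(m.aln_seq)
    rp, qp = m.ref_start, 0
    for op, length in m.cigar:
        if op == "M":
            ref_pos_runs.append(np.arange(rp, rp + length))
            code_runs.append(codes[qp : qp + length])
            rp += length
            qp += length
        elif op == "I":
            # terminal indels are alignment-ambiguous artifacts; a BWA-like
            # scorer (gap open >> mismatch) would not report them
            if _END_EXCLUDE <= qp <= n - length - _END_EXCLUDE:
                pos, seq = left_align_indel(ref, rp, m.aln_seq[qp : qp + length], "insertion")
                m.indels.append((pos, "insertion", seq))
            qp += length
        elif op == "D":
            if _END_EXCLUDE <= qp <= n - _END_EXCLUDE:
                pos, seq = left_align_indel(ref, rp, ref[rp : rp + length], "deletion")
                m.indels.append((pos, "deletion", seq))
            rp += length
    m.match_ref_pos = (
        np.concatenate(ref_pos_runs) if ref_pos_runs else np.empty(0, dtype=int)
    )
    m.match_codes = (
        np.concatenate(code_runs) if code_runs else np.empty(0, dtype=np.uint8)
    )


def map_pool(
    reads: list[ReadRecord],
    index: ReferenceIndex,
    max_mismatch_frac: float = 0.05,
    band: int = 6,
    max_gap_len: int = MAX_GAP_LEN,
) -> list[MappedRead]:
    out = []
    for r in reads:
        m = map_read(r, index, max_mismatch_frac, band, max_gap_len)
        if m is not None:
            out.append(m)
    return out


@dataclass(slots=True)
class CalledVariant:
    """A diploid variant call in 0-based reference coordinates."""

    ref_pos: int
    kind: str  # snp | insertion | deletion
    ref_allele: str
    alt_allele: str
    genotype: str  # het | hom
    call_quality: float
    depth: int

    def __post_init__(self) -> None:
        if self.call_quality < 0 or self.depth < 1:
            raise ValueError("invalid call")


_LOG10_MAX_QUAL = 3000.0
_SPAN_MARGIN = 5  # aligned bases required each side for an indel opportunity
_END_EXCLUDE = 5  # indel observations this close to a read end are ignored
#: Error-dependency coefficient: the i-th base contradicting a genotype is
#: discounted by DEPENDENCY**i, reflecting that apparent errors recur at the
#: same site (terminal deamination stacks identical mismatches at read
#: ends); the MAQ-family caller device, set low enough that a damage pileup
#: needs substantial support before outvoting the reference.
DEPENDENCY = 0.7


def _dep_sum(k):
    """Sum_{i<k} DEPENDENCY**i, the effective count of k correlated errors."""
    return (1.0 - DEPENDENCY**k) / (1.0 - DEPENDENCY)


def _posterior_call(l_rr: float, l_ra: float, l_aa: float, log_priors) -> tuple[str, float]:
    """Best genotype and Phred posterior against ref-hom (log10 inputs)."""
    post = np.array([l_rr, l_ra, l_aa]) + log_priors
    norm = post.max()
    p = 10 ** (post - norm)
    p /= p.sum()
    g = int(np.argmax(post))
    qual = min(_LOG10_MAX_QUAL, -10 * math.log10(max(p[0], 1e-300)))
    return ("RR", "RA", "AA")[g], qual


def pileup_and_call(
    mapped: list[MappedRead],
    reference: str,
    error_floor: int = 40,
    phred: int | None = None,
    het_prior: float = 1e-3,
    hom_prior: float = 5e-4,
    indel_error: float = 1e-4,
) -> list[CalledVariant]:
    """Pileup the mapped reads and call diploid SNPs and indels.

    Per-base error comes from the pool's (constant) Phred quality, capped at
    ``error_floor``; ``phred`` overrides it. Reads must be position-sortable;
    the pileup itself is order-free, but an unsorted SAM emission downstream
    would be invalid, so sorting happens here.
    """
    mapped = sorted(mapped, key=lambda m: m.ref_start)
    L = len(reference)
    ref_codes = encode(reference)
    if mapped:
        all_pos = np.concatenate([m.match_ref_pos for m in mapped])
        all_codes = np.concatenate([m.match_codes for m in mapped]).astype(np.int64)
        flat = np.bincount(all_pos * 4 + all_codes, minlength=4 * L)
        counts = flat.reshape(L, 4).astype(np.int64)
    else:
        counts = np.zeros((L, 4), dtype=np.int64)
    depth = counts.sum(axis=1)

    if phred is None:
        quals = [int(m.read.quality[0]) for m in mapped[:100]] or [35]
        phred = int(np.median(quals))
    eps = 10 ** (-min(phred, error_floor) / 10)
    log_priors = np.log10([1.0 - het_prior - hom_prior, het_prior, hom_prior])
    l_match = math.log10(1 - eps)
    l_mis = math.log10(eps / 3)
    l_het = math.log10(0.5 * (1 - eps) + 0.5 * eps / 3)

    calls: list[CalledVariant] = []
    n_ref_all = counts[np.arange(L), ref_codes]
    cand = np.nonzero(depth - n_ref_all > 0)[0]
    if cand.size:
        alt_counts = counts[cand].copy()
        alt_counts[np.arange(cand.size), ref_codes[cand]] = -1
        alt_code = alt_counts.argmax(axis=1)
        d = depth[cand].astype(float)
        na = counts[cand, alt_code].astype(float)
        nr = n_ref_all[cand].astype(float)
        no = d - na - nr
        l_rr = nr * l_match + _dep_sum(na + no) * l_mis
        l_aa = na * l_match + _dep_sum(nr + no) * l_mis
        l_ra = (nr + na) * l_het + _dep_sum(no) * l_mis
        post = np.stack([l_rr, l_ra, l_aa], axis=1) + log_priors
        post -= post.max(axis=1, keepdims=True)
        p = 10**post
        p_rr = p[:, 0] / p.sum(axis=1)
        geno = post.argmax(axis=1)
        qual = np.minimum(_LOG10_MAX_QUAL, -10 * np.log10(np.maximum(p_rr, 1e-300)))
        for idx in np.nonzero(geno > 0)[0]:
            pos = int(cand[idx])
            calls.append(
                CalledVariant(
                    pos,
                    "snp",
                    reference[pos],
                    "ACGT"[int(alt_code[idx])],
                    "het" if geno[idx] == 1 else "hom",
                    float(qual[idx]),
                    int(depth[pos]),
                )
            )

    # --- indels from left-aligned observations. The opportunity count for a
    # site is the number of reads spanning it with enough aligned context
    # (>= _SPAN_MARGIN bases on both sides) that the aligner could have
    # represented the indel; edge reads are not informative either way.
    obs: dict[tuple[int, str], dict[str, int]] = {}
    for m in mapped:
        for pos, kind, seq in m.indels:
            obs.setdefault((pos, kind), {}).setdefault(seq, 0)
            obs[(pos, kind)][seq] += 1
    span = np.zeros(L + 1, dtype=np.int64)
    for m in mapped:
        lo, hi = m.ref_start + _SPAN_MARGIN, m.ref_end - _SPAN_MARGIN
        if hi > lo:
            span[lo] += 1
            span[hi] -= 1
    span = np.cumsum(span)[:L]
    l_ierr = math.log10(indel_error)
    l_iok = math.log10(1 - indel_error)
    for (pos, kind), alleles in sorted(obs.items()):
        seq, m_count = max(alleles.items(), key=lambda kv: kv[1])
        d = int(span[pos]) if pos < L else 0
        d = max(d, m_count)
        l_rr = _dep_sum(m_count) * l_ierr + (d - m_count) * l_iok
        l_aa = _dep_sum(d - m_count) * l_ierr + m_count * l_iok
        l_ra = d * math.log10(0.5)
        g, qual = _posterior_call(l_rr, l_ra, l_aa, log_priors)
        if g == "RR":
            continue
        ref_allele = seq if kind == "deletion" else ""
        alt_allele = "" if kind == "deletion" else seq
        calls.append(
            CalledVariant(
                pos, kind, ref_allele, alt_allele, "het" if g == "RA" else "hom", qual, d
            )
        )
    calls.sort(key=lambda c: (c.ref_pos, c.kind))
    return calls


def filter_calls(
    calls: list[CalledVariant],
    min_depth: int = 1,
    max_depth: int = 30,
    min_qual: float = 20.0,
) -> list[CalledVariant]:
    """Depth-window and call-quality filter (QUAL >= 20, depth 1-30 defaults)."""
    if min_depth > max_depth:
        raise ValueError("min_depth > max_depth")
    return [
        c
        for c in calls
        if min_depth <= c.depth <= max_depth and c.call_quality >= min_qual
    ]


# ---------------------------------------------------------------------------
# emission


def write_sam(mapped: list[MappedRead], ref_len: int, path, ref_name: str = "ref") -> None:
    """Minimal valid single-contig SAM."""
    rows = sorted(mapped, key=lambda m: m.ref_start)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_len}\n")
        for m in rows:
            flag = 16 if m.strand == "-" else 0
            cig = "".join(f"{l}{op}" for op, l in m.cigar)
            qual = m.read.quality
            qstr = "".join(chr(q + 33) for q in qual)
            if m.strand == "-":
                qstr = qstr[::-1]
            fh.write(
                f"{m.read.id.replace('|', '_')}\t{flag}\t{ref_name}\t{m.ref_start + 1}\t"
                f"{m.mapping_quality}\t{cig}\t*\t0\t0\t{m.aln_seq}\t{qstr}\tNM:i:{m.edit_distance}\n"
            )


def write_calls_vcf(
    calls: list[CalledVariant], reference: str, path, ref_name: str = "ref"
) -> None:
    """Write calls as VCF v4.2 (indels anchored on the preceding base)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name},length={len(reference)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in sorted(calls, key=lambda c: c.ref_pos):
            gt = "1/1" if c.genotype == "hom" else "0/1"
            if c.kind == "snp":
                pos, ref_a, alt_a = c.ref_pos + 1, c.ref_allele, c.alt_allele
            elif c.kind == "deletion":
                anchor = reference[c.ref_pos - 1]
                pos, ref_a, alt_a = c.ref_pos, anchor + c.ref_allele, anchor
            else:
                anchor = reference[c.ref_pos - 1]
                pos, ref_a, alt_a = c.ref_pos, anchor, anchor + c.alt_allele
            fh.write(
                f"{ref_name}\t{pos}\t.\t{ref_a}\t{alt_a}\t{c.call_quality:.1f}\t"
                f"PASS\tDP={c.depth}\tGT\t{gt}\n"
            )
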