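"""Comparison of called variants to ground truth.

Counting is done in *allele copies*: a homozygous variant contributes two
copies, a heterozygous one a single copy, on both the truth and the called
side. A SNP copy is correct only if position and alternate base both match;
indel events match by left-aligned position within a ±3 bp window under a
one-to-one maximum matching. SNPs within 5 bp of any (truth or called)
indel are excluded from both sets, and only variants inside the reference
edge margins are scored.

accuracy      = correct copies / called copies          (per variant kind)
completeness  = correct copies / truth copies
hom:het ratio-of-ratios = (called hom:het among correct positions)
                        / (truth hom:het), -> 1 for unbiased calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align_call import CalledVariant, MappedRead
from .genome_sim import ReferenceSamplePair, TruthVariant
from .seq import left_align_indel

__all__ = [
    "TruthEvent",
    "CallEvent",
    "MatchResult",
    "EvalSummary",
    "prepare_truth",
    "prepare_calls",
    "match_indels",
    "match_snps",
    "summarize",
]


@dataclass(frozen=True)
class TruthEvent:
    pos: int  # left-aligned reference coordinate
    kind: str
    alt: str
    copies: int  # 1 het, 2 hom


@dataclass(frozen=True)
class CallEvent:
    pos: int
    kind: str
    alt: str
    copies: int


@dataclass
class MatchResult:
    """Copy-level tallies for one variant kind."""

    correct: int = 0
    incorrect: int = 0
    missed: int = 0
    # position-level genotype tallies among correctly called events
    correct_hom_calls: int = 0
    correct_het_calls: int = 0
    truth_hom: int = 0
    truth_het: int = 0

    @property
    def n_called(self) -> int:
        return self.correct + self.incorrect

    @property
    def n_truth(self) -> int:
        return self.correct + self.missed

    @property
    def accuracy(self) -> float:
        return 100.0 * self.correct / self.n_called if self.n_called else math.nan

    @property
    def completeness(self) -> float:
        return 100.0 * self.correct / self.n_truth if self.n_truth else math.nan

    @property
    def homhet_ratio_of_ratios(self) -> float:
        if min(self.correct_het_calls, self.truth_hom, self.truth_het) == 0:
            return math.nan
        observed = self.correct_hom_calls / self.correct_het_calls
        expected = self.truth_hom / self.truth_het
        return observed / expected if expected else math.nan


def prepare_truth(pair: ReferenceSamplePair) -> tuple[list[TruthEvent], list[TruthEvent]]:
    """Left-align truth and merge per-chromosome records into events.

    Returns ``(snps, indels)``. Two het records at one site (different
    alleles on the two chromosomes) stay separate single-copy events.
    """
    ref = pair.reference
    snps: list[TruthEvent] = []
    indels: dict[tuple[int, str, str], int] = {}
    for v in pair.truth:
        copies = 2 if v.chromosome_mask == 3 else 1
        if v.kind == "snp":
            snps.append(TruthEvent(v.ref_pos, "snp", v.alt_allele, copies))
        else:
            seq = v.ref_allele if v.kind == "deletion" else v.alt_allele
            pos, seq = left_align_indel(ref, v.ref_pos, seq, v.kind)
            key = (pos, v.kind, seq)
            indels[key] = indels.get(key, 0) + copies
    indel_events = [
        TruthEvent(pos, kind, seq, min(copies, 2))
        for (pos, kind, seq), copies in sorted(indels.items())
    ]
    return snps, indel_events


def prepare_calls(calls: list[CalledVariant]) -> tuple[list[CallEvent], list[CallEvent]]:
    snps, indels = [], []
    for c in calls:
        copies = 2 if c.genotype == "hom" else 1
        alt = c.alt_allele if c.kind != "deletion" else c.ref_allele
        ev = CallEvent(c.ref_pos, c.kind, alt, copies)
        (snps if c.kind == "snp" else indels).append(ev)
    return snps, indels


def _in_margin(pos: int, edge_margin: int, ref_len: int) -> bool:
    return edge_margin <= pos <= ref_len - edge_margin


_FORBIDDEN = 10**6


def _max_window_matching(
    called_pos: list[int], truth_pos: list[int], window: int
) -> list[tuple[int, int]]:
    """One-to-one nearest-position matching of events within ±window.

    Maximum-cardinality matching with minimum total distance as the
    tie-break, solved per connected cluster by optimal assignment (clusters
    are tiny: events further than the window apart never interact).
    """
    from scipy.optimize import linear_sum_assignment

    if not called_pos or not truth_pos:
        return []
    events = sorted(
        [(p, 0, i) for i, p in enumerate(called_pos)]
        + [(p, 1, j) for j, p in enumerate(truth_pos)]
    )
    pairs: list[tuple[int, int]] = []
    cluster: list[tuple[int, int, int]] = []

    def flush() -> None:
        cs = [(p, i) for p, side, i in cluster if side == 0]
        ts = [(p, j) for p, side, j in cluster if side == 1]
        if not cs or not ts:
            return
        cost = np.full((len(cs), len(ts)), _FORBIDDEN, dtype=float)
        for a, (cp, _) in enumerate(cs):
            for b, (tp, _) in enumerate(ts):
                if abs(cp - tp) <= window:
                    cost[a, b] = abs(cp - tp)
        rows, cols = linear_sum_assignment(cost)
        for a, b in zip(rows, cols):
            if cost[a, b] < _FORBIDDEN:
                pairs.append((cs[a][1], ts[b][1]))

    prev = None
    for ev in events:
        if prev is not None and ev[0] - prev > window:
            flush()
            cluster = []
        cluster.append(ev)
        prev = ev[0]
    flush()
    return pairs


def match_indels(
    called: list[CallEvent],
    truth: list[TruthEvent],
    ref_len: int,
    window: int = 3,
    edge_margin: int = 500,
) -> MatchResult:
    """Position-window one-to-one matching of indel events.

    Indels are scored at event level (position only): a matched pair is one
    correct call regardless of genotype, an unmatched call is incorrect, an
    unmatched truth event is missed. Called genotypes enter only the
    hom:het ratio.
    """
    called = [c for c in called if _in_margin(c.pos, edge_margin, ref_len)]
    truth = [t for t in truth if _in_margin(t.pos, edge_margin, ref_len)]
    pairs = _max_window_matching([c.pos for c in called], [t.pos for t in truth], window)
    res = MatchResult()
    res.correct = len(pairs)
    res.incorrect = len(called) - len(pairs)
    res.missed = len(truth) - len(pairs)
    for i, _ in pairs:
        if called[i].copies == 2:
            res.correct_hom_calls += 1
        else:
            res.correct_het_calls += 1
    res.truth_hom = sum(1 for t in truth if t.copies == 2)
    res.truth_het = sum(1 for t in truth if t.copies == 1)
    return res


def match_snps(
    called: list[CallEvent],
    truth: list[TruthEvent],
    ref_len: int,
    indel_positions: list[int] = (),
    indel_exclusion: int = 5,
    edge_margin: int = 500,
) -> MatchResult:
    """Exact position+allele SNP matching with indel-proximity exclusion."""
    excl = np.array(sorted(indel_positions), dtype=int)

    def near_indel(pos: int) -> bool:
        if excl.size == 0:
            return False
        k = np.searchsorted(excl, pos)
        for idx in (k - 1, k):
            if 0 <= idx < excl.size and abs(int(excl[idx]) - pos) <= indel_exclusion:
                return True
        return False

    called = [
        c for c in called if _in_margin(c.pos, edge_margin, ref_len) and not near_indel(c.pos)
    ]
    truth = [
        t for t in truth if _in_margin(t.pos, edge_margin, ref_len) and not near_indel(t.pos)
    ]
    truth_at: dict[tuple[int, str], int] = {}
    for t in truth:
        truth_at[(t.pos, t.alt)] = truth_at.get((t.pos, t.alt), 0) + t.copies
    res = MatchResult()
    remaining = dict(truth_at)
    for c in called:
        avail = remaining.get((c.pos, c.alt), 0)
        hit = min(c.copies, avail)
        if hit:
            remaining[(c.pos, c.alt)] = avail - hit
        res.correct += hit
        res.incorrect += c.copies - hit
        if hit:
            if c.copies == 2:
                res.correct_hom_calls += 1
            else:
                res.correct_het_calls += 1
    res.missed = sum(remaining.values())
    res.truth_hom = sum(1 for t in truth if t.copies == 2)
    res.truth_het = sum(1 for t in truth if t.copies == 1)
    return res


@dataclass
class EvalSummary:
    """Per-read-pool evaluation metrics (percentages in [0, 100])."""

    pct_reads_mapped: float
    mean_mapped_read_len: float
    pct_unique_5prime_starts: float
    snp_accuracy: float
    indel_accuracy: float
    snp_completeness: float
    indel_completeness: float
    snp_homhet_ratio_of_ratios: float
    indel_homhet_ratio_of_ratios: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    pair: ReferenceSamplePair,
    pool_size: int,
    mapped: list[MappedRead],
    calls: list[CalledVariant],
    window: int = 3,
    indel_exclusion: int = 5,
    edge_margin: int = 500,
) -> EvalSummary:
    """Match calls against truth and compute the per-pool summary row."""
    truth_snps, truth_indels = prepare_truth(pair)
    called_snps, called_indels = prepare_calls(calls)
    ref_len = len(pair.reference)
    indel_res = match_indels(called_indels, truth_indels, ref_len, window, edge_margin)
    indel_positions = [t.pos for t in truth_indels] + [c.pos for c in called_indels]
    snp_res = match_snps(
        called_snps, truth_snps, ref_len, indel_positions, indel_exclusion, edge_margin
    )
    if mapped:
        mean_len = float(np.mean([len(m.read.sequence) for m in mapped]))
        starts = {
            (m.strand, m.ref_start if m.strand == "+" else m.ref_end - 1) for m in mapped
        }
        uniq = 100.0 * len(starts) / len(mapped)
    else:
        mean_len, uniq = math.nan, math.nan
    return EvalSummary(
        pct_reads_mapped=100.0 * len(mapped) / pool_size if pool_size else math.nan,
        mean_mapped_read_len=mean_len,
        pct_unique_5prime_starts=uniq,
        snp_accuracy=snp_res.accuracy,
        indel_accuracy=indel_res.accuracy,
        snp_completeness=snp_res.completeness,
        indel_completeness=indel_res.completeness,
        snp_homhet_ratio_of_ratios=snp_res.homhet_ratio_of_ratios,
        indel_homhet_ratio_of_ratios=indel_res.homhet_ratio_of_ratios,
    )
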