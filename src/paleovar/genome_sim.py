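"""Simulation of a reference sequence and a divergent diploid sample.

The sample is modelled as two homologous chromosomes related to the
reference by the unrooted tree ``(reference:1x,(chr1:0.5x,chr2:0.5x):0.5x)``.
Because the HKY model is time-reversible, the root can be pulled onto the
reference tip: the reference is drawn from the stationary base distribution
and evolved along a shared branch of 1.5x to the bifurcation point, then
along two independent terminal branches of 0.5x each. Events on the shared
path appear on both chromosomes (homozygous); events on a terminal branch on
one (heterozygous).

Substitutions follow HKY with a four-category discrete-gamma rate
distribution plus a fraction of invariant sites; substitution along each
branch uses closed-form transition probabilities, so multiple hits within a
branch are collapsed. Indel lengths follow a truncated power law
``P(k) ∝ k^-a``. Every event is recorded in a replayable truth catalog: the
chromosome sequences are *constructed* by replaying the catalog against the
reference, which makes the catalog exact by construction.

Branch lengths are calibrated by bisection so that the realized density of
variant-affected positions matches the configured divergence level
(~2.6 per kb for "low", ~29 per kb for "high").
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .rng import child_seed
from .seq import decode, wrap_fasta

__all__ = [
    "GenomeSimConfig",
    "TruthVariant",
    "ReferenceSamplePair",
    "discrete_gamma_rates",
    "hky_rate_matrix",
    "hky_transition_matrix",
    "indel_length_pmf",
    "sample_indel_length",
    "simulate_pair",
    "calibrate_branch_length",
    "export_truth",
    "TARGET_DENSITY",
]

#: Target variant-position densities (affected positions per bp) by level.
TARGET_DENSITY = {"low": 2.6e-3, "high": 2.9e-2}

# Mean length of a truncated power-law indel with a=1.7, M=5 is ~1.715 bp;
# an event rate of (1/mean length) x the substitution rate makes indel- and
# SNP-affected position counts approximately equal.
_CALIBRATION_SEED_TAG = 20150123


@dataclass
class GenomeSimConfig:
    """Parameters for one reference/diploid-sample simulation."""

    length_bp: int = 10_001_000
    gc_content: float = 0.50
    divergence_level: str = "low"
    kappa: float = 2.0
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    prop_invariant: float = 0.1
    indel_power_a: float = 1.7
    indel_max_len_bp: int = 5
    indel_to_snp_rate_ratio: float | None = None
    seed: int = 0
    #: Total reference-to-chromosome path length in expected substitutions
    #: per variable site. ``None`` means calibrate against the divergence
    #: level's target density.
    total_branch_length: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.prop_invariant < 1:
            raise ValueError("prop_invariant must be in [0, 1)")
        if self.indel_max_len_bp < 1:
            raise ValueError("indel_max_len_bp must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.divergence_level not in TARGET_DENSITY:
            raise ValueError(f"unknown divergence level {self.divergence_level!r}")
        if self.length_bp < 100:
            raise ValueError("length_bp too small")

    @property
    def base_freqs(self) -> np.ndarray:
        """Stationary frequencies (A, C, G, T) for the configured GC."""
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    @property
    def target_density(self) -> float:
        return TARGET_DENSITY[self.divergence_level]

    def indel_rate_ratio(self) -> float:
        if self.indel_to_snp_rate_ratio is not None:
            return self.indel_to_snp_rate_ratio
        pmf = indel_length_pmf(self.indel_power_a, self.indel_max_len_bp)
        mean_len = float(np.sum(np.arange(1, self.indel_max_len_bp + 1) * pmf))
        return 1.0 / mean_len


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth variant event in reference coordinates (0-based).

    ``chromosome_mask`` is a bitmask over the two sample chromosomes
    (1 = chr1, 2 = chr2, 3 = both). For insertions ``ref_pos`` is the
    coordinate of the reference base *before which* ``alt_allele`` is
    inserted; for deletions it is the first deleted base.
    """

    ref_pos: int
    kind: str  # snp | insertion | deletion
    ref_allele: str
    alt_allele: str
    chromosome_mask: int

    def __post_init__(self) -> None:
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp alleles must differ")
        if self.chromosome_mask not in (1, 2, 3):
            raise ValueError("chromosome_mask must be 1, 2 or 3")

    @property
    def genotype(self) -> str:
        return "hom" if self.chromosome_mask == 3 else "het"

    @property
    def length(self) -> int:
        return len(self.ref_allele) if self.kind == "deletion" else len(self.alt_allele)


@dataclass
class ReferenceSamplePair:
    """Reference plus two homologous sample chromosomes and their truth."""

    reference: str
    chromosome1: str
    chromosome2: str
    truth: list[TruthVariant]
    site_rates: np.ndarray
    config: GenomeSimConfig | None = None

    def variant_positions(self) -> int:
        """Number of alignment positions affected by any variant event."""
        snp_pos = {v.ref_pos for v in self.truth if v.kind == "snp"}
        n = len(snp_pos)
        seen_indel: set[tuple[int, str]] = set()
        for v in self.truth:
            if v.kind == "snp" or (v.ref_pos, v.kind) in seen_indel:
                continue
            seen_indel.add((v.ref_pos, v.kind))
            n += v.length
        return n

    def variant_density(self) -> float:
        return self.variant_positions() / len(self.reference)


# ---------------------------------------------------------------------------
# substitution model


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean-one discrete gamma rate multipliers (quantile-midpoint rule)."""
    if shape <= 0:
        raise ValueError("shape must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.array([1.0])
    p = (2 * np.arange(ncat) + 1) / (2 * ncat)
    rates = gamma_dist.ppf(p, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def hky_rate_matrix(kappa: float, base_freqs: np.ndarray) -> np.ndarray:
    """HKY rate matrix scaled to one expected substitution per unit time."""
    pi = np.asarray(base_freqs, dtype=float)
    if abs(pi.sum() - 1) > 1e-8:
        raise ValueError("base_freqs must sum to 1")
    q = np.tile(pi, (4, 1))
    # transitions: A<->G (0,2), C<->T (1,3)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        q[i, j] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(pi, np.diag(q))
    return q / mu


def hky_transition_matrix(
    kappa: float, base_freqs: np.ndarray, branch_length: float, rate: float = 1.0
) -> np.ndarray:
    """Transition probability matrix P = exp(Q * t * rate)."""
    if branch_length < 0:
        raise ValueError("branch_length must be non-negative")
    q = hky_rate_matrix(kappa, base_freqs)
    return expm(q * branch_length * rate)


def indel_length_pmf(a: float, max_len: int) -> np.ndarray:
    """Truncated power-law pmf over lengths 1..max_len, P(k) ∝ k^-a."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    k = np.arange(1, max_len + 1, dtype=float)
    w = k**-a
    return w / w.sum()


def sample_indel_length(
    a: float, max_len: int, rng: np.random.Generator, size: int | None = None
):
    pmf = indel_length_pmf(a, max_len)
    out = rng.choice(np.arange(1, max_len + 1), size=size, p=pmf)
    return out if size is not None else int(out)


# ---------------------------------------------------------------------------
# simulation


def _evolve(
    parent: np.ndarray,
    cat_index: np.ndarray,
    cat_rates: np.ndarray,
    kappa: float,
    base_freqs: np.ndarray,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a code array along a branch of length ``t``.

    ``cat_index`` maps each site to a rate category; a negative index marks
    an invariant site (copied unchanged).
    """
    child = parent.copy()
    if t == 0:
        return child
    for c, rate in enumerate(cat_rates):
        p_mat = hky_transition_matrix(kappa, base_freqs, t, rate)
        cum = np.cumsum(p_mat, axis=1)
        in_cat = cat_index == c
        for b in range(4):
            idx = np.nonzero(in_cat & (parent == b))[0]
            if idx.size == 0:
                continue
            u = rng.random(idx.size)
            child[idx] = np.searchsorted(cum[b], u).astype(np.uint8)
    return child


def _evolve_small(
    seq: list[int],
    rate: float,
    kappa: float,
    base_freqs: np.ndarray,
    t: float,
    rng: np.random.Generator,
) -> list[int]:
    """Evolve a short code list (inserted material) along a branch."""
    if t == 0 or rate == 0:
        return list(seq)
    p_mat = hky_transition_matrix(kappa, base_freqs, t, rate)
    return [int(rng.choice(4, p=p_mat[b])) for b in seq]


def simulate_pair(config: GenomeSimConfig) -> ReferenceSamplePair:
    """Simulate one reference/diploid-sample pair with a replayable truth."""
    rng = np.random.default_rng(config.seed)
    L = config.length_bp
    pi = config.base_freqs
    total = (
        config.total_branch_length
        if config.total_branch_length is not None
        else calibrate_branch_length(
            config.gc_content,
            config.divergence_level,
            kappa=config.kappa,
            gamma_shape=config.gamma_shape,
            n_rate_categories=config.n_rate_categories,
            prop_invariant=config.prop_invariant,
            indel_power_a=config.indel_power_a,
            indel_max_len_bp=config.indel_max_len_bp,
            indel_rate_ratio=config.indel_rate_ratio(),
        )
    )
    t_shared, t_term = 0.75 * total, 0.25 * total

    ref = rng.choice(4, size=L, p=pi).astype(np.uint8)
    cat_rates = discrete_gamma_rates(config.gamma_shape, config.n_rate_categories)
    cat_index = rng.integers(0, config.n_rate_categories, size=L)
    invariant = rng.random(L) < config.prop_invariant
    cat_index[invariant] = -1
    site_rates = np.where(invariant, 0.0, cat_rates[np.clip(cat_index, 0, None)])

    anc = _evolve(ref, cat_index, cat_rates, config.kappa, pi, t_shared, rng)
    chr_subs = [
        _evolve(anc, cat_index, cat_rates, config.kappa, pi, t_term, rng)
        for _ in range(2)
    ]

    ref_str = decode(ref)
    truth: list[TruthVariant] = []

    # --- indel events: branch order shared, chr1, chr2; events that would
    # overlap (within 1 bp of) an earlier event's footprint are discarded.
    rho = config.indel_rate_ratio()
    occupied = np.zeros(L, dtype=bool)
    indel_events: list[tuple[int, str, int, str, int]] = []  # pos, kind, len, seq, mask
    pad = config.indel_max_len_bp + 1
    for t_branch, mask in ((t_shared, 3), (t_term, 1), (t_term, 2)):
        n_events = rng.poisson(rho * t_branch * L)
        for _ in range(n_events):
            pos = int(rng.integers(1, L - pad))
            length = sample_indel_length(config.indel_power_a, config.indel_max_len_bp, rng)
            is_ins = rng.random() < 0.5
            lo = pos - 1
            hi = pos + 1 if is_ins else pos + length + 1
            if occupied[lo:hi].any():
                continue
            occupied[lo:hi] = True
            if is_ins:
                ins = [int(b) for b in rng.choice(4, size=length, p=pi)]
                if mask == 3:
                    # shared insertions keep evolving along each terminal branch
                    local_rate = float(site_rates[pos])
                    c1 = _evolve_small(ins, local_rate, config.kappa, pi, t_term, rng)
                    c2 = _evolve_small(ins, local_rate, config.kappa, pi, t_term, rng)
                    if c1 == c2:
                        indel_events.append((pos, "insertion", length, decode(np.array(c1)), 3))
                    else:
                        indel_events.append((pos, "insertion", length, decode(np.array(c1)), 1))
                        indel_events.append((pos, "insertion", length, decode(np.array(c2)), 2))
                else:
                    indel_events.append((pos, "insertion", length, decode(np.array(ins)), mask))
            else:
                indel_events.append((pos, "deletion", length, "", mask))

    deleted = [np.zeros(L, dtype=bool), np.zeros(L, dtype=bool)]
    for pos, kind, length, _seq, mask in indel_events:
        if kind == "deletion":
            for c in range(2):
                if mask & (1 << c):
                    deleted[c][pos : pos + length] = True

    # Truth keeps the raw event placement (replay depends on it); canonical
    # left-aligned placement is recomputed against the reference wherever
    # positions are compared (see evaluate.match_indels).
    for pos, kind, length, seq, mask in indel_events:
        if kind == "deletion":
            truth.append(
                TruthVariant(pos, "deletion", ref_str[pos : pos + length], "", mask)
            )
        else:
            truth.append(TruthVariant(pos, "insertion", "", seq, mask))

    # --- SNP records from the substituted arrays, masked by deletions
    diff = [chr_subs[c] != ref for c in range(2)]
    for pos in np.nonzero(diff[0] | diff[1])[0]:
        pos = int(pos)
        alts = [int(chr_subs[c][pos]) if diff[c][pos] else None for c in range(2)]
        for c in range(2):
            if alts[c] is not None and deleted[c][pos]:
                alts[c] = None
        if alts[0] is not None and alts[0] == alts[1]:
            truth.append(
                TruthVariant(pos, "snp", ref_str[pos], decode(np.array([alts[0]])), 3)
            )
        else:
            for c in range(2):
                if alts[c] is not None:
                    truth.append(
                        TruthVariant(
                            pos, "snp", ref_str[pos], decode(np.array([alts[c]])), 1 << c
                        )
                    )

    truth.sort(key=lambda v: (v.ref_pos, v.kind, v.chromosome_mask))
    chr1, chr2 = (replay_truth(ref_str, truth, c) for c in (1, 2))
    return ReferenceSamplePair(ref_str, chr1, chr2, truth, site_rates, config)


def replay_truth(reference: str, truth: list[TruthVariant], chromosome: int) -> str:
    """Reconstruct one chromosome by applying the truth catalog."""
    bit = 1 << (chromosome - 1)
    arr = bytearray(reference.encode())
    events = []
    for v in truth:
        if not v.chromosome_mask & bit:
            continue
        if v.kind == "snp":
            arr[v.ref_pos] = ord(v.alt_allele)
        else:
            events.append(v)
    events.sort(key=lambda v: v.ref_pos)
    parts: list[bytes] = []
    prev = 0
    for v in events:
        parts.append(bytes(arr[prev : v.ref_pos]))
        if v.kind == "deletion":
            prev = v.ref_pos + len(v.ref_allele)
        else:
            parts.append(v.alt_allele.encode())
            prev = v.ref_pos
    parts.append(bytes(arr[prev:]))
    return b"".join(parts).decode()


# ---------------------------------------------------------------------------
# branch-length calibration


@functools.lru_cache(maxsize=None)
def calibrate_branch_length(
    gc_content: float,
    divergence_level: str,
    kappa: float = 2.0,
    gamma_shape: float = 1.0,
    n_rate_categories: int = 4,
    prop_invariant: float = 0.1,
    indel_power_a: float = 1.7,
    indel_max_len_bp: int = 5,
    indel_rate_ratio: float | None = None,
    calibration_length: int = 400_000,
    rel_tol: float = 0.05,
) -> float:
    """Bisect the total branch length to hit the target variant density.

    Calibration runs on its own fixed seed so the returned length depends
    only on the model parameters, not on the user's simulation seed.
    """
    target = TARGET_DENSITY[divergence_level]
    seed = child_seed(_CALIBRATION_SEED_TAG, f"calib:{gc_content}:{divergence_level}")

    def realized(total: float) -> float:
        cfg = GenomeSimConfig(
            length_bp=calibration_length,
            gc_content=gc_content,
            divergence_level=divergence_level,
            kappa=kappa,
            gamma_shape=gamma_shape,
            n_rate_categories=n_rate_categories,
            prop_invariant=prop_invariant,
            indel_power_a=indel_power_a,
            indel_max_len_bp=indel_max_len_bp,
            indel_to_snp_rate_ratio=indel_rate_ratio,
            seed=seed,
            total_branch_length=total,
        )
        return simulate_pair(cfg).variant_density()

    # density ~= 2.5 * total * (1 - prop_invariant)-ish; start from a
    # generous bracket around the linear guess
    guess = target / 2.5
    lo, hi = guess / 5, guess * 5
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        d = realized(mid)
        if abs(d - target) / target < rel_tol:
            return mid
        if d < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# export


def export_truth(pair: ReferenceSamplePair, edge_margin: int = 0, path=None) -> str:
    """Render the truth catalog as a VCF v4.2 string (and optionally write it).

    Only variants with reference position in ``[edge_margin,
    length - edge_margin]`` are emitted. Multiple het records at one site are
    merged into a single multi-allelic record.
    """
    L = len(pair.reference)
    if edge_margin < 0:
        raise ValueError("edge_margin must be >= 0")
    if edge_margin >= L / 2:
        raise ValueError("edge_margin must be < length/2")
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=ref,length={L}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
    ]
    by_site: dict[tuple[int, str], list[TruthVariant]] = {}
    for v in pair.truth:
        if not edge_margin <= v.ref_pos <= L - edge_margin:
            continue
        by_site.setdefault((v.ref_pos, v.kind), []).append(v)
    for (pos, kind), group in sorted(by_site.items()):
        ref_str = pair.reference
        if kind == "snp":
            vcf_pos, ref_allele = pos + 1, group[0].ref_allele
            alts = sorted({v.alt_allele for v in group})
        elif kind == "deletion":
            anchor = ref_str[pos - 1]
            vcf_pos = pos  # 1-based coordinate of the anchor base
            ref_allele = anchor + group[0].ref_allele
            alts = [anchor]
        else:
            anchor = ref_str[pos - 1]
            vcf_pos = pos
            ref_allele = anchor
            alts = sorted({anchor + v.alt_allele for v in group})
        mask = 0
        for v in group:
            mask |= v.chromosome_mask
        if len(alts) == 2:
            gt = "1/2"
        elif mask == 3:
            gt = "1/1"
        else:
            gt = "0/1"
        lines.append(
            f"ref\t{vcf_pos}\t.\t{ref_allele}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gt}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def export_fasta(pair: ReferenceSamplePair, path) -> None:
    """Write reference and both chromosomes as 60-column FASTA."""
    with open(path, "w") as fh:
        for name, seq in (
            ("ref", pair.reference),
            ("chr1", pair.chromosome1),
            ("chr2", pair.chromosome2),
        ):
            fh.write(f">{name}\n{wrap_fasta(seq)}\n")
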