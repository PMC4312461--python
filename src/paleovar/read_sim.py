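"""Single-end read synthesis from the diploid sample.

Raw 100 bp reads are drawn uniformly from both strands of both chromosomes
at deep coverage with a uniform per-base substitution error model (constant
Phred quality, default Q35), then trimmed from the 3' end to exponential
length distributions centred on 40/60/80 bp: 15% of reads sit exactly at
the mean and the probability drops by 25% per bp away from it, truncated at
mean ± 10 and renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import revcomp

__all__ = [
    "ReadRecord",
    "TrimDistribution",
    "ErrorModel",
    "trim_length_pmf",
    "generate_raw_reads",
    "trim_read",
    "trim_pool",
]


@dataclass(slots=True)
class ReadRecord:
    """One simulated read and the ledger of edits applied to it.

    ``origin_start``/``origin_end`` delimit the half-open source-chromosome
    interval the read currently covers. ``sequence`` is in sequencing
    orientation (reverse-strand reads are already reverse-complemented).
    ``seq_errors`` holds read-local offsets altered by the sequencing-error
    model; ``damage_edits`` holds ``(offset, "C>T"|"G>A")`` pairs filled in
    by the damage stage.
    """

    id: str
    source_chromosome: int
    origin_start: int
    origin_end: int
    strand: str
    sequence: str
    quality: np.ndarray
    seq_errors: list = field(default_factory=list)
    damage_edits: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimDistribution:
    """Exponential-decay read-length distribution around a mean."""

    mean_len: int
    span: int = 10
    peak_fraction: float = 0.15
    step_factor: float = 0.75

    def __post_init__(self) -> None:
        if self.span < 0:
            raise ValueError("span must be >= 0")
        if not 0 < self.step_factor <= 1:
            raise ValueError("step_factor must be in (0, 1]")
        if not 0 < self.peak_fraction <= 1:
            raise ValueError("peak_fraction must be in (0, 1]")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.mean_len - self.span, self.mean_len + self.span + 1)


@dataclass(frozen=True)
class ErrorModel:
    """Uniform per-base substitution errors at a constant Phred quality.

    ``rate`` overrides the quality-implied error probability (use 0 for
    error-free pools); the emitted quality string is unchanged.
    """

    phred_quality: int = 35
    rate: float | None = None

    @property
    def error_rate(self) -> float:
        if self.rate is not None:
            return self.rate
        return 10 ** (-self.phred_quality / 10)


def trim_length_pmf(dist: TrimDistribution) -> np.ndarray:
    """Renormalised probability vector over ``dist.lengths``."""
    k = np.abs(dist.lengths - dist.mean_len)
    raw = dist.peak_fraction * dist.step_factor**k
    return raw / raw.sum()


def generate_raw_reads(
    chromosomes: list[str],
    raw_read_len: int = 100,
    raw_coverage: float = 300.0,
    error_model: ErrorModel = ErrorModel(),
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Draw raw reads uniformly from both strands of each chromosome.

    ``raw_coverage`` is per chromosome. The pools from the two homologous
    chromosomes are combined and randomly ordered.
    """
    if raw_coverage <= 0:
        raise ValueError("raw_coverage must be positive")
    rng = rng or np.random.default_rng()
    eps = error_model.error_rate
    qual = np.full(raw_read_len, error_model.phred_quality, dtype=np.uint8)
    reads: list[ReadRecord] = []
    serial = 0
    for chrom_no, chrom in enumerate(chromosomes, start=1):
        clen = len(chrom)
        if raw_read_len > clen:
            raise ValueError("raw_read_len exceeds chromosome length")
        n_reads = int(round(raw_coverage * clen / raw_read_len))
        starts = rng.integers(0, clen - raw_read_len + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        n_errors = rng.binomial(raw_read_len, eps, size=n_reads)
        for i in range(n_reads):
            s = int(starts[i])
            frag = chrom[s : s + raw_read_len]
            strand = "-" if strands[i] else "+"
            seq = revcomp(frag) if strand == "-" else frag
            errors: list[int] = []
            if n_errors[i]:
                offs = rng.choice(raw_read_len, size=n_errors[i], replace=False)
                seq_l = list(seq)
                for off in offs:
                    off = int(off)
                    choices = [b for b in "ACGT" if b != seq_l[off]]
                    seq_l[off] = choices[int(rng.integers(3))]
                    errors.append(off)
                seq = "".join(seq_l)
            rid = f"r{serial:08d}|c{chrom_no}|{s}|{strand}"
            reads.append(
                ReadRecord(rid, chrom_no, s, s + raw_read_len, strand, seq, qual, errors)
            )
            serial += 1
    order = rng.permutation(len(reads))
    return [reads[int(i)] for i in order]


def trim_read(read: ReadRecord, target_len: int) -> ReadRecord:
    """Truncate a read to its first ``target_len`` bases (5' end kept)."""
    n = len(read.sequence)
    if target_len > n:
        raise ValueError("target_len exceeds read length")
    if target_len == n:
        return read
    if read.strand == "+":
        start, end = read.origin_start, read.origin_start + target_len
    else:
        start, end = read.origin_end - target_len, read.origin_end
    return ReadRecord(
        read.id,
        read.source_chromosome,
        start,
        end,
        read.strand,
        read.sequence[:target_len],
        read.quality[:target_len],
        [o for o in read.seq_errors if o < target_len],
        [e for e in read.damage_edits if e[0] < target_len],
    )


def trim_pool(
    reads: list[ReadRecord], dist: TrimDistribution, rng: np.random.Generator
) -> list[ReadRecord]:
    """Trim every read in a pool to lengths drawn from ``dist``."""
    pmf = trim_length_pmf(dist)
    targets = rng.choice(dist.lengths, size=len(reads), p=pmf)
    return [trim_read(r, int(t)) for r, t in zip(reads, targets)]
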