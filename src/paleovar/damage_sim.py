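"""Post-mortem damage model: fragmentation bias, terminal deamination,
and subsampling of read pools to target coverage depths.

Fragmentation bias is modelled at read selection: a trimmed read is accepted
with probability proportional to selection weights of the genomic bases
immediately 5' of its start and immediately 3' of its end (on the read's
source strand), normalised so the most-favoured context is accepted at
``base_accept`` (0.5). Purines are favoured 5' of starts and pyrimidines 3'
of ends, with G over A (and C over T) by about two-fold.

Deamination then converts terminal cytosines to thymines from the 5' end
(and guanines to adenines from the 3' end) with probability ``p0`` at the
terminal base, decaying by 25% per position inward until it falls below a
cutoff of 0.01 — 9 affected positions per end at the low level (p0 = 0.12),
13 at the high level (p0 = 0.4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .read_sim import ReadRecord
from .seq import revcomp

__all__ = [
    "DamageConfig",
    "DAMAGE_LEVELS",
    "eligible_positions",
    "misincorporation_probs",
    "accept_fragment",
    "apply_misincorporation",
    "build_damaged_pool",
    "subsample_to_depth",
    "damage_ledger",
]

_UNIFORM = {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0}
# Bordering-nucleotide selection weights; tables average 1.0 at equal base
# frequencies and keep the ~2:1 G:A (and C:T) excess seen in damaged pools.
_W5 = {
    "none": _UNIFORM,
    "low": {"G": 1.2, "A": 1.1, "T": 0.9, "C": 0.8},
    "high": {"G": 1.6, "A": 1.3, "T": 0.7, "C": 0.4},
}
_W3 = {
    "none": _UNIFORM,
    "low": {"C": 1.2, "T": 1.1, "A": 0.9, "G": 0.8},
    "high": {"C": 1.6, "T": 1.3, "A": 0.7, "G": 0.4},
}
_P0 = {"none": 0.0, "low": 0.12, "high": 0.4}


@dataclass(frozen=True)
class DamageConfig:
    """All damage-model parameters for a named level."""

    level: str
    p0: float
    decay: float = 0.75
    cutoff: float = 0.01
    frag_weights_5p: dict = field(default_factory=lambda: dict(_UNIFORM))
    frag_weights_3p: dict = field(default_factory=lambda: dict(_UNIFORM))
    base_accept: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must be in [0, 1]")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")
        if any(w <= 0 for w in self.frag_weights_5p.values()) or any(
            w <= 0 for w in self.frag_weights_3p.values()
        ):
            raise ValueError("fragmentation weights must be positive")

    @classmethod
    def preset(cls, level: str, **overrides) -> "DamageConfig":
        if level not in _P0:
            raise ValueError(f"unknown damage level {level!r}")
        kwargs = dict(
            level=level,
            p0=_P0[level],
            frag_weights_5p=dict(_W5[level]),
            frag_weights_3p=dict(_W3[level]),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


DAMAGE_LEVELS = ("none", "low", "high")


def eligible_positions(p0: float, decay: float, cutoff: float) -> int:
    """Largest n with p0 * decay^(n-1) >= cutoff (0 if p0 < cutoff)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0 < decay <= 1:
        raise ValueError("decay must be in (0, 1]")
    if p0 < cutoff:
        return 0
    if decay == 1.0:
        raise ValueError("decay = 1 with p0 >= cutoff never falls below cutoff")
    n = 0
    p = p0
    while p >= cutoff:
        n += 1
        p *= decay
    return n


def misincorporation_probs(cfg: DamageConfig) -> np.ndarray:
    """Per-offset transition probabilities from a read end, cutoff applied."""
    n = eligible_positions(cfg.p0, cfg.decay, cfg.cutoff) if cfg.p0 > 0 else 0
    return cfg.p0 * cfg.decay ** np.arange(n)


def accept_fragment(
    base_5p: str | None,
    base_3p: str | None,
    cfg: DamageConfig,
    rng: np.random.Generator,
) -> bool:
    """Fragmentation-biased read selection (missing flank => weight 1)."""
    return rng.random() < acceptance_probability(base_5p, base_3p, cfg)


def acceptance_probability(
    base_5p: str | None, base_3p: str | None, cfg: DamageConfig
) -> float:
    if cfg.level == "none":
        return cfg.base_accept
    w5 = cfg.frag_weights_5p.get(base_5p, 1.0) if base_5p else 1.0
    w3 = cfg.frag_weights_3p.get(base_3p, 1.0) if base_3p else 1.0
    return cfg.base_accept * w5 * w3 / (
        max(cfg.frag_weights_5p.values()) * max(cfg.frag_weights_3p.values())
    )


def apply_misincorporation(
    read: ReadRecord, cfg: DamageConfig, rng: np.random.Generator
) -> ReadRecord:
    """Introduce terminal C->T (5' track) and G->A (3' track) transitions.

    The two tracks act on different template bases, so on very short reads
    they overlap without conflict. Edits are recorded in ``damage_edits`` as
    ``(read_offset, "C>T"|"G>A")`` in sequencing orientation.
    """
    probs = misincorporation_probs(cfg)
    if probs.size == 0:
        return read
    seq = list(read.sequence)
    n = len(seq)
    edits = list(read.damage_edits)
    for i, p in enumerate(probs[: n]):
        if seq[i] == "C" and rng.random() < p:
            seq[i] = "T"
            edits.append((i, "C>T"))
    for j, p in enumerate(probs[: n]):
        k = n - 1 - j
        if seq[k] == "G" and rng.random() < p:
            seq[k] = "A"
            edits.append((k, "G>A"))
    if len(edits) == len(read.damage_edits):
        return read
    return ReadRecord(
        read.id,
        read.source_chromosome,
        read.origin_start,
        read.origin_end,
        read.strand,
        "".join(seq),
        read.quality,
        read.seq_errors,
        edits,
    )


def _flanking_bases(read: ReadRecord, chromosomes: list[str]) -> tuple[str | None, str | None]:
    """Genomic neighbours of the fragment ends on the read's source strand."""
    chrom = chromosomes[read.source_chromosome - 1]
    s, e = read.origin_start, read.origin_end
    if read.strand == "+":
        b5 = chrom[s - 1] if s > 0 else None
        b3 = chrom[e] if e < len(chrom) else None
    else:
        b5 = revcomp(chrom[e]) if e < len(chrom) else None
        b3 = revcomp(chrom[s - 1]) if s > 0 else None
    return b5, b3


def build_damaged_pool(
    trimmed: list[ReadRecord],
    chromosomes: list[str],
    cfg: DamageConfig,
    rng: np.random.Generator,
    max_bases: float | None = None,
) -> list[ReadRecord]:
    """Select reads under fragmentation bias and damage the survivors.

    Walks the (already randomly ordered) trimmed pool, accepting each read
    per its fragment-end context and applying deamination to accepted reads.
    Stops early once ``max_bases`` accepted bases have been produced.
    """
    out: list[ReadRecord] = []
    total = 0
    for read in trimmed:
        b5, b3 = _flanking_bases(read, chromosomes)
        if rng.random() >= acceptance_probability(b5, b3, cfg):
            continue
        damaged = apply_misincorporation(read, cfg, rng)
        out.append(damaged)
        total += len(damaged)
        if max_bases is not None and total >= max_bases:
            break
    return out


def subsample_to_depth(
    pool: list[ReadRecord],
    depth: float,
    ref_len: int,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
) -> list[ReadRecord]:
    """Draw reads without replacement until cumulative bases reach depth*ref_len.

    With ``shuffle=False`` the pool order is used as the random order, which
    makes pools at increasing depths nested subsets (the pool must then
    already be randomly ordered).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    target = depth * ref_len
    if target == 0:
        return []
    if shuffle:
        if rng is None:
            raise ValueError("rng required when shuffle=True")
        order = rng.permutation(len(pool))
        pool = [pool[int(i)] for i in order]
    out: list[ReadRecord] = []
    total = 0
    for read in pool:
        out.append(read)
        total += len(read)
        if total >= target:
            return out
    raise ValueError(
        f"pool exhausted at {total / ref_len:.2f}x before reaching {depth}x; "
        "increase raw_coverage"
    )


def damage_ledger(pool: list[ReadRecord]) -> dict:
    """JSON-serialisable record of true misincorporation positions per read."""
    return {
        r.id: [[off, kind] for off, kind in r.damage_edits]
        for r in pool
        if r.damage_edits
    }


def write_damage_ledger(pool: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump(damage_ledger(pool), fh)
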