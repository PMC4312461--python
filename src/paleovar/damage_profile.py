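"""Realized damage profiles from mapped reads.

Two mapDamage-style summaries: reference base composition flanking mapped
fragment ends (fragmentation-bias readout) and misincorporation frequency
by read position (C->T from the 5' end, G->A from the 3' end), both
strand-aware: reverse-strand reads are complemented and mirrored so that
offsets are always measured in the read's sequencing orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_call import MappedRead
from .seq import BASES

__all__ = [
    "CompositionProfile",
    "MisincorporationProfile",
    "composition_around_ends",
    "misincorporation_by_position",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CompositionProfile:
    """Reference base frequencies around mapped fragment ends.

    ``five_prime[d]`` (d = 1..window) are frequencies over A,C,G,T of the
    reference base ``d`` positions before the fragment 5' start, on the
    fragment's strand; ``three_prime[d]`` mirrors this after the 3' end.
    """

    window: int
    five_prime: dict
    three_prime: dict
    background: np.ndarray

    def ratio(self, end: str, distance: int) -> dict:
        """Position/background frequency ratios, keyed by base."""
        table = self.five_prime if end == "5p" else self.three_prime
        freqs = table[distance]
        return {b: freqs[i] / self.background[i] for i, b in enumerate(BASES)}


@dataclass
class MisincorporationProfile:
    """Observed terminal-transition rates by read offset.

    ``ct_rate[i]`` is the fraction of reference-C columns at offset ``i``
    from the 5' read end observed as T; ``ga_rate[j]`` likewise for
    reference-G read as A at offset ``j`` from the 3' end.
    """

    ct_count: np.ndarray
    ct_opportunity: np.ndarray
    ga_count: np.ndarray
    ga_opportunity: np.ndarray

    @property
    def ct_rate(self) -> np.ndarray:
        return np.divide(
            self.ct_count,
            self.ct_opportunity,
            out=np.zeros_like(self.ct_count, dtype=float),
            where=self.ct_opportunity > 0,
        )

    @property
    def ga_rate(self) -> np.ndarray:
        return np.divide(
            self.ga_count,
            self.ga_opportunity,
            out=np.zeros_like(self.ga_count, dtype=float),
            where=self.ga_opportunity > 0,
        )


def composition_around_ends(
    mapped: list[MappedRead], reference: str, window: int = 10
) -> CompositionProfile:
    """Tabulate reference bases flanking mapped fragment ends."""
    if not mapped:
        raise ValueError("no mapped reads")
    L = len(reference)
    five = {d: np.zeros(4) for d in range(1, window + 1)}
    three = {d: np.zeros(4) for d in range(1, window + 1)}
    idx = {b: i for i, b in enumerate(BASES)}
    comp_idx = {b: idx[_COMP[b]] for b in BASES}
    for m in mapped:
        s, e = m.ref_start, m.ref_end
        for d in range(1, window + 1):
            if m.strand == "+":
                if s - d >= 0:
                    five[d][idx[reference[s - d]]] += 1
                if e - 1 + d < L:
                    three[d][idx[reference[e - 1 + d]]] += 1
            else:
                if e - 1 + d < L:
                    five[d][comp_idx[reference[e - 1 + d]]] += 1
                if s - d >= 0:
                    three[d][comp_idx[reference[s - d]]] += 1
    for table in (five, three):
        for d in table:
            total = table[d].sum()
            if total:
                table[d] = table[d] / total
    bg = np.zeros(4)
    for b, i in idx.items():
        bg[i] = reference.count(b)
    bg /= bg.sum()
    return CompositionProfile(window, five, three, bg)


def misincorporation_by_position(
    mapped: list[MappedRead], reference: str, max_offset: int = 25
) -> MisincorporationProfile:
    """Observed C->T / G->A rates among matched columns, by end offset.

    Only CIGAR match columns count as opportunities. Offsets run from each
    read end in sequencing orientation; on reverse-strand reads the 5' end
    is the rightmost reference position and bases are complemented, so a
    template C->T deamination always lands in the ct track.
    """
    ct_n = np.zeros(max_offset, dtype=np.int64)
    ct_d = np.zeros(max_offset, dtype=np.int64)
    ga_n = np.zeros(max_offset, dtype=np.int64)
    ga_d = np.zeros(max_offset, dtype=np.int64)
    for m in mapped:
        n = len(m.aln_seq)
        qp = 0
        rp = m.ref_start
        for op, length in m.cigar:
            if op == "I":
                qp += length
                continue
            if op == "D":
                rp += length
                continue
            for i in range(length):
                ref_b = reference[rp + i]
                read_b = m.aln_seq[qp + i]
                if m.strand == "+":
                    off5 = qp + i
                    off3 = n - 1 - (qp + i)
                else:
                    ref_b = _COMP[ref_b]
                    read_b = _COMP[read_b]
                    off5 = n - 1 - (qp + i)
                    off3 = qp + i
                if ref_b == "C" and off5 < max_offset:
                    ct_d[off5] += 1
                    if read_b == "T":
                        ct_n[off5] += 1
                if ref_b == "G" and off3 < max_offset:
                    ga_d[off3] += 1
                    if read_b == "A":
                        ga_n[off3] += 1
            qp += length
            rp += length
    return MisincorporationProfile(ct_n, ct_d, ga_n, ga_d)


def composition_table(profile: CompositionProfile) -> "pandas.DataFrame":
    """Long-form composition table (end, distance, base, freq, ratio)."""
    import pandas as pd

    rows = []
    for end, table in (("5p", profile.five_prime), ("3p", profile.three_prime)):
        for d, freqs in table.items():
            for i, b in enumerate(BASES):
                rows.append(
                    {
                        "end": end,
                        "distance": d,
                        "base": b,
                        "freq": freqs[i],
                        "background": profile.background[i],
                        "ratio": freqs[i] / profile.background[i],
                    }
                )
    return pd.DataFrame(rows)


def misincorporation_table(
    profile: MisincorporationProfile, injected: dict | None = None
) -> "pandas.DataFrame":
    """Observed (and optionally injected/expected) rates by offset."""
    import pandas as pd

    rows = []
    for track, rate in (("ct_5p", profile.ct_rate), ("ga_3p", profile.ga_rate)):
        for off, r in enumerate(rate):
            row = {"track": track, "offset": off, "observed": r}
            if injected is not None:
                row["injected"] = injected.get(track, {}).get(off, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
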