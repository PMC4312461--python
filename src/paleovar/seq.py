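"""Small sequence utilities shared across the pipeline.

Bases are encoded A=0, C=1, G=2, T=3 in numpy uint8 arrays; plain Python
strings are used at module boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def left_align_indel(ref: str, pos: int, seq: str, kind: str, min_pos: int = 1):
    """Shift an indel to its leftmost equivalent placement.

    ``pos`` is the 0-based reference coordinate of the first deleted base
    (deletions) or of the base before which the sequence is inserted
    (insertions). Returns ``(pos, seq)`` after left-normalisation, the
    canonical placement used for both truth and called indels.
    """
    n = len(seq)
    if kind == "deletion":
        while pos > min_pos and ref[pos - 1] == ref[pos + n - 1]:
            pos -= 1
    elif kind == "insertion":
        while pos > min_pos and ref[pos - 1] == seq[-1]:
            seq = seq[-1] + seq[:-1]
            pos -= 1
    else:
        raise ValueError(f"not an indel kind: {kind!r}")
    return pos, seq


def wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
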