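"""Nucleotide encoding helpers shared across the package.

Sequences travel as Python strings at module boundaries and as uint8 code
arrays (A=0, C=1, G=2, T=3, N=4) inside the numeric kernels.  Any character
outside ACGT (case-insensitive) is treated as N.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T)):
    _ENCODE[ord(_ch)] = _code
    _ENCODE[ord(_ch.lower())] = _code

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    acgt = codes < 4
    n = int(acgt.sum())
    if n == 0:
        return 0.0
    gc = int(((codes == C) | (codes == G)).sum())
    return gc / n


def n_run_intervals(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Half-open intervals of maximal N runs of length >= min_len."""
    codes = encode(seq)
    isn = np.concatenate(([0], (codes == N).view(np.uint8), [0]))
    d = np.diff(isn)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]
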