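"""Sorted-array k-mer index used by the seed-and-extend homology search
and by whole-genome fragment anchoring.

k-mers containing N are never indexed or queried.
"""
from __future__ import annotations

import numpy as np

from ._seq import encode


def kmer_codes(seq_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of a code array into int64; returns (kmers, valid).

    ``kmers[i]`` packs positions [i, i+k); ``valid[i]`` is False when the
    window contains an N.
    """
    n = len(seq_codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    vals = np.zeros(n, np.int64)
    valid = np.ones(n, bool)
    c = seq_codes.astype(np.int64)
    for off in range(k):
        win = c[off : off + n]
        vals = vals * 4 + np.where(win < 4, win, 0)
        valid &= win < 4
    return vals, valid


class KmerIndex:
    """Index of all k-mer positions of one sequence."""

    def __init__(self, seq: str, k: int = 12):
        self.k = k
        codes = encode(seq)
        vals, valid = kmer_codes(codes, k)
        pos = np.flatnonzero(valid)
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self._kmers = vals[order]
        self._pos = pos[order].astype(np.int64)

    def seed_matches(
        self, query: str, step: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) seed matches, query sampled every
        ``step`` positions."""
        codes = encode(query)
        vals, valid = kmer_codes(codes, self.k)
        qpos = np.flatnonzero(valid)[::step]
        if len(qpos) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qv = vals[qpos]
        lo = np.searchsorted(self._kmers, qv, side="left")
        hi = np.searchsorted(self._kmers, qv, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        out_q = np.repeat(qpos, counts)
        out_t = np.empty(total, np.int64)
        at = 0
        for i in range(len(qpos)):
            c = counts[i]
            if c:
                out_t[at : at + c] = self._pos[lo[i] : hi[i]]
                at += c
        return out_q, out_t


def cluster_diagonals(
    qpos: np.ndarray, tpos: np.ndarray, max_gap: int = 100
) -> list[tuple[int, int, int]]:
    """Group seed matches into diagonal clusters.

    Returns (diag_min, diag_max, n_seeds) per cluster, sorted by seed count
    descending.  Seeds on diagonals within ``max_gap`` of each other are
    merged; clusters from well-separated target loci end up distinct
    because their diagonals differ by the locus separation.
    """
    if len(qpos) == 0:
        return []
    diags = np.sort(tpos - qpos)
    breaks = np.flatnonzero(np.diff(diags) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(diags)]))
    clusters = [
        (int(diags[s]), int(diags[e - 1]), int(e - s)) for s, e in zip(starts, ends)
    ]
    clusters.sort(key=lambda c: -c[2])
    return clusters
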