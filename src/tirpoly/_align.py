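"""Affine-gap local alignment kernels.

Two numba kernels implement the same Smith-Waterman recurrence with affine
gap costs (a gap of length L costs ``gap_open + (L-1) * gap_extend``, the
EMBOSS convention for the penalties 30/0.1 used throughout the pipeline):

* a full quadratic DP with per-cell traceback, used for small problems and
  as the exactness contract, and
* a banded DP restricted to a diagonal interval, used for long
  near-collinear windows.  ``align_auto`` derives the band from the
  unit-cost optimal path (edlib) and widens it whenever the traceback
  touches a band edge, falling back to the full DP, so in practice the
  banded route returns the same optimum as the full DP.

Ns score as mismatches against everything, including other Ns.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

from ._seq import decode, encode

NEG = -1e30

# traceback byte layout: bits 0-1 = H source (0 stop, 1 diag, 2 E, 3 F),
# bit 2 = E reached by extension, bit 3 = F reached by extension.


@njit(cache=True)
def _sw_full(a, b, match, mismatch, gap_open, gap_ext, tb):
    n = a.shape[0]
    m = b.shape[0]
    Hprev = np.zeros(m + 1, np.float64)
    Hcur = np.zeros(m + 1, np.float64)
    E = np.full(m + 1, NEG, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        Hcur[0] = 0.0
        F = NEG
        ai = a[i - 1]
        hdiag = Hprev[0]
        trow = tb[i - 1]
        for j in range(1, m + 1):
            eo = Hprev[j] - gap_open
            ee = E[j] - gap_ext
            eflag = np.uint8(4) if ee > eo else np.uint8(0)
            e = max(eo, ee)
            E[j] = e
            fo = Hcur[j - 1] - gap_open
            fe = F - gap_ext
            fflag = np.uint8(8) if fe > fo else np.uint8(0)
            f = max(fo, fe)
            F = f
            bjc = b[j - 1]
            s = hdiag + (match if (ai == bjc and ai < 4) else mismatch)
            hdiag = Hprev[j]
            h = max(0.0, s, e, f)
            src = np.uint8(0)
            if h > 0.0:
                if h == s:
                    src = np.uint8(1)
                elif h == e:
                    src = np.uint8(2)
                else:
                    src = np.uint8(3)
            Hcur[j] = h
            trow[j - 1] = src | eflag | fflag
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
    return best, bi, bj


@njit(cache=True)
def _tb_full(tb, bi, bj, ops):
    """Walk the full-DP traceback from (bi, bj); returns (start_i, start_j, k).

    ops (reversed): 0 = diagonal, 1 = a against gap, 2 = b against gap.
    """
    i = bi
    j = bj
    k = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        v = tb[i - 1, j - 1]
        if state == 0:
            src = v & 3
            if src == 0:
                break
            if src == 1:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            extended = v & 4
            i -= 1
            if not extended:
                state = 0
        else:
            ops[k] = 2
            k += 1
            extended = v & 8
            j -= 1
            if not extended:
                state = 0
    return i, j, k


@njit(cache=True)
def _sw_banded(a, b, match, mismatch, gap_open, gap_ext, dlo, dhi, tb):
    """Banded SW over diagonals j - i in [dlo, dhi] (DP cells, 1-based)."""
    n = a.shape[0]
    m = b.shape[0]
    Hprev = np.zeros(m + 1, np.float64)
    Hcur = np.zeros(m + 1, np.float64)
    E = np.full(m + 1, NEG, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > m:
            jhi = m
        if jlo > jhi:
            continue
        # cells right of the previous row's band carry stale values; the
        # row-0 boundary (i == 1) is genuinely all-zero and must be kept
        if i > 1 and i + dhi <= m:
            Hprev[i + dhi] = NEG
            E[i + dhi] = NEG
        Hcur[jlo - 1] = 0.0
        F = NEG
        ai = a[i - 1]
        hdiag = Hprev[jlo - 1]
        trow = tb[i - 1]
        off = i + dlo
        for j in range(jlo, jhi + 1):
            eo = Hprev[j] - gap_open
            ee = E[j] - gap_ext
            eflag = np.uint8(4) if ee > eo else np.uint8(0)
            e = max(eo, ee)
            E[j] = e
            fo = Hcur[j - 1] - gap_open
            fe = F - gap_ext
            fflag = np.uint8(8) if fe > fo else np.uint8(0)
            f = max(fo, fe)
            F = f
            bjc = b[j - 1]
            s = hdiag + (match if (ai == bjc and ai < 4) else mismatch)
            hdiag = Hprev[j]
            h = max(0.0, s, e, f)
            src = np.uint8(0)
            if h > 0.0:
                if h == s:
                    src = np.uint8(1)
                elif h == e:
                    src = np.uint8(2)
                else:
                    src = np.uint8(3)
            Hcur[j] = h
            trow[j - off] = src | eflag | fflag
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
    return best, bi, bj


@njit(cache=True)
def _tb_banded(tb, bi, bj, dlo, ops):
    i = bi
    j = bj
    k = 0
    state = 0
    dmin = bj - bi
    dmax = bj - bi
    while i > 0 and j > 0:
        v = tb[i - 1, j - (i + dlo)]
        if state == 0:
            src = v & 3
            if src == 0:
                break
            if src == 1:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            extended = v & 4
            i -= 1
            if not extended:
                state = 0
        else:
            ops[k] = 2
            k += 1
            extended = v & 8
            j -= 1
            if not extended:
                state = 0
        d = j - i
        if d < dmin:
            dmin = d
        if d > dmax:
            dmax = d
    return i, j, k, dmin, dmax


@dataclass
class LocalAlignment:
    """A gapped local alignment between two sequences.

    Coordinates are 0-based half-open into the original (ungapped) inputs.
    ``a_row``/``b_row`` are equal-length gapped strings.
    """

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_row: str
    b_row: str

    @property
    def n_columns(self) -> int:
        return len(self.a_row)

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for x, y in zip(self.a_row, self.b_row)
            if x == y and x not in "-N"
        )

    @property
    def identity(self) -> float:
        """Matches over all alignment columns, gap columns included."""
        if self.n_columns == 0:
            return 0.0
        return self.n_matches / self.n_columns


def _rows_from_ops(a: str, b: str, si: int, sj: int, ops: np.ndarray) -> tuple[str, str]:
    ra: list[str] = []
    rb: list[str] = []
    i, j = si, sj
    for op in ops[::-1]:
        if op == 0:
            ra.append(a[i])
            rb.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            ra.append(a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(b[j])
            j += 1
    return "".join(ra), "".join(rb)


def smith_waterman(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 30.0,
    gap_ext: float = 0.1,
) -> LocalAlignment:
    """Exact full-DP affine Smith-Waterman with traceback."""
    ac = encode(a)
    bc = encode(b)
    n, m = len(ac), len(bc)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    tb = np.empty((n, m), np.uint8)
    score, bi, bj = _sw_full(ac, bc, match, mismatch, gap_open, gap_ext, tb)
    if score <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    ops = np.empty(n + m, np.int8)
    si, sj, k = _tb_full(tb, bi, bj, ops)
    ra, rb = _rows_from_ops(a, b, si, sj, ops[:k])
    return LocalAlignment(float(score), si, bi, sj, bj, ra, rb)


def _edlib_diag_range(a: str, b: str) -> tuple[int, int]:
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"] or ""
    qi = ti = 0
    dmin = dmax = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            qi += ln
            ti += ln
        elif ch == "I":  # consumes query
            qi += ln
        else:  # 'D' consumes target
            ti += ln
        d = ti - qi
        dmin = min(dmin, d)
        dmax = max(dmax, d)
    return dmin, dmax


def smith_waterman_banded(
    a: str,
    b: str,
    dlo: int,
    dhi: int,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 30.0,
    gap_ext: float = 0.1,
) -> tuple[LocalAlignment, int, int]:
    """Banded SW; returns (alignment, path_dmin, path_dmax)."""
    ac = encode(a)
    bc = encode(b)
    n, m = len(ac), len(bc)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", ""), 0, 0
    dlo = max(dlo, 1 - n)
    dhi = min(dhi, m - 1)
    width = dhi - dlo + 1
    tb = np.zeros((n, width), np.uint8)
    score, bi, bj = _sw_banded(ac, bc, match, mismatch, gap_open, gap_ext, dlo, dhi, tb)
    if score <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", ""), 0, 0
    ops = np.empty(n + m, np.int8)
    si, sj, k, dmin, dmax = _tb_banded(tb, bi, bj, dlo, ops)
    ra, rb = _rows_from_ops(a, b, si, sj, ops[:k])
    return LocalAlignment(float(score), si, bi, sj, bj, ra, rb), dmin, dmax


def _seed_diag_range(a: str, b: str, k: int = 12, step: int = 4) -> tuple[int, int] | None:
    """Diagonal range (b_pos - a_pos) spanned by k-mer seed clusters.

    Homologous blocks between two windows pin the path's diagonals exactly;
    gap transitions between blocks stay within the blocks' diagonal range.
    Returns None when there is no seed support."""
    from ._kmer import KmerIndex, cluster_diagonals

    idx = KmerIndex(b, k=k)
    qpos, tpos = idx.seed_matches(a, step=step)
    clusters = [c for c in cluster_diagonals(qpos, tpos, max_gap=200) if c[2] >= 3]
    if not clusters:
        return None
    return min(c[0] for c in clusters), max(c[1] for c in clusters)


def align_auto(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 30.0,
    gap_ext: float = 0.1,
    full_dp_limit: int = 4_000_000,
    pad: int = 400,
) -> LocalAlignment:
    """Local alignment choosing full or banded DP by problem size.

    Small problems (n*m <= full_dp_limit) run the full DP.  Larger ones run
    the banded DP around the seed-supported diagonal range (unit-cost
    optimal path as fallback); the band is widened and the DP re-run while
    the optimal traceback touches a band edge.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    if n * m <= full_dp_limit:
        return smith_waterman(a, b, match, mismatch, gap_open, gap_ext)
    rng = _seed_diag_range(a, b)
    if rng is None:
        rng = _edlib_diag_range(a, b)
    dmin, dmax = rng
    while True:
        dlo = max(dmin - pad, 1 - n)
        dhi = min(dmax + pad, m - 1)
        if (dhi - dlo + 1) * n >= n * m:
            return smith_waterman(a, b, match, mismatch, gap_open, gap_ext)
        aln, pmin, pmax = smith_waterman_banded(
            a, b, dlo, dhi, match, mismatch, gap_open, gap_ext
        )
        lo_ok = pmin > dlo or dlo == 1 - n
        hi_ok = pmax < dhi or dhi == m - 1
        if lo_ok and hi_ok:
            return aln
        pad *= 4


def edlib_identity(a: str, b: str, mode: str = "NW") -> tuple[float, int]:
    """Identity (matches / alignment columns) of the unit-cost optimal
    alignment of ``a`` against ``b``; returns (identity, alignment columns).
    """
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a, b, mode=mode, task="path")
    cigar = res["cigar"] or ""
    cols = 0
    matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        cols += ln
        if ch == "=":
            matches += ln
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols
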