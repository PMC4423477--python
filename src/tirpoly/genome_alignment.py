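"""Whole-genome pairwise anchoring and windowed local alignment.

The query genome is split into 5-kb fragments; each fragment's best target
locus is found by k-mer diagonal voting and kept as an anchor only if it
lies on the same chromosome in the same orientation with >= 96% identity
and is collinear with its neighbours (longest strictly increasing chain).
For every anchor, a 12-kb window (the 5-kb fragment plus 7 kb of adjacent
3' sequence, overlapping the next fragment) is aligned against the
corresponding target window with affine-gap Smith-Waterman (gap open 30,
gap extension 0.1, match +5, mismatch -4), filtered by flanking alignment
quality around candidate indels, and the passing windows are re-assembled
into one global alignment per chromosome.

Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._align import LocalAlignment, align_auto
from ._kmer import KmerIndex, cluster_diagonals
from ._seq import revcomp
from .errors import FormatError

FRAGMENT_BP = 5000
WINDOW_BP = 12000
MIN_ANCHOR_IDENTITY = 0.96


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA assembly into {chromosome: sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


@dataclass
class Anchor:
    """Best target placement of one query fragment."""

    query_chrom: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    identity: float
    orientation: str  # "+" | "-"

    @property
    def fragment(self) -> tuple[int, int]:
        return self.query_start, self.query_end


@dataclass
class WindowAlignment:
    """Local alignment of one 12-kb query window against its target window.

    ``query_row``/``target_row`` are equal-length gapped strings; ungapping
    them reproduces query[query_aln_start:query_aln_end] and
    target[target_aln_start:target_aln_end].
    """

    query_chrom: str
    query_window: tuple[int, int]
    target_chrom: str
    target_window: tuple[int, int]
    score: float
    query_aln_start: int
    query_aln_end: int
    target_aln_start: int
    target_aln_end: int
    query_row: str
    target_row: str
    passes_quality_flag: bool | None = None

    @property
    def n_columns(self) -> int:
        return len(self.query_row)


@dataclass
class AlignedBlock:
    """One contiguous gapped block of the assembled chromosome alignment."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    query_row: str
    target_row: str
    source_windows: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ChromosomeAlignment:
    """Ordered, non-overlapping aligned blocks for one chromosome pair."""

    query_chrom: str
    target_chrom: str
    blocks: list[AlignedBlock] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    @property
    def aligned_query_bp(self) -> int:
        return sum(b.query_end - b.query_start for b in self.blocks)


# ---------------------------------------------------------------------------
# anchoring


def _best_locus(
    fragment: str,
    indexes: dict[str, KmerIndex],
    step: int = 4,
) -> tuple[str, int, int, str] | None:
    """Strongest diagonal cluster over all target chromosomes and strands.

    Returns (chrom, diag_lo, diag_hi, orientation) or None."""
    best = None
    best_votes = 0
    for strand in ("+", "-"):
        frag = fragment if strand == "+" else revcomp(fragment)
        for chrom, idx in indexes.items():
            qpos, tpos = idx.seed_matches(frag, step=step)
            clusters = cluster_diagonals(qpos, tpos, max_gap=400)
            if clusters and clusters[0][2] > best_votes:
                best_votes = clusters[0][2]
                best = (chrom, clusters[0][0], clusters[0][1], strand)
    if best_votes < 5:
        return None
    return best


def _hit_identity(qrow: str, trow: str, big_gap: int = 50) -> tuple[float, int]:
    """Identity over alignment columns outside gap runs longer than
    ``big_gap`` (matches / such columns), plus the column count."""
    n = len(qrow)
    exclude = [False] * n
    for row in (qrow, trow):
        i = 0
        while i < n:
            if row[i] == "-":
                j = i
                while j < n and row[j] == "-":
                    j += 1
                if j - i > big_gap:
                    for t in range(i, j):
                        exclude[t] = True
                i = j
            else:
                i += 1
    cols = 0
    matches = 0
    for i in range(n):
        if exclude[i]:
            continue
        cols += 1
        if qrow[i] == trow[i] and qrow[i] not in "-N":
            matches += 1
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


def fragment_and_anchor(
    query_genome: dict[str, str],
    target_genome: dict[str, str],
    fragment_bp: int = FRAGMENT_BP,
    min_identity: float = MIN_ANCHOR_IDENTITY,
    target_indexes: dict[str, KmerIndex] | None = None,
) -> list[Anchor]:
    """Anchor every query fragment onto the target genome.

    Fragments whose best hit is on another chromosome than their
    neighbours, on the opposite strand, below the identity threshold, or
    off the longest strictly-increasing collinear chain are dropped.
    The last short fragment (< fragment_bp) is anchored like any other.
    """
    if target_indexes is None:
        target_indexes = {c: KmerIndex(s, k=12) for c, s in target_genome.items()}
    anchors: list[Anchor] = []
    for qchrom, qseq in query_genome.items():
        raw: list[Anchor] = []
        for start in range(0, len(qseq), fragment_bp):
            frag = qseq[start : start + fragment_bp]
            if len(frag) < 100:
                continue
            locus = _best_locus(frag, target_indexes)
            if locus is None:
                continue
            chrom, dlo, dhi, strand = locus
            if strand != "+":
                continue  # orientation filter (also drops inversions)
            tseq = target_genome[chrom]
            t0 = max(0, dlo - 200)
            t1 = min(len(tseq), dhi + len(frag) + 200)
            aln = align_auto(frag, tseq[t0:t1])
            if aln.n_columns == 0:
                continue
            # hit identity over aligned columns, excluding polymorphism-scale
            # gap runs (> 50 bp): a fragment containing a large indel still
            # anchors on its matching portion, as separate HSPs would
            ident, aligned_cols = _hit_identity(aln.a_row, aln.b_row)
            if ident < min_identity or aligned_cols < min(1800, 0.35 * len(frag)):
                continue
            raw.append(
                Anchor(
                    qchrom, start, start + len(frag), chrom,
                    t0 + aln.b_start - aln.a_start,
                    t0 + aln.b_start - aln.a_start + len(frag),
                    ident, strand,
                )
            )
        anchors.extend(_collinear_chain(raw))
    return anchors


def _collinear_chain(anchors: list[Anchor]) -> list[Anchor]:
    """Longest strictly increasing chain of target starts per target
    chromosome (query order is construction order)."""
    if not anchors:
        return []
    by_target: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_target.setdefault(a.target_chrom, []).append(a)
    main = max(by_target.values(), key=len)
    # O(n^2) LIS is fine at genome/5kb scale
    n = len(main)
    lengths = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if (
                main[j].target_start < main[i].target_start
                and lengths[j] + 1 > lengths[i]
            ):
                lengths[i] = lengths[j] + 1
                prev[i] = j
    best_i = max(range(n), key=lambda i: lengths[i])
    chain = []
    i = best_i
    while i != -1:
        chain.append(main[i])
        i = prev[i]
    return chain[::-1]


# ---------------------------------------------------------------------------
# window alignment


def align_window(
    query_window: str,
    target_window: str,
    gap_open: float = 30.0,
    gap_ext: float = 0.1,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two windows.

    Ns score as mismatches against everything; a window of all Ns yields an
    empty alignment with score 0.  Exactness is the contract: small inputs
    run the full quadratic DP, large windows run a banded DP whose band is
    widened until the optimal traceback clears it.
    """
    return align_auto(
        query_window, target_window,
        match=match, mismatch=mismatch, gap_open=gap_open, gap_ext=gap_ext,
    )


def _column_flags(qrow: str, trow: str) -> tuple[list[bool], list[bool]]:
    """(is_aligned_column, is_match) per column."""
    aligned = []
    matches = []
    for x, y in zip(qrow, trow):
        al = x != "-" and y != "-"
        aligned.append(al)
        matches.append(al and x == y and x != "N")
    return aligned, matches


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal '-' runs as half-open column intervals."""
    runs = []
    i = 0
    n = len(row)
    while i < n:
        if row[i] == "-":
            j = i
            while j < n and row[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _flank_ok(
    aligned: list[bool],
    matches: list[bool],
    start: int,
    direction: int,
    flank_bp: int,
    min_identity: float,
    max_small_gap: int = 10,
) -> bool:
    """Walk outward from ``start`` collecting aligned columns.

    Gap runs of <= max_small_gap columns are skipped (background-scale
    indels); a longer gap run or the window edge ends the walk.  Passes
    when >= flank_bp aligned columns are collected and the match fraction
    over the first flank_bp of them exceeds min_identity.
    """
    got = 0
    matched = 0
    i = start
    gap_run = 0
    n = len(aligned)
    while 0 <= i < n and got < flank_bp:
        if aligned[i]:
            gap_run = 0
            got += 1
            if matches[i]:
                matched += 1
        else:
            gap_run += 1
            if gap_run > max_small_gap:
                break
        i += direction
    return got >= flank_bp and matched / flank_bp > min_identity


def _run_borders_n(qrow: str, trow: str, s: int, e: int, probe: int = 25) -> bool:
    """True when a gap run sits next to (or across from) an assembly-gap N
    run; such events are discarded by the dedicated N filter downstream and
    must not fail the whole window here."""
    lo = max(0, s - probe)
    hi = min(len(qrow), e + probe)
    return "N" in qrow[lo:hi] or "N" in trow[lo:hi]


def passes_quality(
    wa: WindowAlignment,
    flank_bp: int = 200,
    min_flank_identity: float = 0.90,
    indel_min: int = 50,
) -> bool:
    """Alignment-quality filter around candidate indels.

    True iff every gap run longer than ``indel_min`` is flanked on both
    sides by >= flank_bp aligned columns matching at > min_flank_identity,
    and the alignment contains at least flank_bp such columns at all.
    """
    aligned, matches = _column_flags(wa.query_row, wa.target_row)
    if sum(aligned) < flank_bp:
        return False
    regions = _candidate_regions(wa.query_row, wa.target_row, indel_min)
    for s, e in regions:
        if not _flank_ok(aligned, matches, s - 1, -1, flank_bp, min_flank_identity):
            return False
        if not _flank_ok(aligned, matches, e, +1, flank_bp, min_flank_identity):
            return False
    return True


def _candidate_regions(
    qrow: str, trow: str, indel_min: int = 50, merge_cols: int = 150
) -> list[tuple[int, int]]:
    """Candidate indel regions: gap runs merged when near each other (an
    excised TE next to its filler DNA gaps the opposite row), kept when
    they contain a run longer than indel_min and do not border an N run
    (N-adjacent events are discarded by the dedicated downstream filter).
    """
    all_runs = sorted(r for row in (qrow, trow) for r in _gap_runs(row))
    merged: list[list[int]] = []
    for s, e in all_runs:
        if merged and s - merged[-1][1] <= merge_cols:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        (s, e)
        for s, e in merged
        if any(rs >= s and re_ <= e and re_ - rs > indel_min for rs, re_ in all_runs)
        and not _run_borders_n(qrow, trow, s, e)
    ]


def _truncate_window(wa: WindowAlignment, col_start: int, col_end: int) -> WindowAlignment:
    """Restrict a window alignment to the column range [col_start, col_end)."""
    q_cut_front = sum(1 for x in wa.query_row[:col_start] if x != "-")
    t_cut_front = sum(1 for y in wa.target_row[:col_start] if y != "-")
    q_keep = sum(1 for x in wa.query_row[col_start:col_end] if x != "-")
    t_keep = sum(1 for y in wa.target_row[col_start:col_end] if y != "-")
    return WindowAlignment(
        wa.query_chrom, wa.query_window, wa.target_chrom, wa.target_window,
        wa.score,
        wa.query_aln_start + q_cut_front,
        wa.query_aln_start + q_cut_front + q_keep,
        wa.target_aln_start + t_cut_front,
        wa.target_aln_start + t_cut_front + t_keep,
        wa.query_row[col_start:col_end],
        wa.target_row[col_start:col_end],
    )


def quality_trim(
    wa: WindowAlignment,
    flank_bp: int = 200,
    min_flank_identity: float = 0.90,
    indel_min: int = 50,
) -> WindowAlignment | None:
    """Apply the flank-quality rule, trimming failing edge regions.

    An indel too close to a window edge cannot show a 200-bp flank there,
    but the 7-kb window overlap guarantees the neighbouring window sees it
    mid-window; the edge region is cut off rather than the whole window
    discarded.  A mid-window failure discards the window (returns None).
    """
    aligned, matches = _column_flags(wa.query_row, wa.target_row)
    if sum(aligned) < flank_bp:
        return None
    lo = 0
    hi = len(wa.query_row)
    for s, e in _candidate_regions(wa.query_row, wa.target_row, indel_min):
        left_ok = _flank_ok(aligned, matches, s - 1, -1, flank_bp, min_flank_identity)
        right_ok = _flank_ok(aligned, matches, e, +1, flank_bp, min_flank_identity)
        if left_ok and right_ok:
            continue
        near_left = sum(aligned[:s]) < flank_bp + 50
        near_right = sum(aligned[e:]) < flank_bp + 50
        if not right_ok and near_right:
            hi = min(hi, s)
        elif not left_ok and near_left:
            lo = max(lo, e)
        else:
            return None
    if lo >= hi:
        return None
    if lo == 0 and hi == len(wa.query_row):
        wa.passes_quality_flag = True
        return wa
    out = _truncate_window(wa, lo, hi)
    out.passes_quality_flag = True
    return out


def align_anchored_windows(
    query_genome: dict[str, str],
    target_genome: dict[str, str],
    anchors: list[Anchor],
    window_bp: int = WINDOW_BP,
    target_margin: int = 3000,
) -> list[WindowAlignment]:
    """Align the 12-kb window of every anchor.

    The target window gets an extra margin so sequence private to the
    target remains alignable at the window tail."""
    out: list[WindowAlignment] = []
    for a in anchors:
        qseq = query_genome[a.query_chrom]
        tseq = target_genome[a.target_chrom]
        q0 = a.query_start
        q1 = min(len(qseq), q0 + window_bp)
        t0 = max(0, a.target_start - 200)
        t1 = min(len(tseq), a.target_start + window_bp + target_margin)
        aln = align_window(qseq[q0:q1], tseq[t0:t1])
        if aln.n_columns == 0:
            continue
        wa = WindowAlignment(
            a.query_chrom, (q0, q1), a.target_chrom, (t0, t1),
            aln.score,
            q0 + aln.a_start, q0 + aln.a_end,
            t0 + aln.b_start, t0 + aln.b_end,
            aln.a_row, aln.b_row,
        )
        trimmed = quality_trim(wa)
        if trimmed is None:
            wa.passes_quality_flag = False
            out.append(wa)
        else:
            out.append(trimmed)
    return out


# ---------------------------------------------------------------------------
# assembly


def _window_columns(wa: WindowAlignment):
    """Yield (col_index, qpos, tpos) with positions of the consumed bases
    (or -1 when the row has a gap in that column)."""
    q = wa.query_aln_start
    t = wa.target_aln_start
    for i, (x, y) in enumerate(zip(wa.query_row, wa.target_row)):
        qp = q if x != "-" else -1
        tp = t if y != "-" else -1
        yield i, qp, tp
        if x != "-":
            q += 1
        if y != "-":
            t += 1


def _find_seam(wa: WindowAlignment, q_end: int, seam_run: int = 20):
    """Last column of a clean run (>= seam_run consecutive matching
    columns) whose query position is below ``q_end``.

    Returns (column, query_pos, target_pos) or None.  Cutting overlapping
    windows only inside such runs guarantees the seam never lands inside
    or next to an indel, so no event is split across blocks."""
    qp = wa.query_aln_start
    tp = wa.target_aln_start
    run = 0
    best = None
    for i, (x, y) in enumerate(zip(wa.query_row, wa.target_row)):
        if x != "-" and y != "-" and x == y and x != "N":
            run += 1
            if run >= seam_run and qp < q_end - 1:
                best = (i, qp, tp)
        else:
            run = 0
        if x != "-":
            qp += 1
        if y != "-":
            tp += 1
    return best


def _truncate_block_to_query(block: AlignedBlock, jq: int) -> int | None:
    """Cut a block so its last consumed query base is ``jq``; returns the
    block's new target_end, or None when jq is not a consumed base."""
    q = block.query_end
    t = block.target_end
    for i in range(len(block.query_row) - 1, -1, -1):
        if block.query_row[i] != "-":
            q -= 1
        if block.target_row[i] != "-":
            t -= 1
        if q == jq and block.query_row[i] != "-":
            block.query_row = block.query_row[: i + 1]
            block.target_row = block.target_row[: i + 1]
            block.query_end = jq + 1
            block.target_end = t + (1 if block.target_row[i] != "-" else 0)
            return block.target_end
        if q < jq:
            break
    return None


def assemble_chromosome(
    windows: list[WindowAlignment],
    max_target_jump: int = 10_000,
) -> ChromosomeAlignment:
    """Assemble passing overlapping windows into one chromosome alignment.

    Windows are consumed in query order.  Where a window overlaps the
    alignment assembled so far, a seam is placed inside a clean run of
    matching columns that both sides agree on; the previous content is cut
    back to the seam and the window contributes everything after it, so
    every query position appears exactly once and no indel is ever split
    across a seam.  Windows whose target placement disagrees with the
    running alignment by more than ``max_target_jump`` at the seam are
    dropped and the conflict logged.
    """
    if not windows:
        return ChromosomeAlignment("", "")
    windows = sorted(
        (w for w in windows if w.passes_quality_flag is not False),
        key=lambda w: w.query_window[0],
    )
    ca = ChromosomeAlignment(windows[0].query_chrom, windows[0].target_chrom)
    q_end = -1
    t_end = -1

    def append_from(wa: WindowAlignment, col0: int, qp0: int, tp0: int):
        nonlocal q_end, t_end
        qrow = wa.query_row[col0:]
        trow = wa.target_row[col0:]
        nq = sum(1 for x in qrow if x != "-")
        nt = sum(1 for y in trow if y != "-")
        if nq == 0 and nt == 0:
            return
        contiguous = (
            ca.blocks
            and qp0 == ca.blocks[-1].query_end
            and tp0 == ca.blocks[-1].target_end
        )
        if contiguous:
            b = ca.blocks[-1]
            b.query_row += qrow
            b.target_row += trow
            b.query_end += nq
            b.target_end += nt
            b.source_windows.append(wa.query_window)
        else:
            ca.blocks.append(
                AlignedBlock(qp0, qp0 + nq, tp0, tp0 + nt, qrow, trow,
                             [wa.query_window])
            )
        q_end = qp0 + nq
        t_end = tp0 + nt

    for wa in windows:
        if wa.query_aln_end <= q_end + 1:
            continue  # fully covered already
        if not ca.blocks or wa.query_aln_start >= q_end:
            # no overlap with assembled content: new block from the start
            append_from(wa, 0, wa.query_aln_start, wa.target_aln_start)
            continue
        seam = _find_seam(wa, q_end)
        if seam is None:
            ca.conflicts.append(
                f"window {wa.query_window}: no clean seam with previous "
                f"coverage; window dropped"
            )
            continue
        col, jq, jt = seam
        block = ca.blocks[-1]
        if jq < block.query_start:
            ca.conflicts.append(
                f"window {wa.query_window}: seam {jq} precedes the previous "
                f"block; window dropped"
            )
            continue
        prev_t_end = _truncate_block_to_query(block, jq)
        if prev_t_end is None:
            ca.conflicts.append(
                f"window {wa.query_window}: query {jq} absent from the "
                f"previous block (unaligned there); window dropped"
            )
            continue
        disagreement = (jt + 1) - prev_t_end
        if abs(disagreement) > max_target_jump:
            ca.conflicts.append(
                f"window {wa.query_window}: target disagreement "
                f"{disagreement} bp at query {jq}; window dropped"
            )
            q_end = block.query_end
            t_end = block.target_end
            continue
        if disagreement != 0:
            ca.conflicts.append(
                f"window {wa.query_window}: target offset {disagreement} bp "
                f"at query seam {jq}; new block started"
            )
        q_end = block.query_end
        t_end = block.target_end
        append_from(wa, col + 1, jq + 1, jt + 1)
    return ca


def align_genomes(
    query_genome: dict[str, str],
    target_genome: dict[str, str],
    fragment_bp: int = FRAGMENT_BP,
    window_bp: int = WINDOW_BP,
    min_identity: float = MIN_ANCHOR_IDENTITY,
) -> dict[tuple[str, str], ChromosomeAlignment]:
    """Full anchoring + window alignment + assembly, per chromosome pair."""
    indexes = {c: KmerIndex(s, k=12) for c, s in target_genome.items()}
    anchors = fragment_and_anchor(
        query_genome, target_genome, fragment_bp, min_identity, indexes
    )
    out: dict[tuple[str, str], ChromosomeAlignment] = {}
    pairs: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        pairs.setdefault((a.query_chrom, a.target_chrom), []).append(a)
    for key, alist in pairs.items():
        windows = align_anchored_windows(
            query_genome, target_genome, alist, window_bp
        )
        ca = assemble_chromosome([w for w in windows if w.passes_quality_flag])
        ca.query_chrom, ca.target_chrom = key
        out[key] = ca
    return out


def write_block_table(
    alignments: dict[tuple[str, str], ChromosomeAlignment], path: str | Path
) -> None:
    """Tab-delimited block table: intervals in both genomes + gapped rows."""
    with open(path, "w") as fh:
        fh.write(
            "query_chrom\tquery_start\tquery_end\ttarget_chrom\t"
            "target_start\ttarget_end\tquery_row\ttarget_row\n"
        )
        for (qc, tc), ca in alignments.items():
            for b in ca.blocks:
                fh.write(
                    f"{qc}\t{b.query_start}\t{b.query_end}\t{tc}\t"
                    f"{b.target_start}\t{b.target_end}\t{b.query_row}\t{b.target_row}\n"
                )
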