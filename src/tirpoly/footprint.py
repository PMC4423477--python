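"""Classification of TE-homologous presence/absence events.

For every event carrying TE homology the classifier reconstructs the local
situation in both genomes and decides, in order: insertion, perfect
excision, excision with flanking deletion, excision with filler DNA,
excision with both, internal deletion (not transposition), or unclear.

The decisive observables come from a junction reconstruction: the TE body
(annotation borders, snapped onto the TSD pair) is excised in silico from
the bearing species and the remainder is aligned against the empty site.
Bases of the bearing flanks missing at the empty site beyond the one
expected TSD copy are flanking deletion; empty-site bases aligning to
neither the TE nor the bearing flanks are filler DNA.  A precise excision
(TE plus one TSD removed) restores the pre-insertion site and is
deliberately reported as an insertion in the other species — comparative
analysis cannot distinguish the two.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._align import align_auto, smith_waterman, smith_waterman_banded
from ._kmer import KmerIndex, cluster_diagonals
from .errors import ContractError
from .indel_detection import IndelEvent
from .te_model import SUPERFAMILY_PROFILES, TEAnnotation, TELibrary, annotate_segment

VERDICTS = (
    "insertion",
    "excision-perfect",
    "excision-deletion",
    "excision-filler",
    "excision-both",
    "internal-deletion",
    "unclear",
)


@dataclass
class TSDCall:
    """Outcome of the target-site-duplication test at the TE borders."""

    found: bool
    sequence: str = ""
    length: int = 0
    sides: str = "none"  # both | bearing-only | empty-only | none
    mismatches: int = 0
    te_start: int = 0  # TSD-snapped TE borders in the bearing genome
    te_end: int = 0
    reason: str = ""


@dataclass
class PolymorphismCall:
    event: IndelEvent
    family: str
    superfamily: str
    verdict: str
    acting_species: str
    tsd: TSDCall
    deleted_bp: int = 0
    filler_bp: int = 0
    filler_sequence: str = ""
    identity: float = 0.0

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ContractError(f"unknown verdict {self.verdict!r}")


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def detect_tsd(
    event: IndelEvent,
    te: TEAnnotation,
    profile,
    bearing_seq: str,
    border_slack: int = 3,
    max_mismatch_long: int = 1,
    skip_internal_check: bool = False,
) -> TSDCall:
    """Test for the profile-length duplication flanking the TE body.

    The annotation borders are allowed to shift by up to ``border_slack``
    bp to absorb consensus-edge fuzz; the shift maximising TSD agreement
    wins.  Fixed motifs (TA; TAA/TTA) must match exactly and match the
    motif; variable motifs of length >= 8 tolerate ``max_mismatch_long``
    mismatch between the two copies.  TE borders farther than border_slack
    from the event borders yield a no-TSD result with reason "internal".
    """
    k = profile.tsd_length
    te_s = event.start + te.start
    te_e = event.start + te.end
    # a TE continuing well into both flanks is not a transposition locus
    # (classify_polymorphism resolves this case itself and sets the flag)
    slack = max(k + border_slack, 20)
    if (
        not skip_internal_check
        and te_s < event.start - slack
        and te_e > event.end + slack
    ):
        return TSDCall(False, reason="internal", te_start=te_s, te_end=te_e)
    allowed = max_mismatch_long if (not profile.tsd_motifs and k >= 8) else 0
    best: TSDCall | None = None
    for ds in range(-border_slack, border_slack + 1):
        for de in range(-border_slack, border_slack + 1):
            s = te_s + ds
            e = te_e + de
            left = bearing_seq[s - k : s]
            right = bearing_seq[e : e + k]
            if len(left) < k or len(right) < k or "N" in left or "N" in right:
                continue
            mm = _mismatches(left, right)
            if mm > allowed:
                continue
            if profile.tsd_motifs and left not in profile.tsd_motifs:
                continue
            cand = TSDCall(
                True, left, k, "bearing-only", mm, te_start=s, te_end=e
            )
            if best is None or (mm, abs(ds) + abs(de)) < (
                best.mismatches,
                abs(best.te_start - te_s) + abs(best.te_end - te_e),
            ):
                best = cand
    if best is None:
        return TSDCall(False, reason="no duplication at the TE borders",
                       te_start=te_s, te_end=te_e)
    return best


@dataclass
class JunctionAnalysis:
    """In-silico excision of the TE from the bearing locus, aligned to the
    empty site."""

    covered: bool  # alignment spans the junction
    deleted_total: int = 0  # bearing bases missing at the empty site
    filler_total: int = 0  # empty-site bases matching neither flank
    filler_sequence: str = ""
    left_identity: float = 0.0  # flank alignment identity next to junction
    right_identity: float = 0.0


def _anchor_flank(flank: str, co: str, seed_k: int = 12, band_pad: int = 120):
    """Locate one bearing flank in the empty-site context.

    Seed-guided and banded: exact k-mer seeds pick the homologous diagonal
    and the DP is confined to it, so an unrelated flank portion (e.g. one
    lying inside a large flanking deletion) cannot accrete a spurious
    alignment by chaining chance matches across cheap gaps."""
    if not flank or not co:
        return None
    idx = KmerIndex(co, k=seed_k)
    qpos, tpos = idx.seed_matches(flank)
    clusters = [c for c in cluster_diagonals(qpos, tpos, max_gap=120) if c[2] >= 2]
    if not clusters:
        return None
    dlo, dhi, _ = clusters[0]
    aln, _, _ = smith_waterman_banded(flank, co, dlo - band_pad, dhi + band_pad)
    return aln if aln.n_columns else None


def _co_pos_at(aln, a_target: int, side: str) -> int | None:
    """CO position aligned to query offset ``a_target`` in a flank
    alignment (side 'left': first aligned column at/after the offset;
    'right': last aligned column before it, +1)."""
    ap = aln.a_start
    bp = aln.b_start
    best = None
    for x, y in zip(aln.a_row, aln.b_row):
        both = x != "-" and y != "-"
        if both:
            if side == "left" and ap >= a_target:
                return bp
            if side == "right" and ap < a_target:
                best = bp + 1
        if x != "-":
            ap += 1
        if y != "-":
            bp += 1
    return best


def _strip_junk_edges(segments: list[list], max_strip: int = 40) -> list[list]:
    """Split mismatch-dominated edges off aligned stretches next to gaps.

    An affine aligner pairs a small filler against deleted flank bases
    rather than opening a second gap; those spurious columns sit at the
    gap-adjacent edge of an otherwise clean aligned stretch.  The longest
    edge prefix/suffix with <= 50% matches (ending in a mismatch) becomes a
    junk ('J') segment counted on both sides of the footprint."""
    out: list[list] = []
    n = len(segments)
    for i, seg in enumerate(segments):
        if seg[0] != "A" or seg[4] <= 25:
            # short aligned islands are handled by the chain absorber
            out.append(seg)
            continue
        flags = seg[6]
        text = seg[3]
        lo, hi = seg[1], seg[2]
        gap_before = i > 0 and segments[i - 1][0] in ("D", "F")
        gap_after = i + 1 < n and segments[i + 1][0] in ("D", "F")
        p = 0
        if gap_before:
            best = 0
            m = 0
            for j in range(min(max_strip, len(flags))):
                m += flags[j]
                if not flags[j] and m <= 0.5 * (j + 1):
                    best = j + 1
            p = best
        q = 0
        if gap_after:
            best = 0
            m = 0
            for j in range(min(max_strip, len(flags) - p)):
                idx = len(flags) - 1 - j
                m += flags[idx]
                if not flags[idx] and m <= 0.5 * (j + 1):
                    best = j + 1
            q = best
        if p:
            out.append(["J", lo, lo + p, text[:p], p, sum(flags[:p]), flags[:p]])
        core = ["A", lo + p, hi - q, text[p : len(text) - q if q else len(text)],
                len(flags) - p - q, sum(flags[p : len(flags) - q if q else len(flags)]),
                flags[p : len(flags) - q if q else len(flags)]]
        if core[4] > 0:
            out.append(core)
        if q:
            out.append(["J", hi - q, hi, text[len(text) - q :], q,
                        sum(flags[len(flags) - q :]), flags[len(flags) - q :]])
    return out


def _analyse_junction(
    bearing_seq: str,
    other_seq: str,
    te_s: int,
    te_e: int,
    empty_pos: int,
    k: int,
    window: int = 700,
    max_window: int = 3600,
    strip_edges: bool = False,
) -> JunctionAnalysis:
    """Two-step junction reconstruction.

    Each bearing flank is first anchored independently in the empty-site
    context (separate local alignments cannot bridge junk across the
    junction), escalating the flank window when a large deletion leaves the
    junction-adjacent portion unaligned.  A small exact full-DP alignment
    of the in-silico excised junction neighbourhood then yields the
    deleted/filler bases: gap runs chained across short noisy islands and
    intersecting the junction window count as deleted (bearing side) or
    filler (empty-site side).
    """
    W = window
    while True:
        co0 = max(0, empty_pos - W - 300)
        co = other_seq[co0 : empty_pos + W + 300]
        lb = bearing_seq[max(0, te_s - W) : te_s]
        rb = bearing_seq[te_e : te_e + W]
        if not co or (not lb and not rb):
            return JunctionAnalysis(False)
        aln_l = _anchor_flank(lb, co)
        aln_r = _anchor_flank(rb, co)
        lb_un = len(lb) - (aln_l.a_end if aln_l else 0)
        rb_un = aln_r.a_start if aln_r else 0

        def _good(aln, flank_len):
            return (
                aln is not None
                and (aln.a_end - aln.a_start) >= min(200, flank_len)
                and aln.identity >= 0.85
            )

        # escalate when a flank failed to anchor substantially (its whole
        # window may lie inside a large flanking deletion) or its unaligned
        # junction-side portion may extend beyond the window
        if W < max_window and (
            (lb and not _good(aln_l, len(lb)))
            or (rb and not _good(aln_r, len(rb)))
            or lb_un > W - 300
            or rb_un > W - 300
        ):
            W = max_window
            continue
        if (lb and not _good(aln_l, len(lb))) or (rb and not _good(aln_r, len(rb))):
            return JunctionAnalysis(False)
        break
    pad_l = min(len(lb), 250 + lb_un)
    pad_r = min(len(rb), 250 + rb_un)
    co_l0 = _co_pos_at(aln_l, len(lb) - pad_l, "left") if aln_l else None
    co_r1 = _co_pos_at(aln_r, pad_r, "right") if aln_r else None
    if co_l0 is None or co_r1 is None or co_r1 <= co_l0:
        # flanks did not anchor cleanly around the junction
        return JunctionAnalysis(False)
    bj = lb[len(lb) - pad_l :] + rb[:pad_r]
    jn = pad_l
    coj = co[co_l0:co_r1]
    aln = smith_waterman(bj, coj)
    if aln.n_columns == 0:
        return JunctionAnalysis(False)
    jwin_lo = jn - (k + 12)
    jwin_hi = jn + (k + 12)
    if aln.a_start > max(0, jwin_lo) or aln.a_end < min(len(bj), jwin_hi):
        return JunctionAnalysis(False)
    # walk columns into alternating segments: D (gap in empty site),
    # F (gap in bearing side), A (aligned stretch with per-column flags)
    bpos = aln.a_start
    col_match: list[tuple[int, bool]] = []
    segments: list[list] = []  # [kind, bj_lo, bj_hi, co_text, n_cols, n_match, flags]
    for x, y in zip(aln.a_row, aln.b_row):
        if x != "-" and y != "-":
            ismatch = x == y and x != "N"
            col_match.append((bpos, ismatch))
            if segments and segments[-1][0] == "A":
                segments[-1][2] = bpos + 1
                segments[-1][3] += y
                segments[-1][4] += 1
                segments[-1][5] += ismatch
                segments[-1][6].append(ismatch)
            else:
                segments.append(["A", bpos, bpos + 1, y, 1, int(ismatch), [ismatch]])
            bpos += 1
        elif y == "-":
            if segments and segments[-1][0] == "D":
                segments[-1][2] = bpos + 1
            else:
                segments.append(["D", bpos, bpos + 1, "", 0, 0, []])
            bpos += 1
        else:
            if segments and segments[-1][0] == "F":
                segments[-1][3] += y
            else:
                segments.append(["F", bpos, bpos, y, 0, 0, []])
    if strip_edges:
        segments = _strip_junk_edges(segments)
    # chain gap segments across short aligned bridges sandwiched between
    # gaps: the aligner bridges a small filler against deleted flank bases
    # whenever that saves a gap-open, and it cherry-picks the best-matching
    # offset, so a sandwiched island's pairing is spurious regardless of
    # its match fraction; its columns count on both sides.  Long aligned
    # stretches are genuine flank and always break the chain.
    def junky(i: int) -> bool:
        seg = segments[i]
        if seg[0] == "J":
            return True
        if seg[0] != "A" or seg[4] > 25:
            return False
        prev_gap = i > 0 and segments[i - 1][0] in ("D", "F", "J")
        next_gap = i + 1 < len(segments) and segments[i + 1][0] in ("D", "F", "J")
        return prev_gap and next_gap

    regions: list[list] = []
    for i, seg in enumerate(segments):
        if seg[0] == "A" and not junky(i):
            regions.append(None)  # chain breaker
            continue
        if regions and regions[-1] is not None:
            regions[-1].append(seg)
        else:
            if regions and regions[-1] is None:
                regions.pop()
            regions.append([seg])
    deleted = 0
    filler_seq = ""
    for reg in regions:
        if reg is None:
            continue
        gap_segs = [s for s in reg if s[0] != "A"]
        if not gap_segs:
            continue
        lo = min(s[1] for s in reg)
        hi = max(s[2] for s in reg)
        if lo < jwin_hi and hi > jwin_lo:
            # bearing bases in the region = D gaps + junk bridges;
            # empty-site bases = F gaps + junk bridges
            deleted += sum(s[2] - s[1] for s in reg if s[0] in ("D", "A", "J"))
            filler_seq += "".join(s[3] for s in reg if s[0] in ("F", "A", "J"))
    left_cols = [m for p, m in col_match if jn - 60 <= p < jn]
    right_cols = [m for p, m in col_match if jn <= p < jn + 60]
    li = sum(left_cols) / len(left_cols) if left_cols else 0.0
    ri = sum(right_cols) / len(right_cols) if right_cols else 0.0
    return JunctionAnalysis(True, deleted, len(filler_seq), filler_seq, li, ri)


def measure_footprint(
    junction: JunctionAnalysis, tsd_length: int
) -> tuple[int, int, str]:
    """(deleted_bp, filler_bp, filler_sequence) from a junction analysis.

    The one TSD copy expected to be redundant at the empty site is not
    counted as deleted flank."""
    deleted = max(0, junction.deleted_total - tsd_length)
    return deleted, junction.filler_total, junction.filler_sequence


def _filler_is_local_echo(
    filler: str, bearing_seq: str, te_s: int, te_e: int, pad: int = 200
) -> bool:
    """True when the putative filler aligns at >= 80% identity to the
    bearing-species flanks (alignment jitter, not foreign DNA).

    Short segments are exempt: a spurious 80% match of a few bp to a
    400-bp flank is expected by chance, while junction-window jitter that
    matters produces longer echoes."""
    if len(filler) < 20:
        return False
    ctx = bearing_seq[max(0, te_s - pad) : te_s] + bearing_seq[te_e : te_e + pad]
    aln = align_auto(filler, ctx)
    if aln.n_columns == 0:
        return False
    return (
        aln.identity >= 0.80
        and (aln.a_end - aln.a_start) >= 0.8 * len(filler)
    )


def _covers_both_termini(
    extra: str, ann: TEAnnotation, context: "ClassificationContext",
    edge_bp: int = 15,
) -> bool:
    """Does the empty-site extra sequence retain both termini of the
    annotated family's consensus (the signature of an internally deleted
    but still present element)?"""
    fam = context.library[ann.family_name]
    hits = annotate_segment(extra, context.library)
    mine = [h for h in hits if h.family_name == ann.family_name]
    if not mine:
        return False
    lo = min(h.consensus_start for h in mine)
    hi = max(h.consensus_end for h in mine)
    return lo <= edge_bp and hi >= len(fam.sequence) - edge_bp


@dataclass
class ClassificationContext:
    """Genome access for both species, keyed by species then chromosome."""

    genomes: dict[str, dict[str, str]]
    library: TELibrary

    def bearing_seq(self, ev: IndelEvent) -> str:
        chrom = ev.query_chrom if ev.bearing_species == "A" else ev.target_chrom
        return self.genomes[ev.bearing_species][chrom]

    def other_seq(self, ev: IndelEvent) -> str:
        other = "B" if ev.bearing_species == "A" else "A"
        chrom = ev.target_chrom if ev.bearing_species == "A" else ev.query_chrom
        return self.genomes[other][chrom]


def classify_polymorphism(
    event: IndelEvent,
    annotations: list[TEAnnotation],
    context: ClassificationContext,
    border_slack: int = 3,
    min_te_coverage: float = 0.80,
) -> PolymorphismCall:
    """Decide the verdict for one TE-homologous event (decision tree,
    first match wins: insertion, excision-perfect, excision-deletion,
    excision-filler, excision-both, internal-deletion, unclear)."""
    if not annotations:
        raise ContractError(
            "classify_polymorphism requires >= 1 TE annotation; pre-filter events"
        )
    ann = annotations[0]
    profile = SUPERFAMILY_PROFILES[ann.superfamily]
    k = profile.tsd_length
    gB = context.bearing_seq(event)
    gO = context.other_seq(event)
    other_species = "B" if event.bearing_species == "A" else "A"

    def call(verdict, acting, tsd, deleted=0, filler=0, filler_seq=""):
        return PolymorphismCall(
            event, ann.family_name, ann.superfamily, verdict, acting, tsd,
            deleted, filler, filler_seq, identity=ann.identity,
        )

    # (6) first, geometrically: borders strictly inside a TE that continues
    # into both flanks suggest an internal deletion rather than
    # transposition.  The counter-case is an excision whose filler DNA is
    # itself a fragment of the same family: the window aligner then pairs
    # the filler with the element body and fragments the gap run, so the
    # annotation also overhangs both event borders.  The discriminator is
    # terminal retention: after an internal deletion the OTHER species
    # still carries both element termini; after an excision it does not.
    te_s = event.start + ann.start
    te_e = event.start + ann.end
    slack_in = max(k + 2 * border_slack, 20)
    if ann.start < -slack_in and ann.end > event.length + slack_in:
        tsd_int = TSDCall(False, reason="internal", te_start=te_s, te_end=te_e)
        j0 = _analyse_junction(gB, gO, te_s, te_e, event.empty_site_position, k)
        extra = j0.filler_sequence if j0.covered else ""
        # an internally deleted element retains >= ~100 bp including both
        # termini at the other locus; a short extra segment cannot be one
        if (
            not j0.covered
            or len(extra) > 160
            or (len(extra) >= 50 and _covers_both_termini(extra, ann, context))
        ):
            return call("internal-deletion", other_species, tsd_int)
        # the whole element is gone from the empty site: treat the
        # annotation borders as the element borders and classify normally

    # TE must essentially span the event, or share a precise border with it
    ov = min(event.length, ann.end) - max(0, ann.start)
    spans = ov >= min_te_coverage * event.length
    border_match = (
        abs(ann.start) <= k + border_slack
        or abs(ann.end - event.length) <= k + border_slack
    )
    if not spans and not (border_match and ov >= 0.5 * ann.span):
        tsd = TSDCall(False, reason="poor TE coverage", te_start=te_s, te_end=te_e)
        return call("unclear", other_species, tsd)

    tsd = detect_tsd(
        event, ann, profile, gB, border_slack=border_slack,
        skip_internal_check=True,
    )
    if not tsd.found:
        return call("unclear", other_species, tsd)

    raw = _analyse_junction(
        gB, gO, tsd.te_start, tsd.te_end, event.empty_site_position, k
    )
    if not raw.covered:
        tsd.reason = "empty site not alignable"
        return call("unclear", other_species, tsd)
    raw_continuity = raw.left_identity >= 0.90 and raw.right_identity >= 0.90
    if raw.filler_total == 0 and raw_continuity:
        # crisp signatures take the raw analysis: exactly the one redundant
        # TSD copy missing (insertion) or nothing missing (perfect)
        if raw.deleted_total == k:
            tsd.sides = "both"
            return call("insertion", event.bearing_species, tsd)
        if raw.deleted_total == 0:
            tsd.sides = "both"
            return call("excision-perfect", other_species, tsd)
    # messy footprints: re-measure with junk-edge stripping, which undoes
    # the aligner's habit of pairing small fillers against deleted flank
    junction = _analyse_junction(
        gB, gO, tsd.te_start, tsd.te_end, event.empty_site_position, k,
        strip_edges=True,
    )
    if not junction.covered:
        junction = raw

    deleted, filler_bp, filler_seq = measure_footprint(junction, k)
    D = junction.deleted_total
    if filler_bp and _filler_is_local_echo(filler_seq, gB, tsd.te_start, tsd.te_end):
        # filler DNA may legitimately derive from TEs elsewhere in the
        # genome, so TE homology of the segment is not held against it;
        # only a local flank echo (alignment jitter) disqualifies it
        filler_bp = 0
        filler_seq = ""

    continuity = junction.left_identity >= 0.90 and junction.right_identity >= 0.90
    if filler_bp == 0:
        if D == k and continuity:
            tsd.sides = "both"
            return call("insertion", event.bearing_species, tsd)
        if D == 0 and continuity:
            tsd.sides = "both"
            return call("excision-perfect", other_species, tsd)
        if D > k:
            tsd.sides = "bearing-only"
            return call("excision-deletion", other_species, tsd, deleted=deleted)
        return call("unclear", other_species, tsd)
    if D <= k:
        tsd.sides = "both" if D == 0 else "bearing-only"
        return call("excision-filler", other_species, tsd,
                    filler=filler_bp, filler_seq=filler_seq)
    tsd.sides = "bearing-only"
    return call("excision-both", other_species, tsd, deleted=deleted,
                filler=filler_bp, filler_seq=filler_seq)


def classify_events(
    events: list[IndelEvent],
    context: ClassificationContext,
    min_len: int = 50,
    min_identity: float = 0.70,
) -> tuple[list[PolymorphismCall], list[IndelEvent]]:
    """Annotate each event and classify the TE-homologous ones.

    Returns (calls, events_without_te_homology)."""
    calls: list[PolymorphismCall] = []
    no_te: list[IndelEvent] = []
    # generous context: window misalignments can split an event mid-TE, so
    # the TE body may extend well into the recorded flanks
    ctx_bp = 1500
    for ev in events:
        gB = context.bearing_seq(ev)
        c0 = max(0, ev.start - ctx_bp)
        seg = gB[c0 : ev.end + ctx_bp]
        up_len = ev.start - c0
        anns = annotate_segment(
            seg, context.library, min_len=min_len, min_identity=min_identity
        )
        shifted = []
        for a in anns:
            a.start -= up_len
            a.end -= up_len
            ov = min(ev.length, a.end) - max(0, a.start)
            if ov >= min(40, max(10, ev.length // 3)):
                shifted.append(a)
        if not shifted:
            no_te.append(ev)
            continue
        shifted.sort(
            key=lambda a: (
                -(min(ev.length, a.end) - max(0, a.start)),
                -a.identity,
            )
        )
        calls.append(classify_polymorphism(ev, shifted, context))
    return calls, no_te


# ---------------------------------------------------------------------------
# summaries


@dataclass
class FootprintSummary:
    n_calls: int
    verdict_counts: dict
    verdict_counts_by_superfamily: dict
    total_deleted_bp: int
    total_deleted_bp_excluding_outliers: int
    n_deletion_bearing: int
    n_outliers: int
    mean_deleted_per_deletion_event: float
    mean_deleted_per_excision: float
    total_filler_bp: int
    n_filler_bearing: int
    mean_filler_bp: float
    min_filler_bp: int
    max_filler_bp: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_footprints(
    calls: list[PolymorphismCall], outlier_threshold: int = 1000
) -> FootprintSummary:
    """Per-verdict counts and deletion/filler length statistics.

    The mean deletion is reported against two denominators ("per excision
    event" is ambiguous): deletion-bearing events excluding outliers
    beyond ``outlier_threshold``, and all excision verdicts.
    """
    counts = {v: 0 for v in VERDICTS}
    by_sf: dict[str, dict[str, int]] = {}
    for c in calls:
        counts[c.verdict] += 1
        by_sf.setdefault(c.superfamily, {v: 0 for v in VERDICTS})[c.verdict] += 1
    deletions = [
        c.deleted_bp
        for c in calls
        if c.verdict in ("excision-deletion", "excision-both")
    ]
    normal = [d for d in deletions if d <= outlier_threshold]
    outliers = [d for d in deletions if d > outlier_threshold]
    fillers = [
        c.filler_bp
        for c in calls
        if c.verdict in ("excision-filler", "excision-both")
    ]
    n_excision = sum(
        counts[v]
        for v in ("excision-perfect", "excision-deletion", "excision-filler",
                  "excision-both")
    )
    return FootprintSummary(
        n_calls=len(calls),
        verdict_counts=counts,
        verdict_counts_by_superfamily=by_sf,
        total_deleted_bp=sum(deletions),
        total_deleted_bp_excluding_outliers=sum(normal),
        n_deletion_bearing=len(deletions),
        n_outliers=len(outliers),
        mean_deleted_per_deletion_event=(sum(normal) / len(normal)) if normal else 0.0,
        mean_deleted_per_excision=(sum(normal) / n_excision) if n_excision else 0.0,
        total_filler_bp=sum(fillers),
        n_filler_bearing=len(fillers),
        mean_filler_bp=(sum(fillers) / len(fillers)) if fillers else 0.0,
        min_filler_bp=min(fillers) if fillers else 0,
        max_filler_bp=max(fillers) if fillers else 0,
    )


def calls_to_table(calls: list[PolymorphismCall]) -> pd.DataFrame:
    rows = [
        {
            "bearing_species": c.event.bearing_species,
            "start": c.event.start,
            "end": c.event.end,
            "empty_site_position": c.event.empty_site_position,
            "family": c.family,
            "superfamily": c.superfamily,
            "verdict": c.verdict,
            "acting_species": c.acting_species,
            "tsd": c.tsd.sequence,
            "deleted_bp": c.deleted_bp,
            "filler_bp": c.filler_bp,
            "identity": round(c.identity, 4),
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
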