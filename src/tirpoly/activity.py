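"""Activity statistics: insertion:excision ratios, relative activity and
abundance, fixation rates, assembly-gap attribution, and gene context.

The expected insertion:excision ratio in a two-species comparison is 2:1
under the replication-fork proliferation model: an element excising during
replication and reinserting ahead of the fork yields two gamete types, one
with two copies and one with one copy plus the excision footprint, so the
new insertion is transmitted twice as often as the footprint.  Observed
ratios are tested against that expectation with an exact binomial test
(p0 = expected/(expected+1)); an exact 2x2 variant (observed vs rounded
expected counts, Fisher) is co-reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ContractError, ParameterError
from .footprint import PolymorphismCall
from .te_model import TELibrary, annotate_segment
from ._align import align_auto
from ._kmer import KmerIndex, cluster_diagonals
from ._seq import n_run_intervals, revcomp

EXCISION_VERDICTS = (
    "excision-perfect",
    "excision-deletion",
    "excision-filler",
    "excision-both",
)


@dataclass
class RatioTest:
    superfamily: str
    species: str
    insertions: int
    excisions: int
    ratio: float  # nan when excisions == 0
    expected_ratio: float
    p_value: float  # exact binomial against p0 = expected/(expected+1)
    p_value_fisher: float  # 2x2 exact variant, co-reported
    significant: bool

    @property
    def ratio_defined(self) -> bool:
        return self.excisions > 0

    @property
    def ratio_display(self) -> str:
        if not self.ratio_defined:
            return "-"
        return f"{self.ratio:.2f}"


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value: total probability of outcomes no
    more likely than the observed count."""
    return float(stats.binomtest(k, n, p0).pvalue)


def ratio_test(
    insertions: int,
    excisions: int,
    expected: float = 2.0,
    superfamily: str = "",
    species: str = "",
    alpha: float = 0.05,
) -> RatioTest:
    """Insertion:excision ratio with exact tests against ``expected``:1.

    Zero excisions leave the ratio undefined (nan); the tests still run.
    """
    n = insertions + excisions
    if n <= 0:
        raise ParameterError("insertions + excisions must be positive")
    p0 = expected / (expected + 1.0)
    p = binomial_two_sided(insertions, n, p0)
    exp_ins = int(round(n * p0))
    _, p_fisher = stats.fisher_exact(
        [[insertions, excisions], [exp_ins, n - exp_ins]]
    )
    ratio = insertions / excisions if excisions > 0 else float("nan")
    return RatioTest(
        superfamily, species, insertions, excisions, ratio, expected,
        p, float(p_fisher), p < alpha,
    )


def counts_by_superfamily(
    calls: list[PolymorphismCall],
) -> dict[tuple[str, str], tuple[int, int]]:
    """(superfamily, dataset species) -> (insertions, excisions).

    The dataset species is the one bearing the extra sequence, matching a
    per-genome presence-polymorphism survey."""
    out: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        key = (c.superfamily, c.event.bearing_species)
        rec = out.setdefault(key, [0, 0])
        if c.verdict == "insertion":
            rec[0] += 1
        elif c.verdict in EXCISION_VERDICTS:
            rec[1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def ratio_table(
    calls: list[PolymorphismCall], expected: float = 2.0, alpha: float = 0.05
) -> list[RatioTest]:
    out = []
    for (sf, sp), (ins, exc) in sorted(counts_by_superfamily(calls).items()):
        if ins + exc == 0:
            continue
        out.append(ratio_test(ins, exc, expected, sf, sp, alpha))
    return out


# ---------------------------------------------------------------------------
# replication-fork transmission model


def simulate_transmission_ratio(
    n_events: int = 100,
    n_replicates: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Observed insertion:excision ratios under the replication-fork model
    with equal activity in both species.

    Each transposition contributes its new insertion to every gamete but
    transmits the excision footprint with probability 1/2 (the gamete that
    inherited the two-copy chromatid shows no excision).  Returns one
    observed ratio per replicate; the mean approaches 2."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    excisions = rng.binomial(n_events, 0.5, size=n_replicates)
    excisions = np.maximum(excisions, 1)  # ratio undefined at 0 (p ~ 2^-n)
    return n_events / excisions


# ---------------------------------------------------------------------------
# relative activity / abundance


@dataclass
class ActivityRecord:
    family: str
    superfamily: str
    total_copies: int
    moved_copies: int
    relative_activity: float
    relative_abundance: float
    group: str  # I | II | III | inactive


def relative_activity_table(
    library_counts: dict[str, int],
    calls: list[PolymorphismCall],
    superfamilies: dict[str, str] | None = None,
) -> list[ActivityRecord]:
    """Per-family relative activity (moved / total copies) and relative
    abundance (family copies / all DNA-transposon copies), grouped:

    I = abundance and activity both at or above their medians among active
    families, II = activity above / abundance below, III = abundance above
    / activity below, inactive = no moved copies.  Moved copies count
    insertions and excisions in either species."""
    moved: dict[str, int] = {f: 0 for f in library_counts}
    sf: dict[str, str] = dict(superfamilies or {})
    for c in calls:
        if c.verdict != "insertion" and c.verdict not in EXCISION_VERDICTS:
            continue
        if c.family not in library_counts:
            raise ContractError(f"family {c.family!r} missing from library counts")
        if library_counts[c.family] <= 0:
            raise ContractError(f"family {c.family!r} has calls but zero copies")
        moved[c.family] += 1
        sf.setdefault(c.family, c.superfamily)
    total = sum(library_counts.values())
    recs = []
    for fam, copies in library_counts.items():
        act = moved[fam] / copies if copies else 0.0
        ab = copies / total if total else 0.0
        recs.append(
            ActivityRecord(fam, sf.get(fam, fam[:3]), copies, moved[fam], act, ab, "")
        )
    active = [r for r in recs if r.moved_copies > 0]
    if active:
        med_act = float(np.median([r.relative_activity for r in active]))
        med_ab = float(np.median([r.relative_abundance for r in active]))
    for r in recs:
        if r.moved_copies == 0:
            r.group = "inactive"
        elif r.relative_activity >= med_act and r.relative_abundance >= med_ab:
            r.group = "I"
        elif r.relative_activity >= med_act:
            r.group = "II"
        else:
            r.group = "III"
    return recs


# ---------------------------------------------------------------------------
# fixation rate


def fixation_rate(n_events: int, generations: int) -> tuple[float, int | None]:
    """Fixed transposition events per generation and its reciprocal.

    Under neutrality the fixation rate equals the per-individual
    transposition rate m, so n_events/generations individuals per
    generation carry a new fixed event.  The reciprocal is taken on the
    display-rounded rate (3 decimals), matching how such rates are quoted.
    """
    if generations <= 0:
        raise ParameterError("generations must be positive")
    rate = n_events / generations
    rounded = round(rate, 3)
    if rounded <= 0:
        return rate, None
    return rate, int(round(1.0 / rounded))


# ---------------------------------------------------------------------------
# assembly-gap attribution


@dataclass
class GapAttribution:
    total_gaps: int
    mappable_gaps: int
    te_positive_gaps: int
    n_ambiguous_polymorphisms: int = 0

    @property
    def te_fraction(self) -> float:
        return (
            self.te_positive_gaps / self.mappable_gaps if self.mappable_gaps else 0.0
        )

    @property
    def extrapolated_te_gaps(self) -> float:
        return self.te_fraction * self.total_gaps

    @property
    def extrapolated_hidden_polymorphisms(self) -> float:
        return self.te_fraction * self.n_ambiguous_polymorphisms

    def to_dict(self) -> dict:
        return {
            "total_gaps": self.total_gaps,
            "mappable_gaps": self.mappable_gaps,
            "te_positive_gaps": self.te_positive_gaps,
            "te_fraction": self.te_fraction,
            "extrapolated_te_gaps": self.extrapolated_te_gaps,
            "n_ambiguous_polymorphisms": self.n_ambiguous_polymorphisms,
            "extrapolated_hidden_polymorphisms": self.extrapolated_hidden_polymorphisms,
        }


def _map_flank(
    flank: str, genome: dict[str, str], indexes: dict[str, KmerIndex],
    min_hit_len: int, min_hit_id: float,
) -> tuple[str, int, int, str] | None:
    """Best placement of a gap flank: (chrom, start, end, orientation)."""
    best = None
    best_votes = 0
    for strand in ("+", "-"):
        q = flank if strand == "+" else revcomp(flank)
        for chrom, idx in indexes.items():
            qpos, tpos = idx.seed_matches(q, step=2)
            clusters = cluster_diagonals(qpos, tpos, max_gap=200)
            if clusters and clusters[0][2] > best_votes:
                best_votes = clusters[0][2]
                best = (chrom, clusters[0][0], clusters[0][1], strand, q)
    if best is None or best_votes < 3:
        return None
    chrom, dlo, dhi, strand, q = best
    seq = genome[chrom]
    t0 = max(0, dlo - 100)
    t1 = min(len(seq), dhi + len(q) + 100)
    aln = align_auto(q, seq[t0:t1])
    if aln.n_columns < min_hit_len or aln.identity < min_hit_id:
        return None
    return chrom, t0 + aln.b_start, t0 + aln.b_end, strand


def extrapolate_hidden_te_gaps(
    gapped_genome: dict[str, str],
    other_genome: dict[str, str],
    library: TELibrary,
    flank_bp: int = 500,
    max_span: int = 10_000,
    min_hit_len: int = 400,
    min_hit_id: float = 0.95,
    n_ambiguous_polymorphisms: int = 0,
) -> GapAttribution:
    """Attribute assembly gaps (N runs > 50) to hidden TE sequence.

    Both 500-bp gap flanks are mapped onto the other genome; a gap is
    mappable when both flanks place within ``max_span`` of each other in
    the same orientation (hits >= 400 bp at >= 95% identity), and
    TE-positive when the intervening other-genome segment carries TE
    homology.  The TE-positive fraction is extrapolated to all gaps and to
    N-rich (ambiguous) polymorphisms."""
    indexes = {c: KmerIndex(s, k=12) for c, s in other_genome.items()}
    total = mappable = positive = 0
    for chrom, seq in gapped_genome.items():
        for s, e in n_run_intervals(seq, min_len=51):
            total += 1
            up = seq[max(0, s - flank_bp) : s]
            down = seq[e : e + flank_bp]
            if len(up) < min_hit_len or len(down) < min_hit_len:
                continue
            m_up = _map_flank(up, other_genome, indexes, min_hit_len, min_hit_id)
            m_down = _map_flank(down, other_genome, indexes, min_hit_len, min_hit_id)
            if m_up is None or m_down is None:
                continue
            if m_up[0] != m_down[0] or m_up[3] != m_down[3]:
                continue
            lo = min(m_up[2], m_down[2])
            hi = max(m_up[1], m_down[1])
            if hi - lo > max_span or hi < lo:
                continue
            mappable += 1
            segment = other_genome[m_up[0]][lo:hi]
            if segment and annotate_segment(segment, library):
                positive += 1
    return GapAttribution(total, mappable, positive, n_ambiguous_polymorphisms)


# ---------------------------------------------------------------------------
# gene context


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    cds_start: int  # 0-based half-open CDS span
    cds_end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    description: str = ""


def read_gene_models(path: str | Path, drop_transposon_entries: bool = True) -> list[GeneModel]:
    """Minimal GFF3 reader: gene/mRNA spans + exon/CDS children.

    Entries whose attributes mention 'transpos' are removed (they mostly
    correspond to TE-derived gene models)."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            s, e = int(start) - 1, int(end)
            att = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("gene", "mRNA"):
                gid = att.get("ID", att.get("Parent", f"{chrom}:{s}"))
                if drop_transposon_entries and "transpos" in attrs.lower():
                    continue
                if gid not in genes:
                    genes[gid] = GeneModel(gid, chrom, s, e, strand, [], attrs)
            elif ftype in ("exon", "CDS"):
                gid = att.get("Parent", "")
                base = gid.split(".")[0]
                for key in (gid, base):
                    if key in genes:
                        if ftype == "exon":
                            genes[key].exons.append((s, e))
                        else:
                            g = genes[key]
                            if getattr(g, "_cds_seen", False):
                                g.cds_start = min(g.cds_start, s)
                                g.cds_end = max(g.cds_end, e)
                            else:
                                # first CDS line replaces the gene span
                                g.cds_start, g.cds_end = s, e
                                g._cds_seen = True
                        break
    return list(genes.values())


CONTEXTS = ("exon", "intron", "upstream", "downstream", "intergenic")


def _context_for_position(
    chrom: str, pos: int, genes: list[GeneModel], upstream_bp: int, downstream_bp: int
) -> str:
    best: tuple[int, str, str] | None = None  # (distance, gene_id, context)
    for g in genes:
        if g.chrom != chrom:
            continue
        if not g.strand or g.strand not in "+-":
            warnings.warn(f"gene {g.gene_id} lacks strand; skipped")
            continue
        if g.cds_start <= pos < g.cds_end:
            inside_exon = any(s <= pos < e for s, e in g.exons) if g.exons else True
            ctx = "exon" if inside_exon else "intron"
            cand = (0, g.gene_id, ctx)
        else:
            dist = g.cds_start - pos if pos < g.cds_start else pos - g.cds_end + 1
            if g.strand == "+":
                before_cds = pos < g.cds_start
            else:
                before_cds = pos >= g.cds_end
            if before_cds and dist <= upstream_bp:
                cand = (dist, g.gene_id, "upstream")
            elif not before_cds and dist <= downstream_bp:
                cand = (dist, g.gene_id, "downstream")
            else:
                continue
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    return best[2] if best else "intergenic"


def gene_context(
    calls: list[PolymorphismCall],
    gene_models: list[GeneModel],
    upstream_bp: int = 1000,
    downstream_bp: int = 500,
    chrom_of_call=None,
) -> dict[str, int]:
    """Assign each polymorphism one gene context (exon | intron | upstream |
    downstream | intergenic) by position relative to the nearest CDS,
    strand-aware; contexts partition the calls."""
    counts = {c: 0 for c in CONTEXTS}
    for c in calls:
        if c.event.bearing_species == "A":
            chrom = c.event.query_chrom
            pos = (c.event.start + c.event.end) // 2
        else:
            chrom = c.event.query_chrom
            pos = c.event.empty_site_position
        if chrom_of_call is not None:
            chrom = chrom_of_call(c)
        counts[
            _context_for_position(chrom, pos, gene_models, upstream_bp, downstream_bp)
        ] += 1
    return counts
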