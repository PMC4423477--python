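"""TE superfamily diagnostics, consensus libraries, homology annotation and
iterative de novo family discovery.

Five TIR-order Class II superfamilies are in scope, identified by their
3-letter codes: Mariner (DTT), Harbinger (DTH), Mutator (DTM), CACTA (DTC)
and hAT (DTA).  Each has a diagnostic target-site duplication (TSD) length
and, for DTT/DTH, a fixed TSD motif, plus a 5'-terminal TIR consensus.

Annotation is a self-contained k-mer seed-and-extend local search (seed
length 12, banded affine-gap extension) against the library; admission
thresholds are an alignment of at least 50 bp at >= 70% identity, identity
being matches over all alignment columns (gap columns included).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._align import LocalAlignment, align_auto, smith_waterman_banded
from ._kmer import KmerIndex, cluster_diagonals
from ._seq import revcomp
from .errors import (
    ClassificationError,
    DuplicateFamilyError,
    EmptyLibraryError,
    FormatError,
)

TIR_SUPERFAMILY_CODES = ("DTT", "DTH", "DTM", "DTC", "DTA")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _parse_motif(motif: str) -> list[frozenset[str]]:
    """Parse a TIR/TSD motif with parenthesised alternatives,
    e.g. ``CACT(A/G)`` -> [{C},{A},{C},{T},{A,G}]."""
    out: list[frozenset[str]] = []
    i = 0
    while i < len(motif):
        ch = motif[i]
        if ch == "(":
            j = motif.index(")", i)
            alts = motif[i + 1 : j].split("/")
            out.append(frozenset(alts))
            i = j + 1
        else:
            out.append(frozenset(ch))
            i += 1
    return out


@dataclass(frozen=True)
class SuperfamilyProfile:
    """Target-site and TIR diagnostics of one TIR superfamily."""

    code: str
    name: str
    tsd_motif: str  # fixed motif(s), '/'-separated, or "variable"
    tsd_length: int
    tir_consensus: str

    @property
    def tsd_motifs(self) -> tuple[str, ...]:
        if self.tsd_motif == "variable":
            return ()
        return tuple(self.tsd_motif.split("/"))

    @property
    def tir_positions(self) -> list[frozenset[str]]:
        return _parse_motif(self.tir_consensus)

    @property
    def tir_positions_rc(self) -> list[frozenset[str]]:
        fwd = self.tir_positions
        return [frozenset(_COMP[c] for c in s) for s in reversed(fwd)]


SUPERFAMILY_PROFILES: dict[str, SuperfamilyProfile] = {
    "DTT": SuperfamilyProfile("DTT", "Mariner", "TA", 2, "CTCCCTC"),
    "DTH": SuperfamilyProfile("DTH", "Harbinger", "TAA/TTA", 3, "GG(G/C)CC"),
    "DTM": SuperfamilyProfile("DTM", "Mutator", "variable", 9, "GAG"),
    "DTC": SuperfamilyProfile("DTC", "CACTA", "variable", 3, "CACT(A/G)"),
    "DTA": SuperfamilyProfile("DTA", "hAT", "variable", 8, "CA"),
}


@dataclass(frozen=True)
class TIRHit:
    """Result of matching a TIR consensus at both element termini."""

    profile_code: str
    five_prime_mismatches: int
    three_prime_mismatches: int


def match_tir(
    sequence: str, profile: SuperfamilyProfile, max_mismatch: int = 1
) -> TIRHit | None:
    """Match the profile's TIR consensus at the 5' terminus and its reverse
    complement at the 3' terminus, each with <= max_mismatch mismatches.

    Parenthesised alternatives are accepted at their position.  Returns a
    TIRHit, or None when either terminus fails.
    """
    positions = profile.tir_positions
    L = len(positions)
    if len(sequence) < 2 * L:
        return None
    seq = sequence.upper()
    mm5 = sum(1 for i, allowed in enumerate(positions) if seq[i] not in allowed)
    if mm5 > max_mismatch:
        return None
    rc_positions = profile.tir_positions_rc
    tail = seq[-L:]
    mm3 = sum(1 for i, allowed in enumerate(rc_positions) if tail[i] not in allowed)
    if mm3 > max_mismatch:
        return None
    return TIRHit(profile.code, mm5, mm3)


@dataclass
class TEConsensus:
    """One TE family consensus sequence."""

    family_name: str
    superfamily: str
    sequence: str
    source: str = "library"  # "library" | "discovered"
    tir_coords: tuple[int, int] | None = None

    def __post_init__(self):
        if self.superfamily not in TIR_SUPERFAMILY_CODES:
            raise ClassificationError(
                f"family {self.family_name!r}: superfamily code "
                f"{self.superfamily!r} is not a TIR-order Class II code "
                f"{TIR_SUPERFAMILY_CODES}"
            )

    @property
    def profile(self) -> SuperfamilyProfile:
        return SUPERFAMILY_PROFILES[self.superfamily]


@dataclass
class TEAnnotation:
    """A local similarity hit of a genomic segment to a library family.

    ``start``/``end`` are 0-based half-open coordinates in the annotated
    segment; ``alignment_length`` counts alignment columns (gap columns
    included) and ``identity`` is matches / columns.
    """

    start: int
    end: int
    family_name: str
    superfamily: str
    alignment_length: int
    identity: float
    strand: str = "+"
    consensus_start: int = 0
    consensus_end: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


class TELibrary:
    """A collection of TE family consensus sequences keyed by family name."""

    def __init__(self, families: list[TEConsensus] | None = None):
        self.families: dict[str, TEConsensus] = {}
        for fam in families or []:
            self.add(fam)

    def add(self, fam: TEConsensus) -> None:
        if fam.family_name in self.families:
            raise DuplicateFamilyError(
                f"duplicate family name {fam.family_name!r} in TE library"
            )
        if len(fam.sequence) < 50:
            raise FormatError(
                f"family {fam.family_name!r}: consensus shorter than 50 bp"
            )
        self.families[fam.family_name] = fam

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families.values())

    def __contains__(self, name: str) -> bool:
        return name in self.families

    def __getitem__(self, name: str) -> TEConsensus:
        return self.families[name]

    def profile_of(self, family_name: str) -> SuperfamilyProfile:
        return self.families[family_name].profile

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for fam in self:
                fh.write(f">{fam.family_name}#{fam.superfamily} source={fam.source}\n")
                seq = fam.sequence
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def _family_header(header: str) -> tuple[str, str]:
    """Parse a library FASTA header into (family_name, superfamily_code).

    Accepts the explicit grammar ``<family>#<code>`` and TREP-style headers
    where the family name itself starts with the 3-letter code
    (e.g. ``DTT_SB``).
    """
    token = header.split()[0]
    if "#" in token:
        family, code = token.split("#", 1)
        code = code.split("/")[0]
    else:
        family = token
        code = token[:3]
    if len(code) != 3 or not code.isalpha():
        raise FormatError(f"record {header!r}: cannot parse a 3-letter superfamily code")
    return family, code.upper()


def load_te_library(path: str | Path) -> TELibrary:
    """Read a classified TE consensus FASTA into a TELibrary.

    Headers must carry the family name and a TIR superfamily code; records
    with non-TIR codes (e.g. retrotransposon orders) are rejected.
    """
    lib = TELibrary()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        family, code = _family_header(rec.description)
        if code not in TIR_SUPERFAMILY_CODES:
            raise ClassificationError(
                f"record {family!r}: superfamily code {code!r} is not a "
                f"TIR-order Class II code (expected one of {TIR_SUPERFAMILY_CODES})"
            )
        lib.add(TEConsensus(family, code, str(rec.seq).upper()))
    if n == 0:
        raise EmptyLibraryError(f"TE library {path} contains no records")
    return lib


# ---------------------------------------------------------------------------
# seed-and-extend annotation


def _hits_against_consensus(
    segment: str,
    consensus: str,
    min_len: int,
    min_identity: float,
    seed_k: int = 12,
    band_pad: int = 60,
) -> list[tuple[LocalAlignment, str]]:
    """All seeded local hits of segment against one consensus, both strands."""
    out: list[tuple[LocalAlignment, str]] = []
    for strand, cons in (("+", consensus), ("-", revcomp(consensus))):
        idx = KmerIndex(cons, k=seed_k)
        qpos, tpos = idx.seed_matches(segment)
        clusters = cluster_diagonals(qpos, tpos, max_gap=60)
        for dlo, dhi, _cnt in clusters:
            # cluster diagonals are target - query; DP band is query -> j=target
            aln, _pmin, _pmax = smith_waterman_banded(
                segment, cons, dlo - band_pad, dhi + band_pad
            )
            if aln.n_columns >= min_len and aln.identity >= min_identity:
                out.append((aln, strand))
    return out


def annotate_segment(
    segment: str,
    library: TELibrary,
    min_len: int = 50,
    min_identity: float = 0.70,
) -> list[TEAnnotation]:
    """Annotate a segment against the library.

    Returns all non-duplicate local hits meeting both admission thresholds,
    best identity first.  Hits to the same family overlapping by more than
    50% are merged into one annotation keeping the union interval and the
    maximum identity.  A segment that is entirely Ns yields an empty list.
    """
    if not segment:
        return []
    raw: list[TEAnnotation] = []
    for fam in library:
        for aln, strand in _hits_against_consensus(
            segment, fam.sequence, min_len, min_identity
        ):
            cs, ce = aln.b_start, aln.b_end
            if strand == "-":
                L = len(fam.sequence)
                cs, ce = L - aln.b_end, L - aln.b_start
            raw.append(
                TEAnnotation(
                    start=aln.a_start,
                    end=aln.a_end,
                    family_name=fam.family_name,
                    superfamily=fam.superfamily,
                    alignment_length=aln.n_columns,
                    identity=aln.identity,
                    strand=strand,
                    consensus_start=cs,
                    consensus_end=ce,
                )
            )
    merged = _merge_family_overlaps(raw)
    merged.sort(key=lambda a: (-a.identity, a.start))
    return merged


def _merge_family_overlaps(hits: list[TEAnnotation]) -> list[TEAnnotation]:
    """Merge same-family hits overlapping by > 50% of the shorter hit."""
    by_family: dict[str, list[TEAnnotation]] = {}
    for h in hits:
        by_family.setdefault(h.family_name, []).append(h)
    out: list[TEAnnotation] = []
    for fam_hits in by_family.values():
        fam_hits.sort(key=lambda a: a.start)
        cur = fam_hits[0]
        for h in fam_hits[1:]:
            ov = min(cur.end, h.end) - max(cur.start, h.start)
            shorter = min(cur.span, h.span)
            if shorter > 0 and ov > 0.5 * shorter:
                cur = replace(
                    cur,
                    start=min(cur.start, h.start),
                    end=max(cur.end, h.end),
                    identity=max(cur.identity, h.identity),
                    alignment_length=max(cur.alignment_length, h.alignment_length),
                    consensus_start=min(cur.consensus_start, h.consensus_start),
                    consensus_end=max(cur.consensus_end, h.consensus_end),
                )
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# de novo family discovery


@dataclass
class _GenomeHit:
    start: int
    end: int
    identity: float
    chrom: str


def _genome_copies(
    segment: str,
    genome: dict[str, str],
    indexes: dict[str, KmerIndex],
    min_identity: float,
    min_coverage: float = 0.8,
) -> list[_GenomeHit]:
    hits: list[_GenomeHit] = []
    for chrom, idx in indexes.items():
        seq = genome[chrom]
        qpos, tpos = idx.seed_matches(segment)
        for dlo, dhi, cnt in cluster_diagonals(qpos, tpos, max_gap=80):
            if cnt < 3:
                continue
            g0 = max(0, dlo - 80)
            g1 = min(len(seq), dhi + len(segment) + 80)
            aln = align_auto(segment, seq[g0:g1])
            if (
                aln.identity >= min_identity
                and (aln.a_end - aln.a_start) >= min_coverage * len(segment)
            ):
                hits.append(
                    _GenomeHit(g0 + aln.b_start, g0 + aln.b_end, aln.identity, chrom)
                )
    # de-duplicate overlapping loci, keep best identity
    hits.sort(key=lambda h: (h.chrom, h.start))
    dedup: list[_GenomeHit] = []
    for h in hits:
        if dedup and h.chrom == dedup[-1].chrom and h.start < dedup[-1].end - 25:
            if h.identity > dedup[-1].identity:
                dedup[-1] = h
        else:
            dedup.append(h)
    return dedup


def build_star_msa(reference: str, others: list[str]) -> list[str]:
    """Project sequences onto reference coordinates via global alignment.

    Row 0 is the reference itself; every other row has the reference's
    length, with '-' where the row lacks the reference column.  Insertions
    relative to the reference are dropped (star-MSA semantics).
    """
    import edlib

    rows = [reference]
    for other in others:
        res = edlib.align(other, reference, mode="NW", task="path")
        cigar = res["cigar"] or ""
        row: list[str] = []
        qi = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch in "=X":
                row.append(other[qi : qi + ln])
                qi += ln
            elif ch == "I":  # extra in `other`, absent from reference
                qi += ln
            else:  # 'D': reference column absent from `other`
                row.append("-" * ln)
        rows.append("".join(row))
    return rows


@dataclass
class ConsensusResult:
    consensus: TEConsensus | None
    failed: bool
    reason: str = ""


def refine_consensus_borders(
    msa: list[str],
    min_core: int = 50,
    min_occupancy: float = 0.5,
    min_agreement: float = 0.6,
    family_name: str = "candidate",
    superfamily_hint: str | None = None,
) -> ConsensusResult:
    """Trim a hit+flank alignment to the element core and build a consensus.

    The element is the maximal run of columns where at least half the rows
    are non-gap and the majority base is shared by >= ``min_agreement`` of
    the non-gap rows; flank-derived columns outside the element diverge and
    break that run.  A run reaching either alignment end means the borders
    cannot be determined (no flank divergence signal) and a failure flag is
    returned, as for an alignment with no conserved core of >= 50 columns.
    """
    if len(msa) < 3:
        return ConsensusResult(None, True, "fewer than 3 rows")
    ncol = len(msa[0])
    if any(len(r) != ncol for r in msa):
        return ConsensusResult(None, True, "ragged alignment")
    arr = np.frombuffer("".join(msa).encode("ascii"), dtype=np.uint8).reshape(
        len(msa), ncol
    )
    good = np.zeros(ncol, bool)
    cons_chars = np.zeros(ncol, np.uint8)
    gap = ord("-")
    for j in range(ncol):
        col = arr[:, j]
        nongap = col[col != gap]
        if len(nongap) < min_occupancy * len(msa):
            continue
        vals, counts = np.unique(nongap, return_counts=True)
        best = counts.max()
        # strict majority, ties broken alphabetically (np.unique sorts)
        winner = vals[np.argmax(counts)]
        cons_chars[j] = winner
        if best >= min_agreement * len(nongap):
            good[j] = True
    # maximal good run
    best_len = 0
    best_span = (0, 0)
    i = 0
    while i < ncol:
        if good[i]:
            j = i
            while j < ncol and good[j]:
                j += 1
            if j - i > best_len:
                best_len = j - i
                best_span = (i, j)
            i = j
        else:
            i += 1
    s, e = best_span
    if best_len < min_core:
        return ConsensusResult(None, True, "no conserved core of >= 50 columns")
    if s == 0 or e == ncol:
        return ConsensusResult(
            None, True, "conserved run reaches the alignment end; borders indeterminable"
        )
    def _seq(s2: int, e2: int) -> str:
        part = cons_chars[s2:e2]
        return bytes(part[part != 0]).decode("ascii")

    # flank columns are noisy with few rows, so the core run borders can be
    # off by a few columns; search nearby borders for a TIR match, longer
    # motifs first so a short motif cannot shadow a longer exact one
    profiles = sorted(
        SUPERFAMILY_PROFILES.values(),
        key=lambda p: -len(p.tir_positions),
    )
    if superfamily_hint:
        profiles = [p for p in profiles if p.code == superfamily_hint]
    best = None  # (mismatches, |ds|+|de|, code, s2, e2)
    for mm_budget in (0, 1):
        for prof in profiles:
            for ds in range(-8, 9):
                s2 = s + ds
                if s2 < 0:
                    continue
                for de in range(-8, 9):
                    e2 = e + de
                    if e2 > ncol or e2 - s2 < min_core:
                        continue
                    seq2 = _seq(s2, e2)
                    hit = match_tir(seq2, prof, max_mismatch=mm_budget)
                    if hit is not None:
                        cand = (
                            hit.five_prime_mismatches + hit.three_prime_mismatches,
                            abs(ds) + abs(de),
                            prof.code,
                            s2,
                            e2,
                        )
                        if best is None or cand[:2] < best[:2]:
                            best = cand
        if best is not None:
            break
    if best is None:
        cons = TEConsensus(
            family_name, superfamily_hint or "DTT", _seq(s, e), source="discovered"
        )
        return ConsensusResult(cons, True, "no TIR match at the element termini")
    _, _, code, s2, e2 = best
    seq = _seq(s2, e2)
    L = len(SUPERFAMILY_PROFILES[code].tir_positions)
    cons = TEConsensus(
        family_name, code, seq, source="discovered", tir_coords=(0, L)
    )
    return ConsensusResult(cons, False)


def discover_families(
    unassigned_segments: list[str],
    genome: dict[str, str] | str,
    library: TELibrary | None = None,
    min_copies: int = 15,
    min_identity: float = 0.85,
    flank_bp: int = 300,
    top_hits: int = 15,
) -> list[TEConsensus]:
    """Iteratively discover new TE families from unassigned segments.

    Segments are processed longest first.  A segment with at least
    ``min_copies`` genome copies at >= ``min_identity`` seeds a family: the
    top ``top_hits`` copies are extracted with ``flank_bp`` of flanking
    sequence, stacked in a star multiple alignment, and the consensus is
    trimmed to the element borders (flank divergence + TIR match).  Newly
    discovered families immediately annotate the remaining segments, and
    discovery iterates until a pass adds no family (fixed point).
    """
    if isinstance(genome, str):
        genome = {"chr1": genome}
    indexes = {c: KmerIndex(s, k=12) for c, s in genome.items()}
    lib = TELibrary(list(library) if library else [])
    discovered: list[TEConsensus] = []
    pending = sorted((s for s in unassigned_segments if s), key=len, reverse=True)
    counter = 0
    changed = True
    while changed:
        changed = False
        remaining: list[str] = []
        for seg in pending:
            if len(lib) and _is_assigned(seg, lib):
                continue
            copies = _genome_copies(seg, genome, indexes, min_identity)
            if len(copies) < min_copies:
                remaining.append(seg)
                continue
            copies.sort(key=lambda h: -h.identity)
            seqs = []
            for h in copies[:top_hits]:
                s0 = max(0, h.start - flank_bp)
                s1 = min(len(genome[h.chrom]), h.end + flank_bp)
                seqs.append(genome[h.chrom][s0:s1])
            msa = build_star_msa(seqs[0], seqs[1:])
            counter += 1
            result = refine_consensus_borders(msa, family_name=f"NOV{counter:02d}")
            if result.failed or result.consensus is None:
                remaining.append(seg)
                continue
            cons = result.consensus
            cons.family_name = f"{cons.superfamily}_NOV{counter:02d}"
            lib.add(cons)
            discovered.append(cons)
            changed = True
        pending = remaining
    return discovered


def _is_assigned(segment: str, lib: TELibrary, min_coverage: float = 0.8) -> bool:
    anns = annotate_segment(segment, lib)
    return any(a.span >= min_coverage * len(segment) for a in anns)
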