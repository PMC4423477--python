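"""Synthetic diverged genome pairs with planted DNA-transposon activity.

The simulator emulates two assemblies that split ~600 k years ago:

* an i.i.d. ancestor at a configurable GC content,
* shared (ancestral) TE copies of the five TIR superfamilies planted with
  proper TSDs, so both species carry them,
* species-specific transposition: insertions (creating TSDs) and excisions
  whose double-strand-break repair footprints follow the observed mix —
  rare perfect excisions (both TSD copies retained), flanking deletions
  (geometric, mean ~18 bp, with a rare multi-kb "extreme" component),
  filler DNA copied from elsewhere in the genome (1-123 bp, mean ~13 bp),
  or both,
* precise excisions (TE plus one TSD removed; indistinguishable from an
  insertion in the other species by comparative analysis),
* internal TE deletions unrelated to transposition,
* per-lineage substitutions and small (1-10 bp) background indels, and
* assembly gaps (runs of > 50 Ns) in the second species, a configurable
  fraction placed over TE copies.

Every planted mutation is logged as a :class:`GroundTruthEvent` with final
coordinates in both genomes, enabling exact recovery scoring.  All
randomness flows from one seeded generator.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import decode, encode
from .errors import ContractError, ParameterError, PlacementError
from .te_model import (
    SUPERFAMILY_PROFILES,
    SuperfamilyProfile,
    TEConsensus,
    TELibrary,
)

EVENT_KINDS = (
    "insertion",
    "excision-perfect",
    "excision-deletion",
    "excision-filler",
    "excision-both",
    "precise-excision",
    "internal-deletion",
    "background-indel",
)


@dataclass
class FootprintParams:
    """Excision footprint mixture.

    The perfect-excision probability is 8/94 and the remaining mass is
    split across deletion-only / filler-only / both in proportion 43:58:9.
    Deletion lengths are geometric (mean ``deletion_length_mean``) with a
    rare extreme component drawn uniformly from ``extreme_deletion_range``;
    filler lengths are geometric with mean ``filler_length_mean`` truncated
    to ``filler_length_range``.
    """

    p_perfect: float = 8 / 94
    p_deletion: float = (1 - 8 / 94) * 43 / 110
    p_filler: float = (1 - 8 / 94) * 58 / 110
    p_both: float = (1 - 8 / 94) * 9 / 110
    deletion_length_mean: float = 18.0
    extreme_deletion_prob: float = 0.02
    extreme_deletion_range: tuple[int, int] = (1000, 3000)
    filler_length_range: tuple[int, int] = (1, 123)
    filler_length_mean: float = 13.0
    two_sided_deletions: bool = False

    def __post_init__(self):
        total = self.p_perfect + self.p_deletion + self.p_filler + self.p_both
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"footprint probabilities sum to {total}, not 1")


@dataclass
class SimulationConfig:
    genome_length: int = 2_000_000
    gc_fraction: float = 0.44
    substitution_rate: float = 0.0035  # per bp per lineage (~0.7% pairwise)
    background_indel_rate: float = 1e-4
    n_planted_copies_per_family: int = 20
    n_insertions: int = 150
    n_excisions: int = 50
    n_precise_excisions: int = 5
    n_internal_deletions: int = 10
    footprint_params: FootprintParams = field(default_factory=FootprintParams)
    n_gaps: int = 20
    gap_length_range: tuple[int, int] = (60, 500)
    gap_te_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        for name in ("substitution_rate", "background_indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 0.1:
                raise ParameterError(f"{name}={v} outside [0, 0.1]")
        if not 0 <= self.gc_fraction <= 1:
            raise ParameterError(f"gc_fraction={self.gc_fraction} outside [0, 1]")
        if self.seed is None:
            raise ParameterError("seed is mandatory")


@dataclass
class GroundTruthEvent:
    event_id: int
    kind: str
    species: str  # acting species: A | B
    locus_a_start: int
    locus_a_end: int
    locus_b_start: int
    locus_b_end: int
    family: str = ""
    tsd_sequence: str = ""
    deleted_bp: int = 0
    filler_bp: int = 0
    filler_sequence: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if self.filler_bp != len(self.filler_sequence):
            raise ParameterError("filler_bp must equal len(filler_sequence)")
        if self.deleted_bp and self.kind not in (
            "excision-deletion",
            "excision-both",
            "internal-deletion",
            "background-indel",
        ):
            raise ParameterError(f"{self.kind} cannot carry deleted_bp > 0")


@dataclass
class PlantedLocus:
    """A shared (ancestral) TE copy; coordinates of the TE body, the TSD
    copies sit immediately outside [start, end)."""

    family: str
    tsd: str
    base_start: int = 0
    base_end: int = 0
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0
    excised_in: str = ""  # species in which the copy is gone


@dataclass
class SimulatedPair:
    genome_a: str
    genome_b: str
    events: list[GroundTruthEvent]
    planted: list[PlantedLocus]
    library: TELibrary
    gaps: list[tuple[int, int]]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# primitive operations


def make_ancestor(length: int, gc: float, seed: int | np.random.Generator) -> str:
    """I.i.d. ancestor sequence with expected GC content ``gc``."""
    if not 0 <= gc <= 1:
        raise ParameterError(f"gc={gc} outside [0, 1]")
    if length < 1:
        raise ParameterError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return decode(codes)


def _substitute(seq: str, rate: float, rng: np.random.Generator,
                protected: np.ndarray | None = None) -> str:
    codes = encode(seq)
    hit = rng.random(len(codes)) < rate
    hit &= codes < 4
    if protected is not None:
        hit &= ~protected
    idx = np.flatnonzero(hit)
    codes[idx] = (codes[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return decode(codes)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.44) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def diverge(
    ancestor: str, config: SimulationConfig
) -> tuple[str, str, list[GroundTruthEvent]]:
    """Apply independent substitutions and small background indels to two
    copies of the ancestor.  Background indels are 1-10 bp, far below the
    50 bp polymorphism threshold, and are logged."""
    rng = np.random.default_rng(config.seed)
    events: list[GroundTruthEvent] = []
    out = []
    for species in ("A", "B"):
        seq = _substitute(ancestor, config.substitution_rate, rng)
        seq, ev = _apply_background_indels(
            seq, config.background_indel_rate, rng, species, [], start_id=len(events)
        )
        events.extend(ev)
        out.append(seq)
    return out[0], out[1], events


def _apply_background_indels(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    species: str,
    forbidden: list[tuple[int, int]],
    start_id: int = 0,
) -> tuple[str, list[GroundTruthEvent]]:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, []
    fb: list[tuple[int, int]] = []
    for s, e in sorted(forbidden):
        if fb and s <= fb[-1][1]:
            fb[-1] = (fb[-1][0], max(fb[-1][1], e))
        else:
            fb.append((s, e))
    starts = np.array([s for s, _ in fb], dtype=np.int64)
    ends = np.array([e for _, e in fb], dtype=np.int64)

    def allowed(p: int) -> bool:
        if len(starts) == 0:
            return True
        i = int(np.searchsorted(starts, p, side="right")) - 1
        return i < 0 or p >= ends[i]

    pos: list[int] = []
    tries = 0
    while len(pos) < n and tries < 20 * n + 100:
        tries += 1
        p = int(rng.integers(100, max(101, len(seq) - 100)))
        if allowed(p):
            pos.append(p)
    pos.sort(reverse=True)
    events = []
    for k, p in enumerate(pos):
        length = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # insertion
            ins = _random_seq(rng, length)
            seq = seq[:p] + ins + seq[p:]
            events.append(
                GroundTruthEvent(
                    start_id + k, "background-indel", species,
                    p, p + (length if species == "A" else 0),
                    p, p + (length if species == "B" else 0),
                    filler_bp=length, filler_sequence=ins,
                )
            )
        else:
            seq = seq[:p] + seq[p + length :]
            events.append(
                GroundTruthEvent(
                    start_id + k, "background-indel", species,
                    p, p, p, p, deleted_bp=length,
                )
            )
    return seq, events


def _find_motif_site(
    genome: str, position: int, profile: SuperfamilyProfile, max_shift: int = 1000
) -> tuple[int, str]:
    """Return (position, tsd) honouring a fixed target-site motif; variable
    profiles duplicate whatever sits at the site."""
    k = profile.tsd_length
    motifs = profile.tsd_motifs
    if not motifs:
        site = genome[position : position + k]
        if len(site) < k or "N" in site:
            raise PlacementError(f"no valid target site at {position}")
        return position, site
    lo = max(0, position - max_shift)
    hi = min(len(genome) - k, position + max_shift)
    window = genome[lo:hi + k]
    best = None
    for m in motifs:
        at = window.find(m)
        while at != -1:
            p = lo + at
            if best is None or abs(p - position) < abs(best[0] - position):
                best = (p, m)
            at = window.find(m, at + 1)
    if best is None:
        raise PlacementError(
            f"no {profile.tsd_motif} target-site motif within {max_shift} bp "
            f"of position {position}"
        )
    return best


def apply_insertion(
    genome: str,
    te: TEConsensus,
    position: int,
    profile: SuperfamilyProfile,
    rng: np.random.Generator,
    event_id: int = 0,
    species: str = "A",
) -> tuple[str, GroundTruthEvent]:
    """Insert a TE at ``position``, duplicating the target site.

    The sequence becomes flank-TSD-TE-TSD-flank and the genome grows by
    ``len(te) + tsd_length``.  Fixed-motif profiles relocate to the nearest
    motif occurrence (within 1 kb, else a placement error).
    """
    if not te.sequence:
        raise ContractError("cannot insert a zero-length TE")
    pos, tsd = _find_motif_site(genome, position, profile)
    k = profile.tsd_length
    new = genome[:pos] + tsd + te.sequence + tsd + genome[pos + k :]
    start = pos  # first TSD copy
    end = pos + 2 * k + len(te.sequence)
    if species == "A":
        ev = GroundTruthEvent(event_id, "insertion", species, start, end, pos, pos,
                              family=te.family_name, tsd_sequence=tsd)
    else:
        ev = GroundTruthEvent(event_id, "insertion", species, pos, pos, start, end,
                              family=te.family_name, tsd_sequence=tsd)
    return new, ev


def _draw_footprint(params: FootprintParams, rng: np.random.Generator) -> str:
    r = rng.random()
    if r < params.p_perfect:
        return "excision-perfect"
    r -= params.p_perfect
    if r < params.p_deletion:
        return "excision-deletion"
    r -= params.p_deletion
    if r < params.p_filler:
        return "excision-filler"
    return "excision-both"


def _draw_deletion_length(params: FootprintParams, rng: np.random.Generator) -> int:
    if rng.random() < params.extreme_deletion_prob:
        lo, hi = params.extreme_deletion_range
        return int(rng.integers(lo, hi + 1))
    return int(rng.geometric(1.0 / params.deletion_length_mean))


def _draw_filler_length(params: FootprintParams, rng: np.random.Generator) -> int:
    lo, hi = params.filler_length_range
    for _ in range(1000):
        ln = int(rng.geometric(1.0 / params.filler_length_mean))
        if lo <= ln <= hi:
            return ln
    return hi


def apply_excision(
    genome: str,
    te_locus: PlantedLocus,
    params: FootprintParams,
    rng: np.random.Generator,
    event_id: int = 0,
    species: str = "A",
    kind: str | None = None,
) -> tuple[str, GroundTruthEvent]:
    """Excise a TE from a locus created by insertion (TSD known) and repair
    the break with a drawn footprint.

    Footprints: perfect (both TSD copies retained), deletion (one TSD plus
    geometric flanking bp removed on one side, with a rare extreme
    component), filler (a segment copied from a random donor locus of the
    same genome inserted between the TSD copies), or both.
    """
    if not te_locus.tsd or not te_locus.family:
        raise ContractError("locus is not a TSD-flanked TE insertion")
    k = len(te_locus.tsd)
    s, e = te_locus.base_start, te_locus.base_end
    tsd = genome[s - k : s]
    if kind is None:
        kind = _draw_footprint(params, rng)
    deleted = 0
    filler = ""
    if kind == "excision-perfect":
        new = genome[: s - k] + tsd + tsd + genome[e + k :]
    elif kind == "precise-excision":
        new = genome[: s - k] + tsd + genome[e + k :]
    elif kind == "excision-deletion":
        deleted = _draw_deletion_length(params, rng)
        if rng.random() < 0.5:  # left side
            new = genome[: s - k - deleted] + tsd + genome[e + k :]
        else:
            new = genome[: s - k] + tsd + genome[e + k + deleted :]
    elif kind == "excision-filler":
        filler = _copy_filler(genome, params, rng)
        new = genome[: s - k] + tsd + filler + tsd + genome[e + k :]
    elif kind == "excision-both":
        deleted = _draw_deletion_length(params, rng)
        filler = _copy_filler(genome, params, rng)
        if rng.random() < 0.5:
            new = genome[: s - k - deleted] + filler + tsd + genome[e + k :]
        else:
            new = genome[: s - k] + tsd + filler + genome[e + k + deleted :]
    else:
        raise ParameterError(f"unknown excision kind {kind}")
    p = s - k
    ev = GroundTruthEvent(event_id, kind, species, p, p, p, p,
                          family=te_locus.family, tsd_sequence=tsd,
                          deleted_bp=deleted, filler_bp=len(filler),
                          filler_sequence=filler)
    return new, ev


def _copy_filler(genome: str, params: FootprintParams, rng: np.random.Generator) -> str:
    length = _draw_filler_length(params, rng)
    for _ in range(100):
        p = int(rng.integers(0, len(genome) - length))
        seg = genome[p : p + length]
        if "N" not in seg:
            return seg
    return _random_seq(rng, length)


def add_gaps(
    genome: str,
    n_gaps: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    te_intervals: list[tuple[int, int]] | None = None,
    fraction_over_te: float = 0.0,
    forbidden: list[tuple[int, int]] | None = None,
    max_retries: int = 200,
) -> tuple[str, list[tuple[int, int]]]:
    """Replace ``n_gaps`` disjoint segments with N runs.

    ``length_range`` minimum must exceed 50 (assembly-gap convention).  A
    ``fraction_over_te`` of gaps is centred on the supplied TE intervals,
    emulating TE-caused assembly gaps."""
    lo, hi = length_range
    if lo <= 50:
        raise ParameterError("gap lengths must exceed 50")
    if n_gaps == 0:
        return genome, []
    te_intervals = list(te_intervals or [])
    forbidden = sorted(forbidden or [])
    placed: list[tuple[int, int]] = []

    def ok(s: int, e: int) -> bool:
        for ps, pe in placed:
            if s < pe + 10 and ps < e + 10:
                return False
        for fs, fe in forbidden:
            if s < fe and fs < e:
                return False
        return 0 < s and e < len(genome)

    n_over_te = int(round(n_gaps * fraction_over_te))
    rng.shuffle(te_intervals)
    for i in range(n_gaps):
        length = int(rng.integers(lo, hi + 1))
        done = False
        for _ in range(max_retries):
            if i < n_over_te and te_intervals:
                ts, te_ = te_intervals[int(rng.integers(0, len(te_intervals)))]
                mid = (ts + te_) // 2
                s = mid - length // 2
            else:
                s = int(rng.integers(1, len(genome) - length - 1))
            e = s + length
            if ok(s, e):
                placed.append((s, e))
                done = True
                break
        if not done:
            raise PlacementError("could not place disjoint assembly gaps")
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    for s, e in placed:
        arr[s:e] = ord("N")
    placed.sort()
    return arr.tobytes().decode("ascii"), placed


# ---------------------------------------------------------------------------
# synthetic TE library

_FAMILY_LENGTHS = {
    "DTT": (250, 550),
    "DTH": (300, 700),
    "DTM": (520, 1400),
    "DTC": (1200, 2400),
    "DTA": (350, 620),
}


def _concrete_motif(motif_positions) -> str:
    return "".join(sorted(s)[0] for s in motif_positions)


def synthetic_library(seed: int | np.random.Generator) -> TELibrary:
    """A small classified library: two families per superfamily, each with
    the superfamily's TIR consensus at its termini."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lib = TELibrary()
    for code, lengths in _FAMILY_LENGTHS.items():
        prof = SUPERFAMILY_PROFILES[code]
        tir = _concrete_motif(prof.tir_positions)
        from ._seq import revcomp

        for i, length in enumerate(lengths, start=1):
            inner = _random_seq(rng, length - 2 * len(tir))
            seq = tir + inner + revcomp(tir)
            lib.add(TEConsensus(f"{code}_SIM{i}", code, seq))
    return lib


# ---------------------------------------------------------------------------
# full pair simulation


@dataclass
class _Edit:
    base_pos: int
    delta: int = 0


def _shift(sorted_edits: list[_Edit], x: int) -> int:
    total = 0
    for e in sorted_edits:
        if e.base_pos < x:
            total += e.delta
        else:
            break
    return total


def simulate_pair(config: SimulationConfig, library: TELibrary | None = None) -> SimulatedPair:
    """Generate a diverged genome pair with planted TE activity and a
    ground-truth log.  Deterministic for a fixed config (seed mandatory)."""
    rng = np.random.default_rng(config.seed)
    lib = library if library is not None else synthetic_library(rng)
    families = list(lib)
    ancestor = make_ancestor(config.genome_length, config.gc_fraction, rng)

    # --- anchor layout: jittered grid keeps features well separated -------
    n_planted = config.n_planted_copies_per_family * len(families)
    n_anchor = n_planted + config.n_insertions
    usable = config.genome_length - 24_000
    spacing = usable / max(n_anchor, 1)
    if spacing < 3500:
        raise ParameterError(
            "genome too short for the requested feature count "
            f"(anchor spacing {spacing:.0f} bp < 3500)"
        )
    jitter = int(min(700, (spacing - 3200) / 2))
    anchors = (
        12_000
        + (np.arange(n_anchor) * spacing).astype(np.int64)
        + rng.integers(-jitter, jitter + 1, size=n_anchor)
    )
    rng.shuffle(anchors)
    planted_anchor = anchors[:n_planted]
    insertion_anchor = anchors[n_planted:]

    # --- plant shared copies (descending keeps earlier coords valid) -----
    order = np.argsort(planted_anchor)[::-1]
    base = ancestor
    planted: list[PlantedLocus] = []
    applied: list[tuple[int, int, PlantedLocus]] = []  # (pos, delta, locus)
    for idx in order:
        fam = families[int(rng.integers(0, len(families)))]
        pos = int(planted_anchor[idx])
        prof = fam.profile
        new, ev = apply_insertion(base, fam, pos, prof, rng)
        delta = len(new) - len(base)
        base = new
        k = prof.tsd_length
        loc = PlantedLocus(fam.family_name, ev.tsd_sequence)
        applied.append((ev.locus_a_start, delta, loc))
        loc.base_start = ev.locus_a_start + k  # TE body start (pre-shift)
        loc.base_end = ev.locus_a_end - k
    # ascending prefix-shift to final base coordinates
    applied.sort(key=lambda t: t[0])
    shift = 0
    plant_pos: list[int] = []
    plant_cum: list[int] = []
    for pos, delta, loc in applied:
        loc.base_start += shift
        loc.base_end += shift
        shift += delta
        plant_pos.append(pos)
        plant_cum.append(shift)
        planted.append(loc)
    # insertion anchors were drawn on the ancestor grid; carry them into
    # base coordinates so planting cannot squeeze events together
    if len(plant_pos):
        idx = np.searchsorted(plant_pos, insertion_anchor, side="right")
        cum = np.concatenate(([0], np.asarray(plant_cum)))
        insertion_anchor = insertion_anchor + cum[idx]

    # --- event plan -------------------------------------------------------
    fp = config.footprint_params
    n_exc_total = (
        config.n_excisions + config.n_precise_excisions + config.n_internal_deletions
    )
    if n_exc_total > len(planted):
        raise ParameterError("more excision-type events than planted loci")
    loci_idx = rng.permutation(len(planted))
    internal_candidates = [
        i for i in loci_idx if planted[i].base_end - planted[i].base_start >= 260
    ]
    internal_set = internal_candidates[: config.n_internal_deletions]
    rest = [i for i in loci_idx if i not in set(internal_set)]
    excision_set = rest[: config.n_excisions]
    precise_set = rest[config.n_excisions : config.n_excisions + config.n_precise_excisions]

    @dataclass
    class _Planned:
        kind: str
        species: str
        locus: PlantedLocus | None = None
        family: TEConsensus | None = None
        base_pos: int = 0
        event: GroundTruthEvent | None = None
        final_start: int = 0
        final_end: int = 0

    plan: list[_Planned] = []
    for i in excision_set:
        plan.append(
            _Planned("excision", "A" if rng.random() < 0.5 else "B", locus=planted[i],
                     base_pos=planted[i].base_start)
        )
    for i in precise_set:
        plan.append(
            _Planned("precise-excision", "A" if rng.random() < 0.5 else "B",
                     locus=planted[i], base_pos=planted[i].base_start)
        )
    for i in internal_set:
        plan.append(
            _Planned("internal-deletion", "A" if rng.random() < 0.5 else "B",
                     locus=planted[i], base_pos=planted[i].base_start)
        )
    for pos in insertion_anchor:
        fam = families[int(rng.integers(0, len(families)))]
        plan.append(
            _Planned("insertion", "A" if rng.random() < 0.5 else "B", family=fam,
                     base_pos=int(pos))
        )

    # --- apply structural edits per species -------------------------------
    genomes: dict[str, str] = {}
    edits_by_species: dict[str, list[_Edit]] = {"A": [], "B": []}
    eid = 0
    events: list[GroundTruthEvent] = []
    for species in ("A", "B"):
        g = base
        todo = sorted(
            (p for p in plan if p.species == species),
            key=lambda p: p.base_pos,
            reverse=True,
        )
        for p in todo:
            before = len(g)
            if p.kind == "insertion":
                g, ev = apply_insertion(
                    g, p.family, p.base_pos, p.family.profile, rng, event_id=eid,
                    species=species,
                )
                p.final_start = ev.locus_a_start if species == "A" else ev.locus_b_start
                p.final_end = ev.locus_a_end if species == "A" else ev.locus_b_end
            elif p.kind == "excision":
                g, ev = apply_excision(
                    g, p.locus, fp, rng, event_id=eid, species=species
                )
                p.locus.excised_in = species
                p.final_start = p.locus.base_start - len(p.locus.tsd)
                p.final_end = p.final_start
            elif p.kind == "precise-excision":
                g, ev = apply_excision(
                    g, p.locus, fp, rng, event_id=eid, species=species,
                    kind="precise-excision",
                )
                p.locus.excised_in = species
                p.final_start = p.locus.base_start - len(p.locus.tsd)
                p.final_end = p.final_start
            else:  # internal deletion
                s, e = p.locus.base_start, p.locus.base_end
                te_len = e - s
                cut = int(rng.integers(60, max(61, int(te_len * 0.6))))
                off = int(rng.integers(5, te_len - cut - 5))
                g = g[: s + off] + g[s + off + cut :]
                ev = GroundTruthEvent(
                    eid, "internal-deletion", species, s + off, s + off,
                    s + off, s + off, family=p.locus.family,
                    deleted_bp=cut,
                )
                p.locus.excised_in = ""  # copy still present, just shorter
                p.final_start = s + off
                p.final_end = s + off
            delta = len(g) - before
            edits_by_species[species].append(_Edit(p.base_pos, delta))
            p.event = ev
            events.append(ev)
            eid += 1
        genomes[species] = g

    for sp in ("A", "B"):
        edits_by_species[sp].sort(key=lambda e: e.base_pos)

    # --- finalize structural coordinates in both species ------------------
    def final_coord(species: str, x: int) -> int:
        return x + _shift(edits_by_species[species], x)

    recent: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    for p in plan:
        ev = p.event
        own_shift = _shift(edits_by_species[p.species], p.base_pos)
        other = "B" if p.species == "A" else "A"
        if p.kind == "insertion":
            # final_start is the relocated site (first TSD copy), so the
            # other species' empty site is the same base coordinate
            s = p.final_start + own_shift
            e = p.final_end + own_shift
            op = final_coord(other, p.final_start)
            if p.species == "A":
                ev.locus_a_start, ev.locus_a_end = s, e
                ev.locus_b_start = ev.locus_b_end = op
            else:
                ev.locus_b_start, ev.locus_b_end = s, e
                ev.locus_a_start = ev.locus_a_end = op
            recent[p.species].append((s, e))
        elif p.kind in ("excision", "precise-excision"):
            fpz = p.final_start + own_shift  # footprint anchor in acting species
            k = len(p.locus.tsd)
            os_ = final_coord(other, p.locus.base_start - k)
            oe_ = final_coord(other, p.locus.base_end + k)
            if p.species == "A":
                ev.locus_a_start = ev.locus_a_end = fpz
                ev.locus_b_start, ev.locus_b_end = os_, oe_
            else:
                ev.locus_b_start = ev.locus_b_end = fpz
                ev.locus_a_start, ev.locus_a_end = os_, oe_
            if ev.filler_bp:
                recent[p.species].append((fpz + k, fpz + k + ev.filler_bp + k))
        else:  # internal deletion: other species bears the extra interior
            jn = p.final_start + own_shift
            os_ = final_coord(other, p.final_start)
            oe_ = final_coord(other, p.final_start + ev.deleted_bp)
            if p.species == "A":
                ev.locus_a_start = ev.locus_a_end = jn
                ev.locus_b_start, ev.locus_b_end = os_, oe_
            else:
                ev.locus_b_start = ev.locus_b_end = jn
                ev.locus_a_start, ev.locus_a_end = os_, oe_
    for loc in planted:
        loc.a_start = final_coord("A", loc.base_start)
        loc.a_end = final_coord("A", loc.base_end)
        loc.b_start = final_coord("B", loc.base_start)
        loc.b_end = final_coord("B", loc.base_end)

    # --- background indels (kept clear of structural footprints) ----------
    protect = 150
    for species in ("A", "B"):
        zones = []
        for ev in events:
            if ev.kind == "background-indel":
                continue
            s = ev.locus_a_start if species == "A" else ev.locus_b_start
            e = ev.locus_a_end if species == "A" else ev.locus_b_end
            zones.append((s - protect, e + protect))
        g, bg = _apply_background_indels(
            genomes[species], config.background_indel_rate, rng, species, zones,
            start_id=eid,
        )
        eid += len(bg)
        # shift all recorded coordinates of this species past each indel
        deltas = sorted(
            ((b.locus_a_start if species == "A" else b.locus_b_start),
             b.filler_bp - b.deleted_bp)
            for b in bg
        )

        def bump(x: int) -> int:
            t = 0
            for ppos, d in deltas:
                if ppos <= x:
                    t += d
                else:
                    break
            return t

        for ev in events:
            if ev.kind == "background-indel":
                continue
            if species == "A":
                ev.locus_a_start += bump(ev.locus_a_start)
                ev.locus_a_end += bump(ev.locus_a_end)
            else:
                ev.locus_b_start += bump(ev.locus_b_start)
                ev.locus_b_end += bump(ev.locus_b_end)
        for loc in planted:
            if species == "A":
                loc.a_start += bump(loc.a_start)
                loc.a_end += bump(loc.a_end)
            else:
                loc.b_start += bump(loc.b_start)
                loc.b_end += bump(loc.b_end)
        recent[species] = [(s + bump(s), e + bump(e)) for s, e in recent[species]]
        genomes[species] = g
        events.extend(bg)

    # --- substitutions on ancestral material ------------------------------
    for species in ("A", "B"):
        g = genomes[species]
        protected = np.zeros(len(g), bool)
        for s, e in recent[species]:
            protected[max(0, s) : min(len(g), e)] = True
        genomes[species] = _substitute(g, config.substitution_rate, rng, protected)

    # --- assembly gaps in species B ---------------------------------------
    gaps: list[tuple[int, int]] = []
    if config.n_gaps:
        te_iv = [
            (loc.b_start, loc.b_end)
            for loc in planted
            if loc.excised_in != "B" and loc.b_end - loc.b_start > 100
        ]
        zones = []
        for ev in events:
            if ev.kind == "background-indel":
                continue
            zones.append((ev.locus_b_start - 1000, ev.locus_b_end + 1000))
        te_iv = [
            iv for iv in te_iv
            if not any(iv[0] < z[1] and z[0] < iv[1] for z in zones)
        ]
        genomes["B"], gaps = add_gaps(
            genomes["B"], config.n_gaps, config.gap_length_range, rng,
            te_intervals=te_iv, fraction_over_te=config.gap_te_fraction,
            forbidden=zones,
        )

    return SimulatedPair(
        genomes["A"], genomes["B"], events, planted, lib, gaps, config
    )


# ---------------------------------------------------------------------------
# fixture I/O


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_TRUTH_COLUMNS = [f.name for f in dataclasses.fields(GroundTruthEvent)]


def emit_fixture(pair: SimulatedPair, out_dir: str | Path) -> dict[str, Path]:
    """Write genomeA.fasta, genomeB.fasta, te_library.fasta, truth.tsv and
    the config as YAML; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_a": out / "genomeA.fasta",
        "genome_b": out / "genomeB.fasta",
        "library": out / "te_library.fasta",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_fasta(paths["genome_a"], {"chr1": pair.genome_a})
    write_fasta(paths["genome_b"], {"chr1": pair.genome_b})
    pair.library.write_fasta(paths["library"])
    rows = [dataclasses.asdict(ev) for ev in pair.events]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(
        paths["truth"], sep="\t", index=False
    )
    cfg = dataclasses.asdict(pair.config)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths


def load_truth(path: str | Path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for key in ("tsd_sequence", "filler_sequence", "family"):
            d[key] = str(d[key]) if d[key] != "" else ""
        out.append(GroundTruthEvent(**d))
    return out
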