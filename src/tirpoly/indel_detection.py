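"""Presence/absence polymorphism extraction from assembled alignments.

A polymorphism is a maximal gap run longer than 50 bp in either row of the
chromosome alignment, attributed to the gap-free (sequence-bearing)
species.  Events separated by fewer than 4 aligned columns are fused into
one; events bordering assembly gaps (N runs) are discarded (but kept in a
side channel for the hidden-TE extrapolation), and events consisting of
more than 80% Ns are flagged and excluded from footprint classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._seq import n_run_intervals
from .genome_alignment import AlignedBlock, ChromosomeAlignment


@dataclass
class IndelEvent:
    """One presence/absence polymorphism (> 50 bp).

    ``bearing_species`` carries the extra sequence; ``empty_site_position``
    is the coordinate of the gap in the other genome.  Coordinates are
    0-based half-open in the respective genome.
    """

    bearing_species: str  # "A" | "B"
    start: int  # in bearing genome
    end: int
    empty_site_position: int  # in the other genome
    extra_sequence: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    n_fraction: float = 0.0
    borders_gap: bool = False
    query_chrom: str = "chr1"
    target_chrom: str = "chr1"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.extra_sequence:
            self.n_fraction = self.extra_sequence.count("N") / len(self.extra_sequence)


def _block_gap_events(
    block: AlignedBlock, query_species: str, target_species: str, min_len: int
) -> list[tuple[str, int, int, int, str]]:
    """(bearing, start, end, empty_pos, extra_seq) per gap run > min_len."""
    events = []
    qpos = block.query_start
    tpos = block.target_start
    run_row = None  # which row currently holds '-'
    run_start_other = 0
    run_start_col = 0
    cols = len(block.query_row)
    out: list[tuple[str, int, int, int, str]] = []

    def close(run_row, s_other, e_other, empty_pos):
        if e_other - s_other > min_len:
            out.append((run_row, s_other, e_other, empty_pos))

    i = 0
    qr = block.query_row
    tr = block.target_row
    runs: list[tuple[str, int, int, int]] = []
    while i < cols:
        if qr[i] == "-":
            s_t = tpos
            e_pos_q = qpos
            while i < cols and qr[i] == "-":
                if tr[i] != "-":
                    tpos += 1
                i += 1
            runs.append(("target", s_t, tpos, e_pos_q))
        elif tr[i] == "-":
            s_q = qpos
            e_pos_t = tpos
            while i < cols and tr[i] == "-":
                if qr[i] != "-":
                    qpos += 1
                i += 1
            runs.append(("query", s_q, qpos, e_pos_t))
        else:
            qpos += 1
            tpos += 1
            i += 1
    for which, s, e, empty in runs:
        if e - s > min_len:
            bearing = query_species if which == "query" else target_species
            out.append((bearing, s, e, empty, ""))
    return out


def scan_indels(
    ca: ChromosomeAlignment,
    query_genome: dict[str, str],
    target_genome: dict[str, str],
    query_species: str = "A",
    target_species: str = "B",
    min_len: int = 50,
    flank_bp: int = 500,
) -> list[IndelEvent]:
    """Extract every gap run longer than ``min_len`` as an IndelEvent.

    The event is attributed to the species whose row carries sequence;
    flanking genomic context (up to ``flank_bp`` each side) is attached.
    """
    events: list[IndelEvent] = []
    for block in ca.blocks:
        for bearing, s, e, empty, _ in _block_gap_events(
            block, query_species, target_species, min_len
        ):
            genome = (
                query_genome[ca.query_chrom]
                if bearing == query_species
                else target_genome[ca.target_chrom]
            )
            events.append(
                IndelEvent(
                    bearing_species=bearing,
                    start=s,
                    end=e,
                    empty_site_position=empty,
                    extra_sequence=genome[s:e],
                    upstream_flank=genome[max(0, s - flank_bp) : s],
                    downstream_flank=genome[e : e + flank_bp],
                    query_chrom=ca.query_chrom,
                    target_chrom=ca.target_chrom,
                )
            )
    events.sort(key=lambda ev: (ev.bearing_species, ev.start))
    return events


def merge_adjacent(
    indels: list[IndelEvent],
    genomes: dict[str, dict[str, str]] | None = None,
    max_separation: int = 4,
) -> list[IndelEvent]:
    """Fuse same-species event chains separated by < max_separation bp.

    Separation is measured in the bearing genome between the end of one
    event and the start of the next; the fused extra_sequence includes the
    intervening bases.  Events of opposite bearing species never merge.
    Idempotent.
    """
    out: list[IndelEvent] = []
    for species in ("A", "B"):
        chain = sorted(
            (ev for ev in indels if ev.bearing_species == species),
            key=lambda ev: (ev.query_chrom, ev.start),
        )
        i = 0
        while i < len(chain):
            cur = chain[i]
            j = i + 1
            while (
                j < len(chain)
                and chain[j].query_chrom == cur.query_chrom
                and chain[j].start - cur.end < max_separation
            ):
                nxt = chain[j]
                if genomes is not None:
                    chrom = cur.query_chrom if species == "A" else cur.target_chrom
                    seq = genomes[species][chrom]
                    extra = seq[cur.start : nxt.end]
                else:
                    spacer_len = max(0, nxt.start - cur.end)
                    extra = cur.extra_sequence + "N" * spacer_len + nxt.extra_sequence
                cur = IndelEvent(
                    bearing_species=species,
                    start=cur.start,
                    end=nxt.end,
                    empty_site_position=min(
                        cur.empty_site_position, nxt.empty_site_position
                    ),
                    extra_sequence=extra,
                    upstream_flank=cur.upstream_flank,
                    downstream_flank=nxt.downstream_flank,
                    query_chrom=cur.query_chrom,
                    target_chrom=cur.target_chrom,
                )
                j += 1
            out.append(cur)
            i = j
    out.sort(key=lambda ev: (ev.bearing_species, ev.start))
    return out


def drop_gap_adjacent(
    indels: list[IndelEvent],
    genomes: dict[str, dict[str, str]],
    window: int = 10,
    n_threshold: float = 0.80,
) -> tuple[list[IndelEvent], list[IndelEvent]]:
    """Remove events touching assembly gaps (N runs).

    An event is dropped when its extra sequence or its immediate flanks
    (within ``window`` bp) contain an N run, or when its N fraction exceeds
    ``n_threshold``.  Returns (kept, dropped); the dropped side channel
    feeds the hidden-TE gap-attribution estimate.
    """
    kept: list[IndelEvent] = []
    dropped: list[IndelEvent] = []
    for ev in indels:
        chrom = ev.query_chrom if ev.bearing_species == "A" else ev.target_chrom
        seq = genomes[ev.bearing_species][chrom]
        s = max(0, ev.start - window)
        e = min(len(seq), ev.end + window)
        touches = "N" in seq[s:e]
        if touches or classify_n_content(ev, n_threshold):
            ev.borders_gap = touches
            dropped.append(ev)
        else:
            kept.append(ev)
    return kept, dropped


def classify_n_content(event: IndelEvent, threshold: float = 0.80) -> bool:
    """True iff the event's N fraction strictly exceeds the threshold.

    Such events are excluded from footprint classification but counted for
    the hidden-TE extrapolation."""
    return event.n_fraction > threshold


def events_to_table(indels: list[IndelEvent]) -> pd.DataFrame:
    rows = [
        {
            "bearing_species": ev.bearing_species,
            "chrom": ev.query_chrom if ev.bearing_species == "A" else ev.target_chrom,
            "start": ev.start,
            "end": ev.end,
            "length": ev.length,
            "empty_site_position": ev.empty_site_position,
            "n_fraction": round(ev.n_fraction, 4),
            "borders_gap": ev.borders_gap,
        }
        for ev in indels
    ]
    return pd.DataFrame(rows)
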