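"""End-to-end convenience layer: align two assemblies, call and classify
TE polymorphisms, and summarise."""
from __future__ import annotations

from dataclasses import dataclass, field

from .footprint import (
    ClassificationContext,
    PolymorphismCall,
    classify_events,
)
from .genome_alignment import ChromosomeAlignment, align_genomes
from .indel_detection import IndelEvent, drop_gap_adjacent, merge_adjacent, scan_indels
from .te_model import TELibrary


@dataclass
class PipelineResult:
    alignments: dict[tuple[str, str], ChromosomeAlignment]
    events: list[IndelEvent]  # surviving the filter chain
    gap_adjacent: list[IndelEvent]  # side channel for the hidden-TE estimate
    calls: list[PolymorphismCall]
    events_without_te: list[IndelEvent]

    @property
    def aligned_query_bp(self) -> int:
        return sum(ca.aligned_query_bp for ca in self.alignments.values())


def run_pair(
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    library: TELibrary,
    min_indel: int = 50,
    merge_separation: int = 4,
) -> PipelineResult:
    """Species A is the query, species B the target; events borne by either
    species surface as gap runs in the opposite row."""
    genomes = {"A": genome_a, "B": genome_b}
    alignments = align_genomes(genome_a, genome_b)
    events: list[IndelEvent] = []
    for ca in alignments.values():
        events.extend(
            scan_indels(ca, genome_a, genome_b, min_len=min_indel)
        )
    events = merge_adjacent(events, genomes, max_separation=merge_separation)
    kept, dropped = drop_gap_adjacent(events, genomes)
    ctx = ClassificationContext(genomes, library)
    calls, no_te = classify_events(kept, ctx)
    return PipelineResult(alignments, kept, dropped, calls, no_te)
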