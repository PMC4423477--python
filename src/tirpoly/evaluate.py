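"""Recovery scoring of pipeline calls against the simulator's ground truth.

A precise excision restores the pre-insertion site, so its expected call is
an insertion borne by the other species; asserting that forced mislabel is
part of the contract.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .footprint import PolymorphismCall
from .simulate import GroundTruthEvent

# truth kind -> the verdict a correct comparative classifier must return
EXPECTED_VERDICT = {
    "insertion": "insertion",
    "excision-perfect": "excision-perfect",
    "excision-deletion": "excision-deletion",
    "excision-filler": "excision-filler",
    "excision-both": "excision-both",
    "precise-excision": "insertion",
    "internal-deletion": "internal-deletion",
}


def _truth_bearing(ev: GroundTruthEvent) -> tuple[str, int, int]:
    """(bearing species, start, end) of the extra sequence for one truth
    event."""
    if ev.kind == "insertion":
        sp = ev.species
    else:  # excisions, precise, internal: the non-acting species bears it
        sp = "B" if ev.species == "A" else "A"
    if sp == "A":
        return sp, ev.locus_a_start, ev.locus_a_end
    return sp, ev.locus_b_start, ev.locus_b_end


@dataclass
class MatchedEvent:
    truth: GroundTruthEvent
    call: PolymorphismCall | None
    expected_verdict: str

    @property
    def detected(self) -> bool:
        return self.call is not None

    @property
    def verdict_correct(self) -> bool:
        return self.call is not None and self.call.verdict == self.expected_verdict


@dataclass
class RecoveryReport:
    matches: list[MatchedEvent]

    def subset(self, kinds) -> "RecoveryReport":
        return RecoveryReport([m for m in self.matches if m.truth.kind in kinds])

    @property
    def n_truth(self) -> int:
        return len(self.matches)

    @property
    def n_detected(self) -> int:
        return sum(m.detected for m in self.matches)

    @property
    def n_correct(self) -> int:
        return sum(m.verdict_correct for m in self.matches)

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_truth if self.n_truth else 0.0

    @property
    def verdict_accuracy(self) -> float:
        return self.n_correct / self.n_truth if self.n_truth else 0.0

    def by_kind(self) -> dict[str, tuple[int, int, int]]:
        out: dict[str, list[int]] = {}
        for m in self.matches:
            rec = out.setdefault(m.truth.kind, [0, 0, 0])
            rec[0] += 1
            rec[1] += m.detected
            rec[2] += m.verdict_correct
        return {k: tuple(v) for k, v in out.items()}

    def deletion_lengths(self) -> tuple[list[int], list[int]]:
        """(truth, measured) deletion lengths over matched excisions."""
        t, m_ = [], []
        for m in self.matches:
            if m.truth.kind in ("excision-deletion", "excision-both") and m.detected:
                t.append(m.truth.deleted_bp)
                m_.append(m.call.deleted_bp)
        return t, m_

    def filler_lengths(self) -> tuple[list[int], list[int]]:
        t, m_ = [], []
        for m in self.matches:
            if m.truth.kind in ("excision-filler", "excision-both") and m.detected:
                t.append(m.truth.filler_bp)
                m_.append(m.call.filler_bp)
        return t, m_


def end_to_end_recovery(seed: int, zero_background: bool = False, **overrides):
    """Simulate a genome pair under the default study conditions, run the
    full pipeline, and score recovery against the ground truth.

    Returns (report, pipeline_result, simulated_pair)."""
    from .pipeline import run_pair
    from .simulate import SimulationConfig, simulate_pair

    kwargs = dict(seed=seed)
    if zero_background:
        kwargs.update(substitution_rate=0.0, background_indel_rate=0.0)
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    pair = simulate_pair(cfg)
    result = run_pair({"chr1": pair.genome_a}, {"chr1": pair.genome_b}, pair.library)
    report = match_calls(pair.events, result.calls)
    return report, result, pair


def match_calls(
    truth: list[GroundTruthEvent],
    calls: list[PolymorphismCall],
    tolerance: int = 200,
) -> RecoveryReport:
    """Pair every planted transposition-scale truth event with the call at
    the same bearing-species locus (interval overlap, or midpoints within
    ``tolerance`` bp)."""
    matches: list[MatchedEvent] = []
    used: set[int] = set()
    for ev in truth:
        if ev.kind == "background-indel":
            continue
        sp, ts, te = _truth_bearing(ev)
        best = None
        best_d = None
        for i, c in enumerate(calls):
            if i in used or c.event.bearing_species != sp:
                continue
            cs, ce = c.event.start, c.event.end
            overlap = min(te, ce) - max(ts, cs)
            mid_d = abs((ts + te) // 2 - (cs + ce) // 2)
            if overlap > 0 or mid_d <= tolerance:
                d = -overlap if overlap > 0 else mid_d
                if best is None or d < best_d:
                    best = i
                    best_d = d
        call = calls[best] if best is not None else None
        if best is not None:
            used.add(best)
        matches.append(MatchedEvent(ev, call, EXPECTED_VERDICT[ev.kind]))
    return RecoveryReport(matches)
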