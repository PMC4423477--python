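"""Verdict decision tree and footprint measurement on constructed loci.

Each case builds the bearing locus (flank-TSD-TE-TSD-flank) and the
corresponding empty-site sequence explicitly, then presents the event the
aligner would extract.
"""
import numpy as np
import pytest

from tirpoly.errors import ContractError
from tirpoly.footprint import (
    ClassificationContext,
    classify_events,
    classify_polymorphism,
    detect_tsd,
    summarize_footprints,
)
from tirpoly.indel_detection import IndelEvent
from tirpoly.te_model import SUPERFAMILY_PROFILES, TEAnnotation

from conftest import random_seq


@pytest.fixture(scope="module")
def scene(sim_library):
    """Bearing/empty genome pairs for every footprint class, one shared
    random backdrop."""
    rng = np.random.default_rng(99)
    fam = sim_library["DTH_SIM2"]  # Harbinger: TAA/TTA, 3-bp TSD; 700 bp
    te = fam.sequence
    k = 3
    tsd = "TAA"
    L = random_seq(rng, 4000)
    R = random_seq(rng, 4000)
    donor = random_seq(rng, 12)
    bearing = L + tsd + te + tsd + R
    cases = {
        "insertion": L + tsd + R,
        "perfect": L + tsd + tsd + R,
        "deletion": L + tsd + R[25:],          # right side lost TSD + 25 bp
        "filler": L + tsd + donor + tsd + R,
        "both": L + tsd + donor + R[25:],
        "extreme": L + tsd + R[2479:],         # the multi-kb one-sided case
    }
    return dict(
        fam=fam, te=te, k=k, tsd=tsd, L=L, R=R, donor=donor,
        bearing=bearing, cases=cases, library=sim_library,
    )


def _classify(scene, empty_key, x_shift=0):
    """Build the IndelEvent as the aligner would (gap run = TSD + TE) and
    classify it."""
    L, te, k = scene["L"], scene["te"], scene["k"]
    bearing = scene["bearing"]
    empty = scene["cases"][empty_key]
    s = len(L)  # event starts at the first TSD copy
    e = s + k + len(te)
    ev = IndelEvent(
        bearing_species="A", start=s, end=e,
        empty_site_position=len(L),
        extra_sequence=bearing[s:e],
        upstream_flank=bearing[:s][-500:],
        downstream_flank=bearing[e : e + 500],
    )
    ctx = ClassificationContext(
        {"A": {"chr1": bearing}, "B": {"chr1": empty}}, scene["library"]
    )
    calls, no_te = classify_events([ev], ctx)
    assert len(calls) == 1
    return calls[0]


def test_insertion_signature(scene):
    c = _classify(scene, "insertion")
    assert c.verdict == "insertion"
    assert c.acting_species == "A"
    assert c.tsd.found and c.tsd.sequence == "TAA"
    assert c.deleted_bp == 0 and c.filler_bp == 0


def test_perfect_excision_signature(scene):
    c = _classify(scene, "perfect")
    assert c.verdict == "excision-perfect"
    assert c.acting_species == "B"
    assert c.deleted_bp == 0 and c.filler_bp == 0


def test_excision_with_flanking_deletion(scene):
    c = _classify(scene, "deletion")
    assert c.verdict == "excision-deletion"
    assert c.deleted_bp == 25


def test_excision_with_filler(scene):
    c = _classify(scene, "filler")
    assert c.verdict == "excision-filler"
    assert c.filler_bp == len(scene["donor"])
    assert c.filler_sequence == scene["donor"]


def test_excision_with_deletion_and_filler(scene):
    c = _classify(scene, "both")
    assert c.verdict == "excision-both"
    # a short filler's edges can chance-match the deleted flank at the
    # pairing the aligner picks, bleeding a base or two between the counts
    assert abs(c.deleted_bp - 25) <= 3
    assert abs(c.filler_bp - len(scene["donor"])) <= 3


def test_extreme_one_sided_deletion_measured_exactly(scene):
    """A deletion of thousands of bp on one side, precise at the other
    border, is still recognised and measured."""
    c = _classify(scene, "extreme")
    assert c.verdict == "excision-deletion"
    assert c.deleted_bp == 2479


def test_maximum_observed_filler_measured_exactly(sim_library):
    rng = np.random.default_rng(123)
    fam = sim_library["DTT_SIM1"]
    te = fam.sequence
    L, R = random_seq(rng, 3000), random_seq(rng, 3000)
    # place the TSD on a TA site
    tsd = "TA"
    filler = random_seq(rng, 123)
    bearing = L + tsd + te + tsd + R
    empty = L + tsd + filler + tsd + R
    s, e = len(L), len(L) + 2 + len(te)
    ev = IndelEvent("A", s, e, len(L), bearing[s:e])
    ctx = ClassificationContext(
        {"A": {"chr1": bearing}, "B": {"chr1": empty}}, sim_library
    )
    calls, _ = classify_events([ev], ctx)
    assert calls[0].verdict == "excision-filler"
    assert calls[0].filler_bp == 123


def test_internal_deletion_not_transposition(scene):
    """An event strictly inside a TE present in both species is an
    internal deletion."""
    fam, te, k, tsd = scene["fam"], scene["te"], scene["k"], scene["tsd"]
    L, R = scene["L"], scene["R"]
    bearing = scene["bearing"]
    cut_s, cut_e = 200, 480  # interior chunk of the TE
    empty = L + tsd + te[:cut_s] + te[cut_e:] + tsd + R
    s = len(L) + k + cut_s
    e = len(L) + k + cut_e
    ev = IndelEvent("A", s, e, len(L) + k + cut_s, bearing[s:e])
    ctx = ClassificationContext(
        {"A": {"chr1": bearing}, "B": {"chr1": empty}}, scene["library"]
    )
    calls, _ = classify_events([ev], ctx)
    assert calls[0].verdict == "internal-deletion"


def test_precise_excision_reported_as_insertion(scene):
    """A precise excision restores the pre-insertion site; comparative
    analysis must (and does) call the locus an insertion in the bearing
    species."""
    c = _classify(scene, "insertion")  # precise-excision empty == insertion empty
    assert c.verdict == "insertion"


def test_no_annotation_is_contract_error(scene):
    ev = IndelEvent("A", 100, 200, 100, scene["bearing"][100:200])
    ctx = ClassificationContext(
        {"A": {"chr1": scene["bearing"]}, "B": {"chr1": scene["cases"]["insertion"]}},
        scene["library"],
    )
    with pytest.raises(ContractError):
        classify_polymorphism(ev, [], ctx)


def test_detect_tsd_negative_control(scene, rng):
    """No duplication at either border -> not found."""
    seq = random_seq(rng, 2000)
    ev = IndelEvent("A", 800, 1200, 800, seq[800:1200])
    ann = TEAnnotation(0, 400, "DTH_SIM1", "DTH", 400, 0.9)
    call = detect_tsd(ev, ann, SUPERFAMILY_PROFILES["DTH"], seq)
    assert not call.found


def test_verdict_partition_sums(scene):
    calls = [
        _classify(scene, key)
        for key in ("insertion", "perfect", "deletion", "filler", "both")
    ]
    summary = summarize_footprints(calls)
    assert summary.n_calls == 5
    assert sum(summary.verdict_counts.values()) == 5


# ---------------------------------------------------------------------------
# summaries over a reconstructed published-scale call set


def _mk_call(verdict, deleted=0, filler=0):
    ev = IndelEvent("A", 0, 100, 0, "A" * 100)
    from tirpoly.footprint import PolymorphismCall, TSDCall

    return PolymorphismCall(
        ev, "DTT_X", "DTT", verdict, "B", TSDCall(True, "TA", 2),
        deleted_bp=deleted, filler_bp=filler, filler_sequence="G" * filler,
    )


def build_published_scale_calls():
    """A call set reproducing the published marginals: 8 perfect, 43
    deletion-only (one extreme of 2,479 bp), 58 filler-only, 9 both;
    non-extreme deletions total 926 bp and fillers total 880 bp."""
    calls = [_mk_call("excision-perfect") for _ in range(8)]
    # 51 non-extreme deletion-bearing events (42 deletion-only + 9 both)
    # summing 926 bp; one extreme deletion-only event of 2,479 bp
    deletion_only = [19] * 8 + [18] * 34
    calls += [_mk_call("excision-deletion", deleted=d) for d in deletion_only]
    calls += [_mk_call("excision-deletion", deleted=2479)]
    # 67 filler-bearing events (58 filler-only + 9 both) summing 880 bp,
    # spanning the observed 1-123 bp range
    filler_only = [1, 123] + [12] * 56
    both = [9] * 6 + [10] * 3
    calls += [_mk_call("excision-filler", filler=f) for f in filler_only]
    calls += [_mk_call("excision-both", deleted=18, filler=f) for f in both]
    return calls


@pytest.fixture(scope="module")
def published_scale_calls():
    return build_published_scale_calls()


def test_summary_reproduces_published_arithmetic(published_scale_calls):
    s = summarize_footprints(published_scale_calls, outlier_threshold=1000)
    assert s.verdict_counts["excision-perfect"] == 8
    assert s.verdict_counts["excision-deletion"] == 43
    assert s.verdict_counts["excision-filler"] == 58
    assert s.verdict_counts["excision-both"] == 9
    assert s.total_deleted_bp_excluding_outliers == 926
    assert s.total_deleted_bp == 926 + 2479 == 3405
    assert s.n_outliers == 1
    assert s.mean_deleted_per_deletion_event == pytest.approx(926 / 51)
    assert s.total_filler_bp == 880
    assert s.mean_filler_bp == pytest.approx(880 / 67)
    assert s.min_filler_bp == 1 and s.max_filler_bp == 123


def test_summary_empty_call_list():
    s = summarize_footprints([])
    assert s.n_calls == 0
    assert s.total_deleted_bp == 0
    assert s.mean_filler_bp == 0.0
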