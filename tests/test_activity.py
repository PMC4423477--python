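"""Insertion:excision ratio statistics, activity/abundance grouping,
fixation arithmetic, gap attribution and gene-context classification."""
import math

import numpy as np
import pytest

from tirpoly.activity import (
    GapAttribution,
    GeneModel,
    binomial_two_sided,
    extrapolate_hidden_te_gaps,
    fixation_rate,
    gene_context,
    ratio_test,
    relative_activity_table,
    simulate_transmission_ratio,
)
from tirpoly.errors import ContractError
from tirpoly.footprint import PolymorphismCall, TSDCall
from tirpoly.indel_detection import IndelEvent

from conftest import random_seq


# ---------------------------------------------------------------------------
# ratio tests


@pytest.mark.parametrize(
    "ins,exc,ratio_2dp",
    [(59, 21, 2.81), (84, 19, 4.42), (90, 11, 8.18), (26, 3, 8.67), (30, 7, 4.29)],
)
def test_published_superfamily_ratios(ins, exc, ratio_2dp):
    rt = ratio_test(ins, exc)
    assert round(rt.ratio, 2) == ratio_2dp


def test_zero_excisions_ratio_undefined_but_test_runs():
    rt = ratio_test(5, 0)
    assert not rt.ratio_defined
    assert math.isnan(rt.ratio)
    assert 0 <= rt.p_value <= 1
    assert rt.ratio_display == "-"


def test_exact_two_to_one_has_locally_maximal_p():
    n = 10
    rt0 = ratio_test(2 * n, n)
    assert rt0.ratio == 2.0
    assert rt0.p_value >= ratio_test(2 * n + 1, n - 1).p_value
    assert rt0.p_value >= ratio_test(2 * n - 1, n + 1).p_value
    assert not rt0.significant


def oracle_binomial_p(k, n, p0):
    """Brute-force tail sum: total probability of outcomes no more likely
    than the observed one."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    cut = pmf[k] * (1 + 1e-12)
    return sum(p for p in pmf if p <= cut)


@pytest.mark.parametrize("n", [5, 23, 60, 101, 120])
def test_p_value_matches_bruteforce_tail_enumeration(n):
    p0 = 2.0 / 3.0
    for k in range(0, n + 1, max(1, n // 17)):
        assert binomial_two_sided(k, n, p0) == pytest.approx(
            oracle_binomial_p(k, n, p0), abs=1e-12
        )


def test_p_value_decreases_away_from_expectation():
    n = 90
    ps = [ratio_test(k, n - k).p_value for k in range(60, 91, 5)]  # ratio 2 .. up
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# replication-fork transmission model


def test_transmission_model_mean_ratio_near_two():
    ratios = simulate_transmission_ratio(n_events=100, n_replicates=300, rng=5)
    assert 1.9 <= float(np.mean(ratios)) <= 2.1


# ---------------------------------------------------------------------------
# fixation rate


def test_fixation_rate_published_example():
    rate, one_in = fixation_rate(2300, 600_000)
    assert round(rate, 3) == 0.004
    assert one_in == 250


def test_fixation_rate_zero_events():
    rate, one_in = fixation_rate(0, 600_000)
    assert rate == 0.0 and one_in is None


def test_fixation_rate_identity():
    rate, one_in = fixation_rate(600_000, 600_000)
    assert rate == 1.0 and one_in == 1


# ---------------------------------------------------------------------------
# gap attribution


def test_attribution_arithmetic_identity():
    att = GapAttribution(20_080, 7301, 1871, n_ambiguous_polymorphisms=1745)
    assert att.te_fraction == pytest.approx(1871 / 7301)
    assert att.extrapolated_te_gaps == pytest.approx(att.te_fraction * 20_080)
    assert round(att.extrapolated_te_gaps, -1) == 5150
    assert round(att.extrapolated_hidden_polymorphisms) == 447


def test_attribution_zero_gaps(rng, sim_library):
    g = {"chr1": random_seq(rng, 5000)}
    att = extrapolate_hidden_te_gaps(g, g, sim_library)
    assert att.total_gaps == 0
    assert att.te_fraction == 0.0


def test_attribution_finds_hidden_te(rng, sim_library):
    """A gap replacing a TE in one assembly is attributed to that TE via
    flank mapping into the other assembly."""
    fam = sim_library["DTM_SIM2"]
    left = random_seq(rng, 2000)
    mid = random_seq(rng, 2000)
    right = random_seq(rng, 2000)
    other = left + fam.sequence + mid + random_seq(rng, 300) + right
    gapped = (
        left + "N" * len(fam.sequence) + mid + "N" * 300 + right
    )  # TE hidden by a gap; a second gap hides plain sequence
    att = extrapolate_hidden_te_gaps({"chr1": gapped}, {"chr1": other}, sim_library)
    assert att.total_gaps == 2
    assert att.mappable_gaps == 2
    assert att.te_positive_gaps == 1
    assert att.te_fraction == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# relative activity


def _call(family, superfamily, verdict="insertion"):
    ev = IndelEvent("A", 0, 100, 0, "A" * 100)
    return PolymorphismCall(ev, family, superfamily, verdict, "A", TSDCall(True, "TA", 2))


def test_relative_activity_values_and_groups():
    counts = {"DTH_TR": 581, "DTT_SB": 3995, "DTM_MAD": 2, "DTH_TO": 3000}
    calls = (
        [_call("DTH_TR", "DTH") for _ in range(17)]
        + [_call("DTH_TR", "DTH", "excision-perfect")]
        + [_call("DTM_MAD", "DTM")]
        + [_call("DTH_TO", "DTH") for _ in range(5)]
    )
    recs = {r.family: r for r in relative_activity_table(counts, calls)}
    assert recs["DTH_TR"].moved_copies == 18
    assert recs["DTH_TR"].relative_activity == pytest.approx(18 / 581)
    assert recs["DTT_SB"].group == "inactive"
    assert recs["DTM_MAD"].relative_activity == pytest.approx(0.5)
    assert recs["DTM_MAD"].group == "II"  # highly active, rare
    assert recs["DTH_TO"].group == "III"  # abundant, relatively quiet


def test_zero_copy_family_with_calls_is_error():
    with pytest.raises(ContractError):
        relative_activity_table({"DTT_X": 0}, [_call("DTT_X", "DTT")])


def test_unknown_family_is_error():
    with pytest.raises(ContractError):
        relative_activity_table({"DTT_Y": 5}, [_call("DTT_X", "DTT")])


# ---------------------------------------------------------------------------
# gene context


def _gene(gid, start, end, strand, exons=None):
    return GeneModel(gid, "chr1", start, end, strand, exons or [(start, end)])


def _call_at(pos):
    ev = IndelEvent("A", pos - 50, pos + 50, pos, "A" * 100)
    return PolymorphismCall(ev, "DTT_X", "DTT", "insertion", "A", TSDCall(True, "TA", 2))


def test_gene_context_assignments():
    genes = [
        _gene("g1", 10_000, 12_000, "+",
              exons=[(10_000, 10_400), (11_000, 12_000)]),
    ]
    cases = {
        9_200: "upstream",      # 800 bp 5' of the CDS start
        12_600: "intergenic",   # 600 bp 3' of the CDS end (beyond 500)
        12_300: "downstream",   # 300 bp 3'
        11_200: "exon",         # inside the second exon
        10_600: "intron",
        4_000: "intergenic",
    }
    for pos, expect in cases.items():
        counts = gene_context([_call_at(pos)], genes)
        assert counts[expect] == 1, (pos, expect, counts)


def test_gene_context_strand_aware():
    genes = [_gene("g1", 10_000, 12_000, "-")]
    counts = gene_context([_call_at(12_800)], genes)  # 5' side on minus strand
    assert counts["upstream"] == 1
    counts = gene_context([_call_at(9_700)], genes)  # 3' side on minus strand
    assert counts["downstream"] == 1


def test_gene_context_partitions_calls():
    genes = [_gene("g1", 10_000, 12_000, "+")]
    calls = [_call_at(p) for p in (500, 9_500, 10_500, 12_100, 40_000)]
    counts = gene_context(calls, genes)
    assert sum(counts.values()) == len(calls)
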