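"""Simulator contracts: seeded determinism, event bookkeeping, footprint
calibration and fixture round-trips."""
import numpy as np
import pytest

from tirpoly.errors import ContractError, ParameterError, PlacementError
from tirpoly.simulate import (
    FootprintParams,
    PlantedLocus,
    SimulationConfig,
    _draw_filler_length,
    _draw_footprint,
    add_gaps,
    apply_excision,
    apply_insertion,
    diverge,
    emit_fixture,
    load_truth,
    make_ancestor,
    simulate_pair,
    synthetic_library,
)
from tirpoly._seq import n_run_intervals
from tirpoly.te_model import SUPERFAMILY_PROFILES

SMALL = dict(
    genome_length=150_000,
    n_planted_copies_per_family=1,
    n_insertions=8,
    n_excisions=4,
    n_precise_excisions=1,
    n_internal_deletions=1,
    n_gaps=3,
)


# ---------------------------------------------------------------------------
# ancestor


def test_ancestor_seeded_determinism():
    assert make_ancestor(1000, 0.5, 7) == make_ancestor(1000, 0.5, 7)


def test_ancestor_gc_zero_boundary():
    assert set(make_ancestor(500, 0.0, 1)) <= {"A", "T"}


def test_ancestor_gc_concentration():
    seq = make_ancestor(1_000_000, 0.44, 1)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.44) < 0.01  # binomial concentration at n = 1e6


def test_ancestor_invalid_gc_rejected():
    with pytest.raises(ParameterError):
        make_ancestor(100, 1.5, 0)


# ---------------------------------------------------------------------------
# divergence


def test_zero_rates_give_identical_copies():
    anc = make_ancestor(20_000, 0.5, 3)
    cfg = SimulationConfig(substitution_rate=0.0, background_indel_rate=0.0, seed=3)
    a, b, events = diverge(anc, cfg)
    assert a == anc and b == anc
    assert events == []


def test_substitution_count_matches_binomial():
    anc = make_ancestor(100_000, 0.5, 9)
    cfg = SimulationConfig(substitution_rate=0.005, background_indel_rate=0.0, seed=9)
    a, b, _ = diverge(anc, cfg)
    for copy in (a, b):
        mism = sum(1 for x, y in zip(anc, copy) if x != y)
        # Binomial(1e5, 0.005): mean 500, sd ~22.3; +-3 sd
        assert abs(mism - 500) < 3 * 22.4


def test_background_indels_small_and_logged():
    anc = make_ancestor(50_000, 0.5, 4)
    cfg = SimulationConfig(substitution_rate=0.0, background_indel_rate=5e-4, seed=4)
    a, b, events = diverge(anc, cfg)
    assert events, "expected some background indels at this rate"
    for ev in events:
        assert ev.kind == "background-indel"
        assert max(ev.deleted_bp, ev.filler_bp) <= 10  # never mimics a TE event


# ---------------------------------------------------------------------------
# insertion / excision primitives


def _planted(genome, fam, pos, rng):
    g, ev = apply_insertion(genome, fam, pos, fam.profile, rng)
    k = fam.profile.tsd_length
    loc = PlantedLocus(fam.family_name, ev.tsd_sequence,
                       base_start=ev.locus_a_start + k, base_end=ev.locus_a_end - k)
    return g, loc, ev


def test_insertion_creates_tsd_and_grows_by_te_plus_tsd(rng, sim_library):
    genome = make_ancestor(5000, 0.5, 0)
    fam = sim_library["DTT_SIM1"]  # Mariner: TA target site, 2-bp TSD
    g, loc, ev = _planted(genome, fam, 2500, rng)
    assert len(g) == len(genome) + len(fam.sequence) + 2
    assert ev.tsd_sequence == "TA"
    s, e = ev.locus_a_start, ev.locus_a_end
    assert g[s : s + 2] == "TA" and g[e - 2 : e] == "TA"


def test_mutator_duplicates_nine_bp_site_verbatim(rng, sim_library):
    genome = make_ancestor(5000, 0.5, 1)
    fam = sim_library["DTM_SIM1"]
    site = genome[2500:2509]
    g, loc, ev = _planted(genome, fam, 2500, rng)
    assert ev.tsd_sequence == site
    assert len(ev.tsd_sequence) == 9


def test_zero_length_te_rejected(rng):
    from tirpoly.te_model import TEConsensus

    te = TEConsensus.__new__(TEConsensus)
    te.family_name, te.superfamily, te.sequence, te.source = "X", "DTT", "", "library"
    with pytest.raises(ContractError):
        apply_insertion("ACGT" * 100, te, 50, SUPERFAMILY_PROFILES["DTT"], np.random.default_rng(0))


def test_no_motif_nearby_raises_placement_error(rng, sim_library):
    genome = "G" * 5000  # no TA anywhere
    fam = sim_library["DTT_SIM1"]
    with pytest.raises(PlacementError):
        apply_insertion(genome, fam, 2500, fam.profile, rng)


def test_perfect_excision_leaves_tandem_tsd(rng, sim_library):
    genome = make_ancestor(5000, 0.5, 2)
    fam = sim_library["DTH_SIM1"]
    g, loc, ev = _planted(genome, fam, 2500, rng)
    g2, ev2 = apply_excision(g, loc, FootprintParams(), rng, kind="excision-perfect")
    k = len(loc.tsd)
    assert len(g2) == len(g) - len(fam.sequence)
    p = loc.base_start - k
    assert g2[p : p + k] == loc.tsd and g2[p + k : p + 2 * k] == loc.tsd


def test_precise_excision_restores_preinsertion_site(rng, sim_library):
    genome = make_ancestor(5000, 0.5, 8)
    fam = sim_library["DTT_SIM2"]
    g, loc, ev = _planted(genome, fam, 2500, rng)
    g2, _ = apply_excision(g, loc, FootprintParams(), rng, kind="precise-excision")
    assert g2 == genome


def test_excising_unflagged_locus_is_contract_error(rng):
    loc = PlantedLocus("", "", base_start=100, base_end=200)
    with pytest.raises(ContractError):
        apply_excision("ACGT" * 100, loc, FootprintParams(), rng)


def test_filler_lengths_confined_to_range(rng):
    params = FootprintParams()
    lo, hi = params.filler_length_range
    draws = [_draw_filler_length(params, rng) for _ in range(3000)]
    assert min(draws) >= lo and max(draws) <= hi
    assert abs(np.mean(draws) - params.filler_length_mean) < 1.0


def test_footprint_probabilities_sum_to_one_enforced():
    with pytest.raises(ParameterError):
        FootprintParams(p_perfect=0.5, p_deletion=0.5, p_filler=0.5, p_both=0.5)


# ---------------------------------------------------------------------------
# gaps


def test_gap_count_and_minimum_length(rng):
    genome = make_ancestor(100_000, 0.5, 5)
    g, gaps = add_gaps(genome, 10, (60, 500), rng)
    runs = n_run_intervals(g, min_len=51)
    assert len(runs) == 10
    assert all(e - s > 50 for s, e in runs)
    assert len(g) == len(genome)


def test_zero_gaps_identity(rng):
    genome = make_ancestor(10_000, 0.5, 6)
    g, gaps = add_gaps(genome, 0, (60, 100), rng)
    assert g == genome and gaps == []


def test_gap_fraction_over_te(rng):
    genome = make_ancestor(200_000, 0.5, 7)
    te_iv = [(i * 10_000 + 5000, i * 10_000 + 6000) for i in range(19)]
    g, gaps = add_gaps(genome, 20, (60, 200), rng, te_intervals=te_iv,
                       fraction_over_te=0.25)
    mids = [(s + e) // 2 for s, e in gaps]
    n_over = sum(any(ts <= m < te for ts, te in te_iv) for m in mids)
    assert 2 <= n_over <= 9  # ~25% of 20, loose binomial band


def test_gap_min_length_must_exceed_50(rng):
    with pytest.raises(ParameterError):
        add_gaps("ACGT" * 1000, 1, (40, 60), rng)


# ---------------------------------------------------------------------------
# full pair simulation


def test_simulation_seeded_byte_identical():
    cfg1 = SimulationConfig(seed=2, **SMALL)
    cfg2 = SimulationConfig(seed=2, **SMALL)
    p1, p2 = simulate_pair(cfg1), simulate_pair(cfg2)
    assert p1.genome_a == p2.genome_a
    assert p1.genome_b == p2.genome_b
    assert len(p1.events) == len(p2.events)


def test_length_bookkeeping_exact():
    cfg = SimulationConfig(seed=13, **SMALL)
    pair = simulate_pair(cfg)
    lib = pair.library
    base_len = cfg.genome_length + sum(
        (loc.base_end - loc.base_start) + len(loc.tsd) for loc in pair.planted
    )
    for species, genome in (("A", pair.genome_a), ("B", pair.genome_b)):
        expect = base_len
        for ev in pair.events:
            if ev.species != species:
                continue
            if ev.kind == "insertion":
                expect += len(lib[ev.family].sequence) + len(ev.tsd_sequence)
            elif ev.kind == "excision-perfect":
                expect -= len(lib[ev.family].sequence)
            elif ev.kind == "precise-excision":
                expect -= len(lib[ev.family].sequence) + len(ev.tsd_sequence)
            elif ev.kind == "excision-deletion":
                expect -= (
                    len(lib[ev.family].sequence) + len(ev.tsd_sequence) + ev.deleted_bp
                )
            elif ev.kind == "excision-filler":
                expect += ev.filler_bp - len(lib[ev.family].sequence)
            elif ev.kind == "excision-both":
                expect += ev.filler_bp - (
                    len(lib[ev.family].sequence) + len(ev.tsd_sequence) + ev.deleted_bp
                )
            elif ev.kind == "internal-deletion":
                expect -= ev.deleted_bp
            elif ev.kind == "background-indel":
                expect += ev.filler_bp - ev.deleted_bp
        assert len(genome) == expect, species


def test_tsd_motifs_by_superfamily():
    cfg = SimulationConfig(seed=21, **SMALL)
    pair = simulate_pair(cfg)
    checked = 0
    for ev in pair.events:
        if not ev.family or ev.kind == "internal-deletion":
            continue
        code = pair.library[ev.family].superfamily
        if code == "DTT":
            assert ev.tsd_sequence == "TA"
            checked += 1
        elif code == "DTH":
            assert ev.tsd_sequence in ("TAA", "TTA")
            checked += 1
        elif code in ("DTM", "DTA"):
            assert len(ev.tsd_sequence) == SUPERFAMILY_PROFILES[code].tsd_length
            checked += 1
    assert checked > 0


def test_event_counts_match_config():
    cfg = SimulationConfig(seed=17, **SMALL)
    pair = simulate_pair(cfg)
    kinds = {}
    for ev in pair.events:
        kinds[ev.kind] = kinds.get(ev.kind, 0) + 1
    assert kinds.get("insertion", 0) == cfg.n_insertions
    n_exc = sum(v for k, v in kinds.items() if k.startswith("excision-"))
    assert n_exc == cfg.n_excisions
    assert kinds.get("precise-excision", 0) == cfg.n_precise_excisions
    assert kinds.get("internal-deletion", 0) == cfg.n_internal_deletions


def test_seed_mandatory():
    with pytest.raises(ParameterError):
        SimulationConfig()


# ---------------------------------------------------------------------------
# fixtures on disk


def test_fixture_round_trip(tmp_path):
    cfg = SimulationConfig(seed=19, **SMALL)
    pair = simulate_pair(cfg)
    paths = emit_fixture(pair, tmp_path)
    back = load_truth(paths["truth"])
    assert back == pair.events
    from tirpoly.genome_alignment import read_genome

    ga = read_genome(paths["genome_a"])
    assert ga["chr1"] == pair.genome_a
    # FASTA fixed at 60 columns
    lines = paths["genome_a"].read_text().splitlines()
    assert all(len(l) <= 60 for l in lines[1:])
    assert len(lines[1]) == 60
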