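"""TE library handling, TIR matching, seed-and-extend annotation and de
novo family discovery."""
import itertools

import numpy as np
import pytest

from tirpoly.errors import ClassificationError, DuplicateFamilyError, EmptyLibraryError
from tirpoly.simulate import make_ancestor
from tirpoly.te_model import (
    SUPERFAMILY_PROFILES,
    TEConsensus,
    TELibrary,
    annotate_segment,
    build_star_msa,
    discover_families,
    load_te_library,
    match_tir,
    refine_consensus_borders,
)
from tirpoly._seq import revcomp

from conftest import random_seq


# ---------------------------------------------------------------------------
# superfamily profiles


def test_five_profiles_with_diagnostic_tsd_lengths():
    assert set(SUPERFAMILY_PROFILES) == {"DTT", "DTH", "DTM", "DTC", "DTA"}
    assert {p.tsd_length for p in SUPERFAMILY_PROFILES.values()} == {2, 3, 8, 9}
    assert SUPERFAMILY_PROFILES["DTT"].tsd_motif == "TA"
    assert SUPERFAMILY_PROFILES["DTT"].tsd_length == 2
    assert SUPERFAMILY_PROFILES["DTH"].tsd_motifs == ("TAA", "TTA")
    assert SUPERFAMILY_PROFILES["DTH"].tsd_length == 3
    for code in ("DTM", "DTC", "DTA"):
        assert SUPERFAMILY_PROFILES[code].tsd_motifs == ()


# ---------------------------------------------------------------------------
# match_tir


def _expand(positions):
    """All concrete strings a motif with alternatives can take."""
    return ["".join(t) for t in itertools.product(*[sorted(s) for s in positions])]


def brute_force_tir(seq, profile, max_mismatch):
    """Oracle: enumerate every motif expansion and compare position-wise."""
    L = len(profile.tir_positions)
    if len(seq) < 2 * L:
        return False
    head_ok = any(
        sum(x != y for x, y in zip(seq[:L], var)) <= max_mismatch
        for var in _expand(profile.tir_positions)
    )
    tail_ok = any(
        sum(x != y for x, y in zip(seq[-L:], revcomp(var))) <= max_mismatch
        for var in _expand(profile.tir_positions)
    )
    return head_ok and tail_ok


def test_cacta_alternative_accepted():
    seq = "CACTA" + "G" * 90 + "TAGTG"
    assert match_tir(seq, SUPERFAMILY_PROFILES["DTC"]) is not None


def test_hat_short_tir():
    seq = "CA" + "G" * 96 + "TG"
    assert match_tir(seq, SUPERFAMILY_PROFILES["DTA"]) is not None


def test_random_sequence_without_terminal_motifs_rejected():
    seq = "GGGG" + "A" * 92 + "CCCC"
    assert match_tir(seq, SUPERFAMILY_PROFILES["DTT"], max_mismatch=0) is None


@pytest.mark.parametrize("code", sorted(SUPERFAMILY_PROFILES))
@pytest.mark.parametrize("max_mismatch", [0, 1])
def test_match_tir_equals_bruteforce_enumeration(code, max_mismatch, rng):
    profile = SUPERFAMILY_PROFILES[code]
    L = len(profile.tir_positions)
    hits = 0
    for i in range(300):
        n = int(rng.integers(2 * L, 40))
        seq = random_seq(rng, n)
        if i % 3 == 0:  # plant a valid prefix to exercise the positive path
            var = _expand(profile.tir_positions)[0]
            seq = var + seq[L:]
        if i % 5 == 0:
            var = _expand(profile.tir_positions)[-1]
            seq = seq[:-L] + revcomp(var)
        got = match_tir(seq, profile, max_mismatch) is not None
        want = brute_force_tir(seq, profile, max_mismatch)
        assert got == want, (seq, code, max_mismatch)
        hits += got
    assert hits > 0  # the sweep exercised positive cases


# ---------------------------------------------------------------------------
# library I/O


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def test_load_library_trep_style_headers(tmp_path):
    p = tmp_path / "lib.fasta"
    _write_fasta(p, [("DTT_SB", "A" * 80), ("DTM_MK extra text", "C" * 90)])
    lib = load_te_library(p)
    assert len(lib) == 2
    assert lib["DTT_SB"].superfamily == "DTT"
    assert lib["DTM_MK"].superfamily == "DTM"


def test_load_library_hash_grammar(tmp_path):
    p = tmp_path / "lib.fasta"
    _write_fasta(p, [("mping#DTH from rice", "G" * 120)])
    lib = load_te_library(p)
    assert lib["mping"].superfamily == "DTH"


def test_retrotransposon_code_rejected(tmp_path):
    p = tmp_path / "lib.fasta"
    _write_fasta(p, [("RLX_Gypsy1", "A" * 200)])
    with pytest.raises(ClassificationError):
        load_te_library(p)


def test_duplicate_family_name_rejected(tmp_path):
    p = tmp_path / "lib.fasta"
    _write_fasta(p, [("DTT_SB", "A" * 80), ("DTT_SB", "C" * 80)])
    with pytest.raises(DuplicateFamilyError):
        load_te_library(p)


def test_empty_library_rejected(tmp_path):
    p = tmp_path / "lib.fasta"
    p.write_text("")
    with pytest.raises(EmptyLibraryError):
        load_te_library(p)


def test_library_fasta_round_trip(tmp_path, sim_library):
    p = tmp_path / "out.fasta"
    sim_library.write_fasta(p)
    back = load_te_library(p)
    assert {f.family_name for f in back} == {f.family_name for f in sim_library}
    for fam in back:
        assert fam.sequence == sim_library[fam.family_name].sequence


# ---------------------------------------------------------------------------
# annotation


def test_short_perfect_match_below_min_length_not_annotated(rng):
    """A 49-bp perfect fragment cannot reach the 50-bp admission floor
    (an optimal local alignment never pads itself with gap columns), while
    the same fragment one base longer is admitted."""
    cons = random_seq(rng, 120)
    lib = TELibrary([TEConsensus("DTT_S1", "DTT", cons)])
    assert annotate_segment(cons[30:79], lib) == []  # 49 bp
    at_floor = annotate_segment(cons[30:80], lib)  # 50 bp
    assert at_floor and at_floor[0].alignment_length == 50


def test_full_self_match_identity_one(tiny_library):
    fam = tiny_library["DTT_X1"]
    anns = annotate_segment(fam.sequence, tiny_library)
    assert anns and anns[0].family_name == "DTT_X1"
    assert anns[0].identity == pytest.approx(1.0)
    assert anns[0].alignment_length == len(fam.sequence)


def test_degraded_copy_above_identity_floor_retained(rng):
    """A 60-bp hit at ~73% identity passes the >= 70% admission threshold."""
    cons = random_seq(rng, 60)
    lib = TELibrary([TEConsensus("DTM_D1", "DTM", cons)])
    # 12-bp exact seed + (2 match, 1 sub) blocks on either side
    copy = list(cons)
    for i in range(len(copy)):
        if i < 24 or i >= 36:
            if i % 3 == 2:
                copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
    seg = random_seq(rng, 150) + "".join(copy) + random_seq(rng, 150)
    anns = annotate_segment(seg, lib)
    assert anns, "hit at ~73% identity must be admitted"
    assert 0.70 <= anns[0].identity < 0.85


def test_heavily_degraded_copy_rejected(rng):
    cons = random_seq(rng, 60)
    lib = TELibrary([TEConsensus("DTM_D2", "DTM", cons)])
    copy = "".join(
        c if i < 14 else "ACGT"[("ACGT".index(c) + 1 + i % 3) % 4]
        for i, c in enumerate(cons)
    )
    seg = random_seq(rng, 100) + copy + random_seq(rng, 100)
    for a in annotate_segment(seg, lib):
        assert a.identity >= 0.70 and a.alignment_length >= 50


def test_all_n_segment_yields_empty(tiny_library):
    assert annotate_segment("N" * 500, tiny_library) == []


def test_annotation_thresholds_always_respected(rng, sim_library):
    for _ in range(5):
        seg = random_seq(rng, 1500)
        fam = list(sim_library)[int(rng.integers(0, len(sim_library)))]
        seg = seg[:400] + fam.sequence + seg[400:]
        for a in annotate_segment(seg, sim_library):
            assert a.alignment_length >= 50
            assert a.identity >= 0.70


def test_reverse_strand_copy_annotated(tiny_library):
    fam = tiny_library["DTM_Y1"]
    seg = "ACGT" * 30 + revcomp(fam.sequence) + "TGCA" * 30
    anns = annotate_segment(seg, tiny_library)
    assert any(a.family_name == "DTM_Y1" and a.strand == "-" for a in anns)


# ---------------------------------------------------------------------------
# discovery


def _genome_with_planted_family(rng, n_copies, mutate=0.0):
    """Disjoint, evenly spaced copies so none nests inside another."""
    cons = "CTCCCTC" + random_seq(rng, 300) + "GAGGGAG"
    pieces = [random_seq(rng, 700)]
    for _ in range(n_copies):
        copy = cons
        if mutate:
            copy = "".join(
                "ACGT"[("ACGT".index(c) + 1) % 4] if rng.random() < mutate else c
                for c in copy
            )
        pieces.append(copy)
        pieces.append(random_seq(rng, 700))
    return "".join(pieces), cons


def test_discovery_recovers_planted_family(rng):
    genome, cons = _genome_with_planted_family(rng, 20)
    found = discover_families([cons[3:-3]], genome, min_copies=15)
    assert len(found) == 1
    new = found[0]
    hit = annotate_segment(cons, TELibrary([new]))
    assert hit and hit[0].identity >= 0.99
    assert new.source == "discovered"


def test_discovery_is_idempotent_fixed_point(rng):
    genome, cons = _genome_with_planted_family(rng, 20)
    found = discover_families([cons[3:-3]], genome, min_copies=15)
    lib = TELibrary(found)
    again = discover_families([cons[3:-3]], genome, library=lib, min_copies=15)
    assert again == []


def test_too_few_copies_yield_no_family(rng):
    genome, cons = _genome_with_planted_family(rng, 8)
    assert discover_families([cons[3:-3]], genome, min_copies=15) == []


def test_segment_without_genome_copies_yields_no_family(rng):
    genome = random_seq(rng, 5000)
    orphan = random_seq(rng, 300)
    assert discover_families([orphan], genome) == []


# ---------------------------------------------------------------------------
# consensus border refinement


def test_core_with_divergent_flanks_trimmed_to_core(rng):
    core = "CTCCCTC" + random_seq(rng, 186) + "GAGGGAG"
    rows = [random_seq(rng, 300) + core + random_seq(rng, 300) for _ in range(15)]
    msa = build_star_msa(rows[0], rows[1:])
    res = refine_consensus_borders(msa)
    assert not res.failed
    assert abs(len(res.consensus.sequence) - 200) <= 10
    assert res.consensus.sequence.startswith("CTCCCTC"[:5])


def test_identical_rows_including_flanks_fail(rng):
    row = random_seq(rng, 500)
    res = refine_consensus_borders([row] * 10)
    assert res.failed


def test_alignment_without_conserved_core_fails(rng):
    rows = [random_seq(rng, 400) for _ in range(10)]
    msa = build_star_msa(rows[0], rows[1:])
    res = refine_consensus_borders(msa)
    assert res.failed


def test_fewer_than_three_rows_fail(rng):
    res = refine_consensus_borders([random_seq(rng, 100)] * 2)
    assert res.failed
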