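import numpy as np
import pytest

from zwevo import homology, simdata
from zwevo.divergence import DivergenceEstimate
from zwevo.homology import GametologPair


def _est(ds, aligned=300):
    return DivergenceEstimate(ds=ds, dn=0.01, omega=None, se_ds=0.01, se_dn=0.01,
                              ci95_ds=(0, ds), method="ML", n_codons=100)


def _pair(w="w1", z="z1", aligned=300):
    return GametologPair(locus="l", taxon="Ap", w_id=w, z_id=z, z_position_mb=1.0,
                         pairing_route="reciprocal-best", aligned_length_bp=aligned)


class TestBestHits:
    def test_identical_target_ranks_first_with_max_score(self):
        seqs = simdata.simulate_diverged_pair(0.3, 100, seed=1)
        targets = {"self": seqs["A"], "other": seqs["B"]}
        hits = homology.best_hits({"q": seqs["A"]}, targets)["q"]
        assert hits[0].target == "self"
        assert hits[0].score == max(h.score for h in hits)

    def test_no_hit_under_cutoff_gives_empty_list(self):
        rng = np.random.default_rng(0)
        q = "".join(rng.choice(list("ACGT"), 120))
        t = "".join(rng.choice(list("ACGT"), 120))
        hits = homology.best_hits({"q": q}, {"t": t}, evalue_cutoff=1e-30)
        assert hits["q"] == []

    def test_empty_target_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty target"):
            homology.best_hits({"q": "ACGT"}, {})

    def test_true_ortholog_recovered_at_ten_percent_divergence(self):
        hits_ok = 0
        for i in range(20):
            seqs = simdata.simulate_diverged_pair(0.3, 150, omega=1.0, seed=100 + i)
            decoy = simdata.simulate_diverged_pair(0.3, 150, omega=1.0, seed=500 + i)
            targets = {"true": seqs["B"], "decoy": decoy["A"]}
            top = homology.best_hits({"q": seqs["A"]}, targets)["q"][0].target
            hits_ok += top == "true"
        assert hits_ok == 20


class TestReciprocalBestHits:
    def test_identical_single_gene_sets_pair_up(self):
        seqs = simdata.simulate_diverged_pair(0.0, 100, seed=2)
        assert homology.reciprocal_best_hits({"a": seqs["A"]}, {"b": seqs["B"]}) == [("a", "b")]

    def test_asymmetric_best_hit_gives_no_pair(self):
        # b's best hit is a_prime (identical), not a (diverged)
        seqs = simdata.simulate_diverged_pair(0.4, 150, seed=3)
        set_a = {"a": seqs["A"], "a_prime": seqs["B"]}
        set_b = {"b": seqs["B"]}
        pairs = homology.reciprocal_best_hits(set_a, set_b)
        assert pairs == [("a_prime", "b")]

    def test_duplicated_paralog_excluded_from_rbh(self):
        base = simdata.simulate_diverged_pair(0.1, 150, seed=4)
        # paralog diverged further from the duck copy than the true ortholog
        paralog = simdata.simulate_diverged_pair(0.5, 150, seed=4)["B"]
        set_a = {"gg": base["A"]}
        set_b = {"ap": base["B"], "ap_paralog": paralog}
        pairs = homology.reciprocal_best_hits(set_a, set_b)
        assert ("gg", "ap") in pairs
        assert all(p[1] != "ap_paralog" for p in pairs)


class TestFilterWCandidates:
    @pytest.mark.parametrize("cov,length,keep", [
        (0.20, 140, False),   # both thresholds violated -> exclude
        (0.80, 300, True),
        (0.20, 300, True),    # literal conjunction: only coverage fails -> keep
        (0.80, 140, True),
        (0.25, 150, True),    # boundary: strict '<'
    ])
    def test_literal_conjunction(self, cov, length, keep):
        got, reason = homology.filter_w_candidates(cov, length)
        assert got is keep
        if not keep:
            assert "coverage" in reason and "aligned" in reason

    def test_borderline_flagged_in_reason(self):
        keep, reason = homology.filter_w_candidates(0.20, 300)
        assert keep and "borderline" in reason

    def test_or_mode_excludes_on_single_failure(self):
        keep, _ = homology.filter_w_candidates(0.20, 300, mode="or")
        assert not keep


class TestResolveParalogs:
    def test_lowest_ds_wins(self):
        cands = [(_pair(w=f"w{i}"), _est(ds)) for i, ds in enumerate([0.30, 0.12, 0.19])]
        assert homology.resolve_paralogs(cands).w_id == "w1"

    def test_single_candidate_returned(self):
        p = _pair()
        assert homology.resolve_paralogs([(p, _est(0.3))]) is p

    def test_no_estimable_ds_gives_none(self):
        assert homology.resolve_paralogs([(_pair(), None)]) is None

    def test_tie_broken_by_aligned_length_then_id(self):
        a = _pair(w="wa", aligned=100)
        b = _pair(w="wb", aligned=400)
        assert homology.resolve_paralogs([(a, _est(0.2)), (b, _est(0.2))]) is b


@pytest.fixture(scope="module")
def clean_world():
    """1:1:1 orthology: reference (Gg) W+Z and species (Ap) W+Z for 3 loci."""
    world = {"ref_w": {}, "ref_z": {}, "ap_w": {}, "ap_z": {}, "map": {}}
    for i in range(3):
        anc = simdata.simulate_diverged_pair(0.25, 120, seed=800 + i)  # Z-W split
        world["ref_z"][f"ggZ{i}"] = anc["A"]
        world["ref_w"][f"ggW{i}"] = anc["B"]
        # species copies evolve from the reference Z/W
        world["ap_z"][f"apZ{i}"] = simdata.evolve_sequence(anc["A"], 0.10, seed=850 + i)
        world["ap_w"][f"apW{i}"] = simdata.evolve_sequence(anc["B"], 0.10, seed=880 + i)
        world["map"][f"ggW{i}"] = f"ggZ{i}"
    return world


class TestPairGametologs:
    def test_clean_orthology_pairs_reciprocally(self, clean_world):
        w = clean_world
        species = {**w["ap_z"], **w["ap_w"]}
        pairs = homology.pair_gametologs(
            w["ap_w"], w["ref_w"], w["ref_z"], w["map"], species, taxon="Ap",
            z_positions_mb={f"ggZ{i}": float(i) for i in range(3)})
        assert len(pairs) == 3
        assert all(p.pairing_route == "reciprocal-best" for p in pairs)
        for p in pairs:
            assert p.w_id.replace("apW", "") == p.z_id.replace("apZ", "")

    def test_missing_reference_reported(self, clean_world):
        w = clean_world
        pairs = homology.pair_gametologs(
            {"apW0": w["ap_w"]["apW0"]}, w["ref_w"], w["ref_z"], {},  # empty W->Z map
            {**w["ap_z"], **w["ap_w"]}, taxon="Ap")
        assert pairs[0].pairing_route == "unpaired"
        assert pairs[0].reason == "no reference ortholog"
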