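import numpy as np
import pytest

from zwevo import geneconv, simdata
from zwevo.geneconv import ConversionFragment, SilentSiteProfile
from zwevo.seqio import CodonAlignment
from zwevo.studies import _brute_force_segments


class TestSilentSites:
    def test_invariant_alignment_gives_empty_profile(self):
        aln = CodonAlignment.from_dict({"a": "ATGGCTAAA", "b": "ATGGCTAAA"})
        assert geneconv.silent_polymorphic_sites(aln).n_sites == 0

    def test_synonymous_polymorphism_included(self):
        # TTT vs TTC: both Phe, third position varies
        aln = CodonAlignment.from_dict({"a": "TTTGGG", "b": "TTCGGG"})
        prof = geneconv.silent_polymorphic_sites(aln)
        assert list(prof.columns) == [2]

    def test_nonsynonymous_polymorphism_excluded(self):
        # TTT vs TTA: Phe vs Leu
        aln = CodonAlignment.from_dict({"a": "TTTGGG", "b": "TTAGGG"})
        assert geneconv.silent_polymorphic_sites(aln).n_sites == 0

    def test_gapped_codons_skipped(self):
        aln = CodonAlignment.from_dict({"a": "TTT---GGA", "b": "TTCAAAGGG"})
        prof = geneconv.silent_polymorphic_sites(aln)
        assert list(prof.columns) == [2, 8]


def _profile(agree, labels=("x", "y")):
    agree = np.asarray(agree, dtype=bool)
    states = np.vstack([np.where(agree, "A", "C"), np.full(len(agree), "A")])
    return SilentSiteProfile(columns=np.arange(len(agree)) * 2, states=states, labels=labels)


class TestFindFragments:
    def test_full_agreement_is_one_fragment(self):
        prof = _profile([1] * 10)
        frags = geneconv.find_fragments(prof, ("x", "y"))
        assert len(frags) == 1 and frags[0].n_sites == 10

    def test_run_bounded_by_disagreements(self):
        prof = _profile([0, 1, 1, 1, 1, 1, 1, 1, 1, 0])
        frags = geneconv.find_fragments(prof, ("x", "y"))
        assert [(f.site_indices[0], f.site_indices[-1]) for f in frags] == [(1, 8)]
        assert frags[0].score == 8

    def test_gscale2_merges_across_single_mismatch_when_worth_it(self):
        # runs of 4 and 4 around one mismatch: merged score 8 - 2.5 = 5.5 > 4
        prof = _profile([1, 1, 1, 1, 0, 1, 1, 1, 1])
        frags = geneconv.find_fragments(prof, ("x", "y"), gscale=2)
        assert len(frags) == 1 and frags[0].score == pytest.approx(5.5)
        # runs of 2 and 2: merged 4 - 2.5 = 1.5 < 2, so they stay separate
        prof2 = _profile([1, 1, 0, 1, 1])
        frags2 = geneconv.find_fragments(prof2, ("x", "y"), gscale=2)
        assert len(frags2) == 2

    def test_span_includes_monomorphic_columns_between_sites(self):
        prof = _profile([1, 1, 1])     # columns 0, 2, 4
        (f,) = geneconv.find_fragments(prof, ("x", "y"))
        assert (f.start, f.end, f.span_bp) == (0, 5, 5)

    @pytest.mark.parametrize("gscale", [0, 2])
    def test_matches_independent_brute_force(self, gscale):
        rng = np.random.default_rng(77)
        for _ in range(40):
            m = int(rng.integers(2, 25))
            agree = rng.random(m) < 0.6
            prof = _profile(agree)
            got = sorted(
                (f.site_indices[0], f.site_indices[-1] + 1, f.score)
                for f in geneconv.find_fragments(prof, ("x", "y"), gscale=gscale))
            want = sorted(_brute_force_segments(agree, gscale, geneconv.GSCALE2_MISMATCH_PENALTY))
            assert got == want


class TestPermutationTest:
    def test_single_polymorphic_site_gives_p_one(self):
        aln = CodonAlignment.from_dict(
            {"a_Z": "TTTGGG", "b_Z": "TTCGGG", "a_W": "TTTGGG", "b_W": "TTTGGG"})
        frags = geneconv.permutation_test(aln, n_perm=200, seed=1)
        assert all(f.sim_p == 1.0 for f in frags)

    def test_no_between_group_pair_is_an_error(self):
        aln = CodonAlignment.from_dict({"a_Z": "TTTGGG", "b_Z": "TTCGGG"})
        with pytest.raises(geneconv.GeneConvError, match="between-group"):
            geneconv.permutation_test(aln, n_perm=200, seed=1,
                                      group_spec={"a_Z": "Z", "b_Z": "Z"})

    def test_same_seed_gives_identical_fragment_tables(self):
        ds = simdata.simulate_gametolog_history(simdata.SimulationConfig(
            n_loci=1, cds_length=600, seed=31,
            suppression_times={"Gg": 90e6, "Ap": 90e6}))
        aln = CodonAlignment.from_dict(
            {k: v for k, v in ds.sequences[0].items() if k != "Tg_Z"})
        f1 = geneconv.permutation_test(aln, n_perm=500, seed=5)
        f2 = geneconv.permutation_test(aln, n_perm=500, seed=5)
        assert [(f.pair, f.start, f.sim_p) for f in f1] == [(f.pair, f.start, f.sim_p) for f in f2]

    def test_injected_tract_detected_as_significant_inner_fragment(self):
        # a 174 bp tract copied from Ap_Z onto Ap_W in a diverged pair
        cfg = simdata.SimulationConfig(
            n_loci=1, cds_length=900, seed=42,
            suppression_times={"Gg": 90e6, "Mg": 90e6, "Ap": 90e6},
            conversion_tracts=[(0, "Ap_Z", "Ap_W", 300, 474)])
        ds = simdata.simulate_gametolog_history(cfg)
        sub = {k: ds.sequences[0][k] for k in ("Gg_Z", "Gg_W", "Ap_Z", "Ap_W")}
        aln = CodonAlignment.from_dict(sub, exon_map=tuple(ds.exon_map))
        prof = geneconv.silent_polymorphic_sites(aln)
        frags = geneconv.permutation_test(aln, prof, n_perm=10_000, seed=3)
        hits = [f for f in frags if f.pair == ("Ap_Z", "Ap_W") and f.sim_p < 0.05]
        assert hits
        best = min(hits, key=lambda f: f.sim_p)
        overlap = min(best.end, 474) - max(best.start, 300)
        assert overlap / 174 >= 0.8
        assert best.klass == "global-inner"


class TestExonFilter:
    EXONS = [(0, 0, 150), (1, 150, 300), (2, 300, 450)]

    def _frag(self, start, end):
        return ConversionFragment(pair=("Z", "W"), start=start, end=end,
                                  span_bp=end - start, n_sites=5, score=5)

    def test_forty_bp_coverage_dropped(self):
        out = geneconv.filter_fragments_by_exon([self._frag(10, 50)], self.EXONS)
        assert out == []

    def test_exactly_fifty_bp_kept(self):
        out = geneconv.filter_fragments_by_exon([self._frag(10, 60)], self.EXONS)
        assert out and out[0].spanning_exons == [0]

    def test_partial_exon_spans_filtered_per_exon(self):
        # 30 bp of exon 1 and 120 bp of exon 2
        out = geneconv.filter_fragments_by_exon([self._frag(120, 270)], self.EXONS)
        assert out[0].spanning_exons == [1]

    def test_missing_exon_map_passes_through_with_warning(self):
        out = geneconv.filter_fragments_by_exon([self._frag(0, 100)], None)
        assert out[0].warned_no_exon_map


@pytest.fixture(scope="module")
def converted_locus():
    # suppression well before the Gg-Mg split leaves 80 My of shared W
    # history, so a W-derived tract is recognisably W-like
    cfg = simdata.SimulationConfig(
        n_loci=1, cds_length=900, seed=50,
        suppression_times={"Gg": 110e6, "Mg": 110e6},
        conversion_tracts=[(0, "Gg_W", "Gg_Z", 300, 480)])
    ds = simdata.simulate_gametolog_history(cfg)
    sub = {k: ds.sequences[0][k] for k in ("Gg_Z", "Gg_W", "Mg_Z", "Mg_W", "Tg_Z")}
    return CodonAlignment.from_dict(sub, exon_map=tuple(ds.exon_map))


class TestDirectionAndRecomputation:
    def test_w_to_z_tract_direction_called(self, converted_locus):
        prof = geneconv.silent_polymorphic_sites(converted_locus)
        frags = geneconv.permutation_test(converted_locus, prof, n_perm=500, seed=2)
        best = min((f for f in frags if f.pair == ("Gg_Z", "Gg_W")), key=lambda f: f.sim_p)
        direction = geneconv.infer_direction(converted_locus, prof, best)
        assert direction == "Gg_W->Gg_Z"

    def test_fragment_without_informative_sites_is_unknown(self):
        aln = CodonAlignment.from_dict(
            {"a_Z": "TTTGGTCCTAAA", "a_W": "TTTGGTCCTAAA",
             "b_Z": "TTCGGACCAAAG", "b_W": "TTCGGACCAAAG"})
        prof = geneconv.silent_polymorphic_sites(aln)
        frag = geneconv.find_fragments(prof, ("a_Z", "a_W"))[0]
        assert geneconv.infer_direction(aln, prof, frag) == "unknown"

    def test_excluding_converted_exons_raises_ds(self, converted_locus):
        before, after = geneconv.recompute_divergence_excluding(
            converted_locus, converted_exons=[2, 3], a="Gg_Z", b="Gg_W")
        assert after.ds > before.ds

    def test_empty_exclusion_list_rejected(self, converted_locus):
        with pytest.raises(geneconv.GeneConvError, match="empty"):
            geneconv.recompute_divergence_excluding(converted_locus, [], a="Gg_Z", b="Gg_W")
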