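import numpy as np
import pytest

from zwevo import genetrees, simdata
from zwevo.genetrees import SupportedTree, TreeError


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_unrooted_topology_counts(self, n, count):
        topos = genetrees.enumerate_topologies(n)
        assert len(topos) == count
        assert len({frozenset(genetrees._splits_of(t, n)) for t in topos}) == count

    def test_too_many_tips_rejected(self):
        with pytest.raises(TreeError):
            genetrees.enumerate_topologies(9)


def _locus(t_supp, cds=900, seed=1, taxa=("Gg", "Mg")):
    cfg = simdata.SimulationConfig(
        n_loci=1, cds_length=cds, seed=seed,
        suppression_times={t: t_supp for t in taxa})
    ds = simdata.simulate_gametolog_history(cfg)
    tips = [f"{t}_{c}" for t in taxa for c in ("Z", "W")] + ["Tg_Z"]
    return {k: ds.sequences[0][k] for k in tips}


class TestMLTree:
    def test_best_topology_beats_all_enumerated_alternatives(self):
        sub = _locus(90e6, seed=2)
        tree = genetrees.ml_tree(sub, "Tg_Z")
        fits = tree._fit_cache["fits"]
        assert all(-res.fun <= tree.lnl + 1e-6 for res in fits.values())

    def test_long_internal_branch_pairing_recovered(self):
        # two well-separated pairs: the W clade and the Z clade
        sub = _locus(110e6, seed=3)
        tree = genetrees.ml_tree(sub, "Tg_Z")
        assert frozenset({"Gg_W", "Mg_W"}) in tree.split_labels() or \
            frozenset({"Gg_Z", "Mg_Z", "Tg_Z"}) in tree.split_labels()

    def test_identical_sequences_flagged_as_star(self):
        seq = _locus(90e6, seed=4)["Gg_Z"]
        tree = genetrees.ml_tree({f"s{i}_Z" if i < 3 else "s3_W": seq for i in range(4)}, "s0_Z")
        assert tree.star

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(TreeError, match="outgroup"):
            genetrees.ml_tree(_locus(90e6), "nope")


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        sub = _locus(90e6, seed=5)
        tree = genetrees.bootstrap_support(sub, "Tg_Z", n_reps=1, seed=0, method="rell")
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        sub = _locus(90e6, seed=6)
        t1 = genetrees.bootstrap_support(sub, "Tg_Z", 50, seed=9, method="rell")
        t2 = genetrees.bootstrap_support(sub, "Tg_Z", 50, seed=9, method="rell")
        assert t1.supports == t2.supports

    def test_strong_signal_gets_full_support(self):
        sub = _locus(120e6, cds=1800, seed=7)
        tree = genetrees.bootstrap_support(sub, "Tg_Z", 100, seed=1, method="rell")
        w = frozenset({"Gg_W", "Mg_W"})
        sup = tree.supports.get(w, tree.supports.get(frozenset(tree.tips) - w))
        assert sup == 100.0

    def test_refit_and_rell_agree_on_strong_signal(self):
        sub = _locus(120e6, cds=900, seed=8)
        t_rell = genetrees.bootstrap_support(sub, "Tg_Z", 30, seed=2, method="rell")
        t_refit = genetrees.bootstrap_support(sub, "Tg_Z", 30, seed=2, method="refit")
        w = frozenset({"Gg_W", "Mg_W"})
        for t in (t_rell, t_refit):
            sup = t.supports.get(w, t.supports.get(frozenset(t.tips) - w))
            assert sup >= 90.0

    def test_invalid_rep_count_rejected(self):
        with pytest.raises(TreeError):
            genetrees.bootstrap_support(_locus(90e6), "Tg_Z", n_reps=0)


def _fabricated_tree(supports):
    tips = ("Gg_W", "Gg_Z", "Mg_W", "Mg_Z", "Tg_Z")
    return SupportedTree(
        tips=tips, topology=(0, (1, 3), (2, 4)), branch_lengths=np.ones(7),
        kappa=2.0, lnl=0.0, outgroup="Tg_Z",
        supports={frozenset(k): v for k, v in supports.items()}, n_boot=100)


class TestClassifyTopology:
    def test_w_clade_with_high_support_is_shared(self):
        tree = _fabricated_tree({("Gg_W", "Mg_W"): 100.0})
        assert genetrees.classify_topology(tree) == "shared"

    def test_species_clades_with_high_support_are_independent(self):
        tree = _fabricated_tree({("Gg_W", "Gg_Z"): 98.0, ("Mg_W", "Mg_Z"): 97.0})
        assert genetrees.classify_topology(tree) == "independent"

    def test_low_support_is_unresolved(self):
        tree = _fabricated_tree({("Gg_W", "Gg_Z"): 80.0, ("Mg_W", "Mg_Z"): 97.0})
        assert genetrees.classify_topology(tree) == "unresolved"

    def test_simulated_shared_locus_classified_shared(self):
        sub = _locus(120e6, cds=1800, seed=9)
        tree = genetrees.bootstrap_support(sub, "Tg_Z", 100, seed=3, method="rell")
        assert genetrees.classify_topology(tree) == "shared"
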