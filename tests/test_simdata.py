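import numpy as np
import pytest

from zwevo import divergence, simdata, wlinkage
from zwevo.seqio import CodonAlignment
from zwevo.simdata import SimulationConfig, SimulationError


class TestConfigValidation:
    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(SimulationError, match="multiple of 3"):
            SimulationConfig(cds_length=100).validate()

    def test_suppression_above_root_rejected(self):
        cfg = SimulationConfig(suppression_times={"Gg": 200e6})
        with pytest.raises(SimulationError, match="outside"):
            cfg.validate()

    def test_contradictory_singleton_time_rejected(self):
        # Gg suppressed before the Gg-Mg split while Mg suppressed separately
        cfg = SimulationConfig(suppression_times={"Gg": 50e6, "Mg": 10e6})
        with pytest.raises(SimulationError, match="predates the origin"):
            cfg.validate()

    def test_rates_must_be_positive(self):
        with pytest.raises(SimulationError, match="positive"):
            SimulationConfig(mu_w=0.0).validate()


class TestSimulation:
    def test_same_seed_reproduces_dataset_exactly(self):
        cfg = SimulationConfig(n_loci=2, cds_length=300, seed=11)
        a = simdata.simulate_gametolog_history(cfg)
        b = simdata.simulate_gametolog_history(SimulationConfig(n_loci=2, cds_length=300, seed=11))
        assert a.sequences == b.sequences

    def test_zero_suppression_time_leaves_pair_identical(self):
        cfg = SimulationConfig(
            n_loci=1, cds_length=300, seed=2,
            suppression_times={"Gg": 0.0, "Mg": 0.0, "Ap": 0.0})
        ds = simdata.simulate_gametolog_history(cfg)
        seqs = ds.sequences[0]
        for taxon in ("Gg", "Mg", "Ap"):
            assert seqs[f"{taxon}_Z"] == seqs[f"{taxon}_W"]

    def test_every_locus_carries_outgroup_and_truth(self, shared_dataset):
        assert len(shared_dataset.truth) == len(shared_dataset.sequences)
        for seqs in shared_dataset.sequences:
            assert "Tg_Z" in seqs

    def test_clock_expectation_at_90my(self):
        # shared suppression 90 My ago: E[dS] = 3.8e-9 * 90e6 = 0.342
        cfg = SimulationConfig(
            n_loci=40, cds_length=900, seed=3,
            suppression_times={"Gg": 90e6, "Mg": 90e6})
        ds = simdata.simulate_gametolog_history(cfg)
        vals = []
        for seqs in ds.sequences:
            aln = CodonAlignment.from_dict({k: seqs[k] for k in ("Gg_Z", "Gg_W")})
            vals.append(divergence.ml_pairwise_divergence(aln).ds)
        assert np.mean(vals) == pytest.approx(0.342, rel=0.10)

    def test_truth_topology_classes(self):
        t = simdata.LocusTruth("l", {"Gg": 90e6, "Mg": 90e6})
        assert t.topology_class("Gg", "Mg") == "shared"
        t2 = simdata.LocusTruth("l", {"Gg": 20e6, "Mg": 20e6})
        assert t2.topology_class("Gg", "Mg") == "independent"


class TestGeneConversionInjection:
    def test_full_cds_tract_copies_everything(self, shared_dataset):
        L = shared_dataset.config.cds_length
        out = simdata.inject_gene_conversion(shared_dataset, (0, "Gg_Z", "Gg_W", 0, L))
        assert out.sequences[0]["Gg_W"] == out.sequences[0]["Gg_Z"]
        assert shared_dataset.sequences[0]["Gg_W"] != out.sequences[0]["Gg_W"]  # original intact

    def test_tract_identity_inside_unchanged_outside(self, shared_dataset):
        out = simdata.inject_gene_conversion(shared_dataset, (1, "Ap_Z", "Ap_W", 150, 300))
        z, w_new = out.sequences[1]["Ap_Z"], out.sequences[1]["Ap_W"]
        w_old = shared_dataset.sequences[1]["Ap_W"]
        assert w_new[150:300] == z[150:300]
        assert w_new[:150] == w_old[:150] and w_new[300:] == w_old[300:]
        assert out.truth[1].tracts[0]["start"] == 150

    def test_overlapping_contradictory_tracts_rejected(self, shared_dataset):
        out = simdata.inject_gene_conversion(shared_dataset, (0, "Gg_Z", "Gg_W", 0, 150))
        with pytest.raises(SimulationError, match="contradictory"):
            simdata.inject_gene_conversion(out, (0, "Mg_Z", "Gg_W", 90, 210))

    def test_out_of_range_tract_rejected(self, shared_dataset):
        with pytest.raises(SimulationError, match="outside CDS"):
            simdata.inject_gene_conversion(shared_dataset, (0, "Gg_Z", "Gg_W", 0, 10_000))


class TestExpressionAndSnps:
    def test_w_genes_are_zero_in_every_male(self, shared_dataset):
        expr, klass = simdata.simulate_expression(shared_dataset, 5, 5, seed=8)
        males = [s for s in expr.columns if s.startswith("male")]
        w_genes = [g for g, k in klass.items() if k == "W"]
        assert (expr.loc[w_genes, males].to_numpy() == 0).all()

    def test_autosomal_sex_ratio_near_one(self, shared_dataset):
        expr, klass = simdata.simulate_expression(
            shared_dataset, 20, 20, n_autosomal=200, seed=9)
        males = [s for s in expr.columns if s.startswith("male")]
        females = [s for s in expr.columns if s.startswith("female")]
        auto = [g for g, k in klass.items() if k == "A"]
        ratio = expr.loc[auto, females].mean(axis=1) / expr.loc[auto, males].mean(axis=1)
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.15)

    def test_w_classification_recovers_truth(self, shared_dataset):
        expr, klass = simdata.simulate_expression(shared_dataset, 5, 5, n_autosomal=50, seed=10)
        cands = wlinkage.classify_w_candidates(expr)
        called_w = {c.gene for c in cands if c.klass == "female-limited"}
        true_w = {g for g, k in klass.items() if k == "W"}
        true_auto = {g for g, k in klass.items() if k == "A"}
        assert len(called_w & true_w) / len(true_w) >= 0.95
        assert not called_w & true_auto

    def test_snps_are_female_limited(self, shared_dataset):
        snps = simdata.simulate_snps(shared_dataset)
        assert (snps["male_carriers"] == 0).all()
        assert (snps["female_carriers"] > 0).all()
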