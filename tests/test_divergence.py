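import numpy as np
import pytest

from zwevo import divergence, simdata
from zwevo.divergence import SaturationError
from zwevo.seqio import CodonAlignment


def pair(a, b):
    return CodonAlignment.from_dict({"A": a, "B": b})


class TestNG86:
    def test_identical_sequences_give_zero(self):
        est = divergence.ng86_divergence(pair("TTTGGGAAA", "TTTGGGAAA"))
        assert est.ds == 0.0 and est.dn == 0.0

    def test_hand_computed_synonymous_example(self):
        # One synonymous difference over 5/3 synonymous sites: pS = 0.6,
        # dS = -(3/4) ln(1 - 4*0.6/3) ~ 1.207
        est = divergence.ng86_divergence(pair("TTTGGGAAA", "TTCGGGAAA"))
        assert est.ds == pytest.approx(1.2071, abs=1e-3)
        assert est.dn == 0.0

    def test_lysine_synonymous_change(self):
        # AAA -> AAG is Lys -> Lys: purely synonymous
        est = divergence.ng86_divergence(pair("TTTGGGAAA", "TTTGGGAAG"))
        assert est.dn == 0.0 and est.ds > 0

    def test_nonsynonymous_only_change(self):
        # TTT -> TTA is Phe -> Leu
        est = divergence.ng86_divergence(pair("TTTGGGAAA", "TTAGGGAAA"))
        assert est.ds == 0.0 and est.dn > 0

    def test_symmetry(self):
        a, b = "TTTGGGAAACATCGA", "TTCGGGAAGCATCGA"
        e1 = divergence.ng86_divergence(pair(a, b))
        e2 = divergence.ng86_divergence(pair(b, a))
        assert e1.ds == pytest.approx(e2.ds) and e1.dn == pytest.approx(e2.dn)

    def test_saturated_proportion_raises(self):
        # every codon differs synonymously: pS = 3 diffs / ~3.33 sites > 3/4
        with pytest.raises(SaturationError):
            divergence.ng86_divergence(pair("CGACGGCGT", "CGGCGTCGC"))


class TestMLPairwise:
    def test_identical_sequences_give_zero_with_zero_se(self):
        seqs = simdata.simulate_diverged_pair(0.0, n_codons=60, seed=3)
        est = divergence.ml_pairwise_divergence(
            CodonAlignment.from_dict(seqs), min_codons=50)
        assert est.ds == 0.0 and est.dn == 0.0 and est.se_ds == 0.0
        assert est.omega is None

    def test_too_few_codons_rejected(self):
        with pytest.raises(divergence.EstimationError, match="< 50"):
            divergence.ml_pairwise_divergence(pair("TTTGGGAAA", "TTCGGGAAA"))

    def test_returned_optimum_is_local_maximum(self):
        seqs = simdata.simulate_diverged_pair(0.2, n_codons=200, seed=5)
        aln = CodonAlignment.from_dict(seqs)
        est = divergence.ml_pairwise_divergence(aln)
        from zwevo import codon as _codon
        ca, cb = aln.pairwise_codons("A", "B")
        pi = _codon.f3x4_frequencies([_codon.SENSE_CODONS[i] for i in np.concatenate([ca, cb])])
        model = _codon.CodonModel(pi)
        ii, jj, counts = divergence._pair_pattern_counts(ca, cb)

        def lnl(t, k, w):
            p = model.transition_matrix(k, w, t)
            return float(np.dot(counts, np.log(pi)[ii] + np.log(np.maximum(p[ii, jj], 1e-300))))

        base = lnl(est.t, est.kappa, est.omega)
        for factor in (0.9, 1.1):
            assert base >= lnl(est.t * factor, est.kappa, est.omega) - 1e-6
            assert base >= lnl(est.t, est.kappa * factor, est.omega) - 1e-6
            assert base >= lnl(est.t, est.kappa, est.omega * factor) - 1e-6

    def test_agreement_with_counting_oracle_at_moderate_divergence(self):
        diffs = []
        for i, ds_true in enumerate([0.05, 0.15, 0.30] * 10):
            seqs = simdata.simulate_diverged_pair(ds_true, 300, kappa=1.0, omega=1.0, seed=900 + i)
            aln = CodonAlignment.from_dict(seqs)
            diffs.append(abs(
                divergence.ml_pairwise_divergence(aln).ds
                - divergence.ng86_divergence(aln).ds
            ))
        assert np.mean(diffs) <= 0.02

    def test_se_shrinks_with_alignment_length(self):
        # quadrupling the length should roughly halve the SE (within 30%)
        ses = {}
        for n_codons in (150, 600):
            vals = [
                divergence.ml_pairwise_divergence(CodonAlignment.from_dict(
                    simdata.simulate_diverged_pair(0.2, n_codons, seed=40 + i))).se_ds
                for i in range(6)
            ]
            ses[n_codons] = np.mean(vals)
        ratio = ses[150] / ses[600]
        assert 2.0 * 0.7 <= ratio <= 2.0 * 1.3

    def test_ds_increases_with_simulation_time_in_expectation(self):
        means = []
        for ds_true in (0.05, 0.2, 0.4):
            vals = [
                divergence.ml_pairwise_divergence(CodonAlignment.from_dict(
                    simdata.simulate_diverged_pair(ds_true, 200, seed=70 + i))).ds
                for i in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSaturationGate:
    @pytest.mark.parametrize("ds,ok", [(0.404, True), (1.0, True), (1.2, False)])
    def test_ds_boundary(self, ds, ok):
        est = divergence.DivergenceEstimate(
            ds=ds, dn=0.1, omega=None, se_ds=0.01, se_dn=0.01,
            ci95_ds=(ds - 0.02, ds + 0.02), method="ML", n_codons=300)
        assert divergence.check_saturation(est) is ok
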