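"""Reproducible simulation studies exercising the whole pipeline.

Each study regenerates its data from a seed, runs the relevant estimators,
and returns summary statistics.  The same functions back the validation
test suite and the results-reproduction script, so the numbers they report
are always recomputed from scratch.

Problem sizes follow the study conditions: CDS lengths of 900 nt (300
codons; 1800 for the tree-classification study, where typical real
gametolog CDS run 1.5–8 kb), suppression times spanning the three-stratum
history (ancestral 90 My, intermediate 60 My, lineage-specific 20 My) on
the (((Gg, Mg), Ap), Tg) species tree with splits at 30/90/130 My, and the
combined Z+W synonymous clock rate of 3.8e-9 per site per year.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest


from . import divergence as _div
from . import geneconv as _gc
from . import genetrees as _gt
from . import selection as _sel
from . import simdata as _sim
from . import strata as _st
from .seqio import CodonAlignment


def _sub(seed: int, tag: int) -> int:
    """Derived stream seed, kept within 31 bits."""
    return (seed * 1_000_003 + tag) % (2**31)

# Printed dS bounds of the Galloanserae strata (inputs to clock dating):
# (stratum edge label, synonymous divergence)
STRATUM_DS_BOUNDS = {
    "conserved_I_lower": 0.285,
    "conserved_I_upper": 0.404,
    "conserved_II_lower": 0.171,
    "conserved_II_upper": 0.271,
    "galliform_III_lower": 0.156,
    "galliform_III_upper": 0.268,
    "galliform_IV_lower": 0.137,
    "galliform_IV_upper": 0.257,
    "anseriform_III_upper": 0.148,
}


def clock_dates_for_bounds() -> dict[str, float]:
    """Clock-dated stratum boundaries (My) for the printed dS bounds."""
    return {k: _st.clock_date(v) for k, v in STRATUM_DS_BOUNDS.items()}


# ---------------------------------------------------------------------------
# ML vs NG86 oracle equivalence
# ---------------------------------------------------------------------------

def oracle_equivalence_study(n_pairs: int = 100, seed: int = 0) -> dict:
    """Simulated pairs at true dS in {0.05, 0.15, 0.30} under kappa=1,
    omega=1 (the regime where NG86's counting assumptions hold exactly):
    ML-vs-NG86 agreement and truth coverage by +-2 SE."""
    ds_levels = [0.05, 0.15, 0.30]
    diffs, covered = [], []
    for i in range(n_pairs):
        ds_true = ds_levels[i % 3]
        seqs = _sim.simulate_diverged_pair(
            ds_true, n_codons=300, kappa=1.0, omega=1.0, seed=_sub(seed, i)
        )
        aln = CodonAlignment.from_dict(seqs)
        ng = _div.ng86_divergence(aln)
        ml = _div.ml_pairwise_divergence(aln)
        diffs.append(abs(ml.ds - ng.ds))
        covered.append(abs(ml.ds - ds_true) <= 2.0 * ml.se_ds if ml.se_ds > 0 else True)
    diffs = np.array(diffs)
    return dict(
        n=n_pairs,
        mean_abs_diff=float(diffs.mean()),
        frac_within_002=float((diffs <= 0.02).mean()),
        truth_coverage_2se=float(np.mean(covered)),
    )


# ---------------------------------------------------------------------------
# Fragment-finder brute-force oracle
# ---------------------------------------------------------------------------

def _brute_force_segments(agree: np.ndarray, gscale: int, penalty: float) -> list[tuple[int, int, float]]:
    """Independent O(n^2)/recursive enumeration of maximal fragments.

    gscale 0: scan for runs of consecutive agreement.  gscale 2: score all
    spans bounded by agreement sites and select recursively (argmax span,
    ties leftmost then longest, recurse left and right).
    """
    m = len(agree)
    if gscale == 0:
        out, i = [], 0
        while i < m:
            if agree[i]:
                j = i
                while j + 1 < m and agree[j + 1]:
                    j += 1
                out.append((i, j + 1, float(j + 1 - i)))
                i = j
            i += 1
        return out

    def span_score(a, b):
        return float(sum(1.0 if agree[k] else -penalty for k in range(a, b)))

    def solve(lo, hi):
        cands = []
        for a in range(lo, hi):
            if not agree[a]:
                continue
            for b in range(a + 1, hi + 1):
                if not agree[b - 1]:
                    continue
                s = span_score(a, b)
                if s > 0:
                    cands.append((-s, a, -(b - a), b))
        if not cands:
            return []
        cands.sort()
        _, a, _, b = cands[0]
        score = -cands[0][0]
        return solve(lo, a) + [(a, b, score)] + solve(b, hi)

    return solve(0, m)


def fragment_oracle_study(n_profiles: int = 200, max_sites: int = 30, seed: int = 0) -> dict:
    """Equality of the production fragment finder with brute force on
    random agreement profiles, at gscale 0 and 2."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_profiles):
        m = int(rng.integers(2, max_sites + 1))
        agree = rng.random(m) < rng.uniform(0.2, 0.8)
        cols = np.sort(rng.choice(3 * max_sites, size=m, replace=False))
        states = np.vstack([
            np.where(agree, "A", "C"), np.full(m, "A"),
        ])
        prof = _gc.SilentSiteProfile(columns=cols, states=states, labels=("x", "y"))
        for gscale in (0, 2):
            got = [
                (f.site_indices[0], f.site_indices[-1] + 1, f.score)
                for f in _gc.find_fragments(prof, ("x", "y"), gscale=gscale)
            ]
            want = _brute_force_segments(agree, gscale, _gc.GSCALE2_MISMATCH_PENALTY)
            if sorted(got) != sorted(want):
                mismatches += 1
    return dict(n_profiles=n_profiles, mismatches=mismatches)


# ---------------------------------------------------------------------------
# Conversion-test type-I calibration
# ---------------------------------------------------------------------------

def null_conversion_calibration(
    n_loci: int = 400, n_perm: int = 2000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """sim_p distribution of the within-species Z–W pair on null loci
    (shared suppression, no conversion), with suppression times drawn
    across 90–130 My for realistic heterogeneity."""
    rng = np.random.default_rng(seed)
    sims = []
    for i in range(n_loci):
        t = float(rng.uniform(90e6, 130e6))
        cfg = _sim.SimulationConfig(
            n_loci=1, cds_length=900, suppression_times={"Gg": t, "Ap": t},
            seed=_sub(seed, i),
        )
        ds = _sim.simulate_gametolog_history(cfg)
        seqs = {k: v for k, v in ds.sequences[0].items()
                if k in ("Gg_Z", "Gg_W", "Ap_Z", "Ap_W")}
        aln = CodonAlignment.from_dict(seqs)
        prof = _gc.silent_polymorphic_sites(aln)
        frags = [f for f in _gc.permutation_test(
            aln, prof, n_perm=n_perm, seed=_sub(seed, 500_000 + i)
        ) if f.pair == ("Ap_Z", "Ap_W")]
        sims.append(min((f.sim_p for f in frags), default=1.0))
    sims = np.array(sims)
    ks = kstest(sims, "uniform")
    return dict(
        n_loci=n_loci, n_perm=n_perm,
        rejection_rate=float((sims < alpha).mean()),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        sim_p=sims,
    )


# ---------------------------------------------------------------------------
# Stratum recovery (divergence + CI overlap + tree override)
# ---------------------------------------------------------------------------

def stratum_recovery_study(
    n_per_stratum: int = 10, cds_length: int = 900, n_boot: int = 200, seed: int = 0
) -> dict:
    """Three-stratum history in the Gg/Ap frame: ancestral 90 My (shared at
    the Galloanserae split), intermediate 60 My (independent suppression in
    both lineages), lineage-specific 20 My (Ap only; Gg at 60).  Candidate
    Ap loci are assigned against their Gg reference orthologs."""
    strata_def = [
        ("ancestral", {"Gg": 90e6, "Ap": 90e6}, "shared", 90.0),
        ("intermediate", {"Gg": 60e6, "Ap": 60e6}, "independent", 60.0),
        ("lineage-specific", {"Gg": 60e6, "Ap": 20e6}, "independent", 20.0),
    ]
    times = []
    for _, tmap, _, _ in strata_def:
        times.extend([dict(tmap)] * n_per_stratum)
    cfg = _sim.SimulationConfig(
        n_loci=len(times), cds_length=cds_length, suppression_times=times, seed=seed,
    )
    ds = _sim.simulate_gametolog_history(cfg)

    pairs, reference, tree_calls = [], {}, {}
    truth_class, truth_date = {}, {}
    for li, (truth, seqs) in enumerate(zip(ds.truth, ds.sequences)):
        stratum_idx = li // n_per_stratum
        name, _, klass, t_my = strata_def[stratum_idx]
        locus = truth.locus
        truth_class[locus] = klass
        truth_date[locus] = t_my
        ap = _div.ml_pairwise_divergence(
            CodonAlignment.from_dict({k: seqs[k] for k in ("Ap_Z", "Ap_W")}))
        gg = _div.ml_pairwise_divergence(
            CodonAlignment.from_dict({k: seqs[k] for k in ("Gg_Z", "Gg_W")}))
        pairs.append(dict(locus=locus, ds=ap.ds, ci95_ds=ap.ci95_ds,
                          z_position_mb=float(li)))
        reference[locus] = dict(ds=gg.ds, ci95_ds=gg.ci95_ds, stratum=name)
        sub = {k: seqs[k] for k in ("Gg_Z", "Gg_W", "Ap_Z", "Ap_W", "Tg_Z")}
        tree = _gt.ml_tree(sub, "Tg_Z")
        tree = _gt.bootstrap_support(sub, "Tg_Z", n_boot, seed=seed + li,
                                     method="rell", tree=tree)
        tree_calls[locus] = _gt.classify_topology(tree)

    assigns = _st.assign_strata(pairs, reference, tree_calls)
    correct, date_err = [], {name: [] for name, *_ in strata_def}
    ds_by_locus = {p["locus"]: p["ds"] for p in pairs}
    for a in assigns:
        predicted = "shared" if a.basis == "ci-overlap-with-reference" else (
            "independent" if a.stratum == "lineage-specific" else "unassigned"
        )
        correct.append(predicted == truth_class[a.locus])
    for name, _, _, t_my in strata_def:
        members = [t.locus for t in ds.truth if truth_date[t.locus] == t_my
                   and reference[t.locus]["stratum"] == name]
        dates = [_st.clock_date(ds_by_locus[l]) for l in members if ds_by_locus[l] <= 1.0]
        date_err[name] = abs(float(np.mean(dates)) - t_my) / t_my
    return dict(
        n_loci=len(times),
        class_accuracy=float(np.mean(correct)),
        date_rel_err=date_err,
        tree_calls=tree_calls,
    )


# ---------------------------------------------------------------------------
# Topology classification power
# ---------------------------------------------------------------------------

def topology_classification_study(
    n_per_class: int = 25, cds_length: int = 1800, n_boot: int = 200, seed: int = 0
) -> dict:
    """Shared loci (Gg+Mg suppressed 90 My, classified on the Gg/Mg tree)
    versus independent loci (Gg and Ap each suppressed 40 My, Gg/Ap tree)."""
    results = []
    scenarios = [
        ({"Gg": 90e6, "Mg": 90e6}, ("Gg", "Mg"), "shared"),
        ({"Gg": 40e6, "Ap": 40e6}, ("Gg", "Ap"), "independent"),
    ]
    for sc_i, (tmap, pair, truth) in enumerate(scenarios):
        cfg = _sim.SimulationConfig(
            n_loci=n_per_class, cds_length=cds_length,
            suppression_times=tmap, seed=_sub(seed, 600_000 + sc_i),
        )
        ds = _sim.simulate_gametolog_history(cfg)
        for li, seqs in enumerate(ds.sequences):
            tips = [f"{pair[0]}_Z", f"{pair[0]}_W", f"{pair[1]}_Z", f"{pair[1]}_W", "Tg_Z"]
            sub = {k: seqs[k] for k in tips}
            tree = _gt.ml_tree(sub, "Tg_Z")
            tree = _gt.bootstrap_support(sub, "Tg_Z", n_boot, seed=_sub(seed, 700_000 + 31 * li + sc_i),
                                         method="rell", tree=tree)
            results.append(_gt.classify_topology(tree) == truth)
    return dict(n_loci=len(results), accuracy=float(np.mean(results)))


# ---------------------------------------------------------------------------
# Branch-model calibration and power
# ---------------------------------------------------------------------------

def selection_calibration_study(
    n_null: int = 25, n_power: int = 25, cds_length: int = 900, seed: int = 0,
    alpha_null: float = 0.05, alpha_power: float = 0.01,
) -> dict:
    """Free-vs-omega=1 LRT on the W foreground: rejection rate under
    neutral foreground simulation and power against omega = 0.1."""
    tmpl = _sel.build_branch_tree("shared-suppression")
    times = {"Gg": 90e6, "Mg": 90e6, "Ap": 90e6}

    def run(n, omega_w, omega_z, base_seed):
        ps = []
        for i in range(n):
            cfg = _sim.SimulationConfig(
                n_loci=1, cds_length=cds_length, suppression_times=times,
                omega_w=omega_w, omega_z=omega_z, seed=base_seed + i,
            )
            d = _sim.simulate_gametolog_history(cfg)
            aln = CodonAlignment.from_dict(d.sequences[0])
            res = _sel.branch_model_lrt(aln, tmpl, "fix1")
            ps.append(res.p_value)
        return np.array(ps)

    p_null = run(n_null, 1.0, 1.0, _sub(seed, 800_000))
    p_power = run(n_power, 0.1, 0.2, _sub(seed, 900_000))
    return dict(
        n_null=n_null, n_power=n_power,
        null_rejection_rate=float((p_null < alpha_null).mean()),
        power=float((p_power < alpha_power).mean()),
        p_null=p_null, p_power=p_power,
    )
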