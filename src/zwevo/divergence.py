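"""Pairwise synonymous/nonsynonymous divergence estimation.

Two routes are provided: maximum likelihood under a Goldman–Yang codon model
with F3x4 frequencies (the production estimator), and the Nei–Gojobori (1986)
counting method with Jukes–Cantor correction, which serves as an independent
cross-check.  Standard errors for the ML route come from the curvature of the
log-likelihood via the delta method; 95% confidence intervals are
estimate ± 1.96 SE floored at zero.

Estimates with dS > 1 are regarded as mutationally saturated and are gated
out of downstream strata assignment and clock dating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import codon as _codon
from .seqio import CodonAlignment


class SaturationError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass
class DivergenceEstimate:
    ds: float
    dn: float
    omega: float | None          # None when dS = 0 (ratio undefined)
    se_ds: float
    se_dn: float
    ci95_ds: tuple[float, float]
    method: str                  # "ML" or "NG86"
    n_codons: int
    converged: bool = True
    lnl: float | None = None
    kappa: float | None = None
    t: float | None = None       # substitutions per codon (ML only)

    @property
    def saturated(self) -> bool:
        return self.ds > 1.0


def check_saturation(est: DivergenceEstimate) -> bool:
    """True (pass) iff dS <= 1; failing pairs are excluded from dating."""
    return est.ds <= 1.0


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) counting
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous / nonsynonymous sites of one codon.

    Each position contributes s/3 synonymous sites where s of its three
    possible changes are synonymous; mutations to stop codons count as
    nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        s = 0
        for nt in _codon.NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in _codon.CODON_INDEX and _codon.CODON_AA[alt] == _codon.CODON_AA[codon]:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


_SITE_COUNTS = {c: _codon_site_counts(c) for c in _codon.SENSE_CODONS}


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous / nonsynonymous difference counts.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded (if every pathway does, stops count as
    nonsynonymous steps and all pathways are retained).
    """
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur, steps, via_stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _codon.STOP_CODONS:
                via_stop = True
                steps.append((cur, nxt, False))
            else:
                steps.append((cur, nxt, _codon.CODON_AA.get(cur) == _codon.CODON_AA.get(nxt)))
            cur = nxt
        pathways.append((via_stop, steps))
    usable = [steps for via_stop, steps in pathways if not via_stop] or [s for _, s in pathways]
    syn = nonsyn = 0.0
    for steps in usable:
        for _, _, is_syn in steps:
            if is_syn:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(usable), nonsyn / len(usable)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; Jukes–Cantor correction undefined")
    return max(0.0, -0.75 * np.log(1.0 - 4.0 * p / 3.0))


def ng86_divergence(aln: CodonAlignment, a: str | None = None, b: str | None = None) -> DivergenceEstimate:
    """Nei–Gojobori counting estimate of dS and dN for a sequence pair."""
    if a is None or b is None:
        if len(aln.records) != 2:
            raise ValueError("specify the two sequence labels for multi-sequence alignments")
        a, b = aln.labels
    ca, cb = aln.pairwise_codons(a, b)
    if len(ca) == 0:
        raise EstimationError("no ungapped codon columns")
    s_sites = n_sites = sd = nd = 0.0
    for i, j in zip(ca, cb):
        c1, c2 = _codon.SENSE_CODONS[i], _codon.SENSE_CODONS[j]
        s1 = _SITE_COUNTS[c1]
        s2 = _SITE_COUNTS[c2]
        s_sites += (s1[0] + s2[0]) / 2.0
        n_sites += (s1[1] + s2[1]) / 2.0
        dsyn, dnon = _pathway_differences(c1, c2)
        sd += dsyn
        nd += dnon
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    # delta-method SE on the JC-corrected estimates
    def _se(p, n):
        if n <= 0 or p <= 0:
            return 0.0
        return float(np.sqrt(p * (1 - p) / n) / (1 - 4 * p / 3))

    se_ds = _se(ps, s_sites)
    se_dn = _se(pn, n_sites)
    omega = (dn / ds) if ds > 0 else None
    return DivergenceEstimate(
        ds=float(ds), dn=float(dn), omega=omega,
        se_ds=se_ds, se_dn=se_dn,
        ci95_ds=(max(0.0, ds - 1.96 * se_ds), ds + 1.96 * se_ds),
        method="NG86", n_codons=int(len(ca)),
    )


# ---------------------------------------------------------------------------
# Maximum likelihood under GY94 + F3x4
# ---------------------------------------------------------------------------

_START_POINTS = ((0.2, 2.0, 0.3), (0.6, 1.0, 1.0), (1.5, 4.0, 0.1))
_BOUNDS = ((np.log(1e-6), np.log(30.0)), (np.log(0.05), np.log(50.0)), (np.log(1e-4), np.log(50.0)))


def _pair_pattern_counts(ca: np.ndarray, cb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    combined = ca * _codon.N_CODONS + cb
    uniq, counts = np.unique(combined, return_counts=True)
    return uniq // _codon.N_CODONS, uniq % _codon.N_CODONS, counts.astype(float)


def ml_pairwise_divergence(
    aln: CodonAlignment,
    a: str | None = None,
    b: str | None = None,
    min_codons: int = 50,
) -> DivergenceEstimate:
    """ML estimate of (t, kappa, omega) under GY94/F3x4 for a pair.

    dS and dN are derived from the fitted branch length t and the
    synonymous/nonsynonymous flux and site proportions of the fitted model.
    Optimisation is a bounded quasi-Newton search on (log t, log kappa,
    log omega) from three fixed starting points.
    """
    if a is None or b is None:
        if len(aln.records) != 2:
            raise ValueError("specify the two sequence labels for multi-sequence alignments")
        a, b = aln.labels
    ca, cb = aln.pairwise_codons(a, b)
    n_codons = int(len(ca))
    if n_codons < min_codons:
        raise EstimationError(f"only {n_codons} ungapped codon columns (< {min_codons})")

    if np.array_equal(ca, cb):
        return DivergenceEstimate(
            ds=0.0, dn=0.0, omega=None, se_ds=0.0, se_dn=0.0,
            ci95_ds=(0.0, 0.0), method="ML", n_codons=n_codons,
            lnl=None, kappa=None, t=0.0,
        )

    codon_strings = [_codon.SENSE_CODONS[i] for i in np.concatenate([ca, cb])]
    pi = _codon.f3x4_frequencies(codon_strings)
    model = _codon.CodonModel(pi, style="gy94")
    pi_log = np.log(pi)
    ii, jj, counts = _pair_pattern_counts(ca, cb)

    def neg_lnl(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        p = model.transition_matrix(kappa, omega, t)
        vals = pi_log[ii] + np.log(np.maximum(p[ii, jj], 1e-300))
        return -float(np.dot(counts, vals))

    best = None
    for start in _START_POINTS:
        res = minimize(
            neg_lnl, np.log(start), method="L-BFGS-B", bounds=_BOUNDS,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("pairwise ML optimisation failed")

    t_hat, kappa_hat, omega_hat = np.exp(best.x)
    ds, dn = model.ds_dn_from_t(t_hat, kappa_hat, omega_hat)

    se_ds, se_dn = _delta_method_se(model, best.x, neg_lnl)
    return DivergenceEstimate(
        ds=float(ds), dn=float(dn),
        omega=float(omega_hat) if ds > 0 else None,
        se_ds=se_ds, se_dn=se_dn,
        ci95_ds=(max(0.0, ds - 1.96 * se_ds), ds + 1.96 * se_ds),
        method="ML", n_codons=n_codons,
        converged=bool(best.success), lnl=-float(best.fun),
        kappa=float(kappa_hat), t=float(t_hat),
    )


def _delta_method_se(model: _codon.CodonModel, x_hat: np.ndarray, neg_lnl) -> tuple[float, float]:
    """SEs of dS and dN from the observed information in log-parameter space."""
    eps = 1e-4
    k = len(x_hat)
    hess = np.zeros((k, k))
    f0 = neg_lnl(x_hat)
    for i in range(k):
        for j in range(i, k):
            xi, xj = np.zeros(k), np.zeros(k)
            xi[i] = eps
            xj[j] = eps
            fpp = neg_lnl(x_hat + xi + xj)
            fpm = neg_lnl(x_hat + xi - xj)
            fmp = neg_lnl(x_hat - xi + xj)
            fmm = neg_lnl(x_hat - xi - xj)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return 0.0, 0.0
    if not np.all(np.isfinite(cov)):
        return 0.0, 0.0

    def ds_dn_at(x):
        t, kappa, omega = np.exp(x)
        return np.array(model.ds_dn_from_t(t, kappa, omega))

    grads = np.zeros((k, 2))
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps
        grads[i] = (ds_dn_at(x_hat + step) - ds_dn_at(x_hat - step)) / (2 * eps)
    var = np.einsum("ia,ij,jb->ab", grads, cov, grads)
    se = np.sqrt(np.clip(np.diag(var), 0.0, None))
    return float(se[0]), float(se[1])
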