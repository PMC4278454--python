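"""Branch-model and branch-site likelihood-ratio tests of selective regime.

Codon likelihoods are computed on a fixed gene-tree template whose W (or Z)
branches are designated foreground.  The branch model gives the foreground
its own dN/dS ratio omega; comparing the free model against versions with
the foreground omega fixed to 1 (neutrality) or 0 (strict purifying
selection, numerically floored) yields chi-square likelihood-ratio tests
on one degree of freedom.  The branch-site model (model A) adds site
classes — a purifying class omega0 < 1, a neutral class, and classes 2a/2b
in which the foreground takes omega2 >= 1 — and tests omega2 = 1 against
omega2 free, reporting both the chi2(1) p-value and the 0/chi2(1) mixture.

Branch lengths, kappa and all free omegas are re-optimised under every
model.  Two tree templates are provided, matching the shared- and
independent-suppression histories of the Galloanserae gametologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from . import codon as _codon
from .seqio import CodonAlignment


class SelectionError(RuntimeError):
    pass


OMEGA_FLOOR = 1e-6   # stands in for omega = 0 (keeps the likelihood finite)

_SHARED = ("Tg_Z", ((((("Gg_W", "Mg_W"), "Ap_W")), (("Gg_Z", "Mg_Z"), "Ap_Z"))))
_INDEPENDENT = ("Tg_Z", ((("Gg_W", "Mg_W"), ("Gg_Z", "Mg_Z")), ("Ap_Z", "Ap_W")))


@dataclass(frozen=True)
class LabeledTreeTemplate:
    case: str                         # shared-suppression | independent-suppression
    topology: tuple                   # nested tuples of tip labels
    foreground: str                   # "W" or "Z"

    def tips(self) -> list[str]:
        out = []

        def walk(n):
            if isinstance(n, str):
                out.append(n)
            else:
                for c in n:
                    walk(c)

        walk(self.topology)
        return out


def _prune(node, keep: set[str]):
    if isinstance(node, str):
        return node if node in keep else None
    kids = [k for k in (_prune(c, keep) for c in node) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def build_branch_tree(
    case: str,
    taxa: tuple[str, ...] = ("Gg", "Mg", "Ap", "Tg"),
    foreground: str = "W",
) -> LabeledTreeTemplate:
    """Case-appropriate gene-tree template pruned to the taxa present."""
    if case == "shared-suppression":
        topo = _SHARED
    elif case == "independent-suppression":
        topo = _INDEPENDENT
    else:
        raise SelectionError(f"unknown case {case!r}")
    if "Tg" not in taxa:
        raise SelectionError("the outgroup taxon Tg must be present")
    if foreground not in ("W", "Z"):
        raise SelectionError("foreground must be 'W' or 'Z'")
    keep = {f"{t}_{c}" for t in taxa for c in ("Z", "W")}
    pruned = _prune(topo, keep)
    return LabeledTreeTemplate(case=case, topology=pruned, foreground=foreground)


@dataclass
class SelectionTestResult:
    model: str
    foreground: str
    lnl_alt: float
    lnl_null: float
    lrt: float
    df: int
    p_value: float
    omega_background: float
    omega_foreground: float | None      # branch model: fitted/fixed foreground omega
    p_value_mixture: float | None = None   # branch-site: 0/chi2(1) mixture
    site_classes: dict | None = None       # branch-site: proportions and omega2
    converged: bool = True


# ---------------------------------------------------------------------------
# Tree compilation and pruning likelihood
# ---------------------------------------------------------------------------

class _CodonTreeLik:
    def __init__(self, template: LabeledTreeTemplate, aln: CodonAlignment,
                 model: _codon.CodonModel):
        self.model = model
        labels = set(aln.labels)
        tips = template.tips()
        missing = [t for t in tips if t not in labels]
        if missing:
            raise SelectionError(f"alignment lacks template tips {missing}")
        topo = template.topology
        # trifurcate the root for an unrooted parameterisation
        if isinstance(topo, tuple) and len(topo) == 2 and isinstance(topo[1], tuple):
            topo = (topo[0],) + tuple(topo[1])
        mat = aln.codon_matrix(tips)
        # pattern compression
        _, first, inverse, counts = np.unique(
            mat, axis=1, return_index=True, return_inverse=True, return_counts=True
        )
        self.tip_codons = {t: mat[i, first] for i, t in enumerate(tips)}
        self.counts = counts.astype(float)
        self.inverse = inverse
        self.n_pat = len(first)
        self.n_codons_total = mat.shape[1]

        self.nodes: list[dict] = []     # post-order, excluding root

        def build(n):
            if isinstance(n, str):
                idx = len(self.nodes)
                self.nodes.append({"tip": n, "children": []})
            else:
                kids = [build(c) for c in n]
                idx = len(self.nodes)
                self.nodes.append({"tip": None, "children": kids})
            return idx

        self.root_children = [build(c) for c in topo]
        self.n_branches = len(self.nodes)
        # foreground = branches whose subtree tips are all on the foreground chromosome
        fg = template.foreground

        def tipset(i):
            node = self.nodes[i]
            if node["tip"] is not None:
                return {node["tip"]}
            s = set()
            for k in node["children"]:
                s |= tipset(k)
            return s

        self.is_foreground = np.zeros(self.n_branches, dtype=bool)
        for i in range(self.n_branches):
            ts = tipset(i)
            if ts and all(t.endswith(f"_{fg}") for t in ts) and "Tg_Z" not in ts:
                self.is_foreground[i] = True

    def _partials(self, bl: np.ndarray, kappa: float, omega_branch: np.ndarray) -> np.ndarray:
        """Root partial (61, n_pat) for per-branch omega values."""
        parts: list[np.ndarray] = [None] * self.n_branches
        contrib: list[np.ndarray] = [None] * self.n_branches

        for i, node in enumerate(self.nodes):
            if node["tip"] is not None:
                part = None
            else:
                part = np.ones((_codon.N_CODONS, self.n_pat))
                for k in node["children"]:
                    part *= contrib[k]
            p = self.model.transition_matrix(kappa, float(omega_branch[i]), float(bl[i]))
            if node["tip"] is not None:
                cod = self.tip_codons[node["tip"]]
                c = np.ones((_codon.N_CODONS, self.n_pat))
                known = cod >= 0
                c[:, known] = p[:, cod[known]]
                contrib[i] = c
            else:
                contrib[i] = p @ part
        root = np.ones((_codon.N_CODONS, self.n_pat))
        for k in self.root_children:
            root *= contrib[k]
        return root

    def loglik_branch(self, bl, kappa, omega_bg, omega_fg) -> float:
        ob = np.where(self.is_foreground, omega_fg, omega_bg)
        root = self._partials(bl, kappa, ob)
        site = self.model.pi @ root
        return float(np.dot(self.counts, np.log(np.maximum(site, 1e-300))))

    def loglik_branch_site(self, bl, kappa, p0, p1, omega0, omega2) -> float:
        fg = self.is_foreground
        n = self.n_branches
        specs = [
            (p0, np.full(n, omega0)),
            (p1, np.full(n, 1.0)),
        ]
        rest = max(0.0, 1.0 - p0 - p1)
        denom = max(p0 + p1, 1e-12)
        specs.append((rest * p0 / denom, np.where(fg, omega2, omega0)))
        specs.append((rest * p1 / denom, np.where(fg, omega2, 1.0)))
        site = np.zeros(self.n_pat)
        for prop, ob in specs:
            if prop <= 0:
                continue
            root = self._partials(bl, kappa, ob)
            site += prop * (self.model.pi @ root)
        return float(np.dot(self.counts, np.log(np.maximum(site, 1e-300))))


def _build_model(aln: CodonAlignment, tips: list[str]) -> _codon.CodonModel:
    codons = []
    for t in tips:
        seq = aln[t]
        for s in aln.unmasked_codon_starts():
            c = seq[s : s + 3]
            if c in _codon.CODON_INDEX:
                codons.append(c)
    return _codon.CodonModel(_codon.f3x4_frequencies(codons), style="gy94")


_BL_BOUNDS = (np.log(1e-6), np.log(20.0))
_KAPPA_BOUNDS = (np.log(0.2), np.log(30.0))
_OMEGA_BOUNDS = (np.log(1e-5), np.log(40.0))


def branch_model_lrt(
    aln: CodonAlignment,
    template: LabeledTreeTemplate,
    constraint: str = "fix1",
    start_bl: float = 0.2,
) -> SelectionTestResult:
    """LRT of free foreground omega against a constrained null.

    ``constraint`` is "fix1" (foreground omega = 1, the neutral null) or
    "fix0" (foreground omega = 0, numerically floored: strict purifying
    selection on the foreground).  Background omega, kappa and all branch
    lengths are free in both models.
    """
    if constraint not in ("fix1", "fix0"):
        raise SelectionError("constraint must be 'fix1' or 'fix0'")
    lik = _CodonTreeLik(template, aln, _build_model(aln, template.tips()))
    nb = lik.n_branches

    def fit(omega_fg_fixed: float | None, x_init=None):
        free_fg = omega_fg_fixed is None
        k = nb + 2 + (1 if free_fg else 0)

        def nll(x):
            bl = np.exp(x[:nb])
            kappa = np.exp(x[nb])
            om_bg = np.exp(x[nb + 1])
            om_fg = np.exp(x[nb + 2]) if free_fg else omega_fg_fixed
            return -lik.loglik_branch(bl, kappa, om_bg, om_fg)

        if x_init is None:
            x_init = np.concatenate([
                np.full(nb, np.log(start_bl)), [np.log(2.0)], [np.log(0.3)],
                [np.log(0.5)] if free_fg else [],
            ])
        bounds = [_BL_BOUNDS] * nb + [_KAPPA_BOUNDS, _OMEGA_BOUNDS] + (
            [_OMEGA_BOUNDS] if free_fg else []
        )
        res = minimize(nll, x_init, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10})
        return res

    res_alt = fit(None)
    if not np.isfinite(res_alt.fun):
        raise SelectionError("free branch-model fit failed to converge")
    fg_fixed = 1.0 if constraint == "fix1" else OMEGA_FLOOR
    res_null = fit(fg_fixed, x_init=res_alt.x[: nb + 2])
    lnl_alt, lnl_null = -res_alt.fun, -res_null.fun
    if lnl_null > lnl_alt + 1e-6:
        # nested models: re-polish the alternative from the null's optimum
        res_alt2 = fit(None, x_init=np.concatenate([res_null.x, [np.log(fg_fixed)]]))
        if -res_alt2.fun > lnl_alt:
            res_alt, lnl_alt = res_alt2, -res_alt2.fun
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return SelectionTestResult(
        model=f"branch:{constraint}",
        foreground=template.foreground,
        lnl_alt=lnl_alt, lnl_null=lnl_null, lrt=lrt, df=1,
        p_value=float(chi2.sf(lrt, 1)),
        omega_background=float(np.exp(res_alt.x[nb + 1])),
        omega_foreground=float(np.exp(res_alt.x[nb + 2])),
        converged=bool(res_alt.success and res_null.success),
    )


def branch_site_test(
    aln: CodonAlignment,
    template: LabeledTreeTemplate,
    start_bl: float = 0.2,
) -> SelectionTestResult:
    """Branch-site model A test of positive selection on the foreground.

    The alternative estimates omega2 >= 1 for foreground site classes
    2a/2b; the null fixes omega2 = 1.  Site-class proportions derive from
    (p0, p1) as in model A.  Reported p-values: chi2(1) and the 0/chi2(1)
    mixture.
    """
    lik = _CodonTreeLik(template, aln, _build_model(aln, template.tips()))
    nb = lik.n_branches

    def unpack(x, free_w2):
        bl = np.exp(x[:nb])
        kappa = np.exp(x[nb])
        a, b = x[nb + 1], x[nb + 2]
        p01 = 1.0 / (1.0 + np.exp(-a))          # p0 + p1
        q = 1.0 / (1.0 + np.exp(-b))            # p0 / (p0 + p1)
        p0, p1 = p01 * q, p01 * (1 - q)
        omega0 = 1.0 / (1.0 + np.exp(-x[nb + 3]))
        omega2 = 1.0 + np.exp(x[nb + 4]) if free_w2 else 1.0
        return bl, kappa, p0, p1, omega0, omega2

    def fit(free_w2: bool, x_init=None):
        k = nb + 4 + (1 if free_w2 else 0)

        def nll(x):
            bl, kappa, p0, p1, om0, om2 = unpack(x, free_w2)
            return -lik.loglik_branch_site(bl, kappa, p0, p1, om0, om2)

        if x_init is None:
            x_init = np.concatenate([
                np.full(nb, np.log(start_bl)), [np.log(2.0)],
                [1.0, 1.0, 0.0], [np.log(1.0)] if free_w2 else [],
            ])
        bounds = [_BL_BOUNDS] * nb + [_KAPPA_BOUNDS] + [(-8, 8), (-8, 8), (-8, 8)] + (
            [(np.log(1e-4), np.log(60.0))] if free_w2 else []
        )
        return minimize(nll, x_init, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": 600, "ftol": 1e-10})

    res_null = fit(False)
    res_alt = fit(True, x_init=np.concatenate([res_null.x, [np.log(0.5)]]))
    lnl_alt, lnl_null = -res_alt.fun, -res_null.fun
    if lnl_alt < lnl_null:                      # nesting guard
        lnl_alt = lnl_null
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p_chi = float(chi2.sf(lrt, 1))
    p_mix = 0.5 * p_chi if lrt > 0 else 1.0
    bl, kappa, p0, p1, om0, om2 = unpack(res_alt.x, True)
    rest = max(0.0, 1.0 - p0 - p1)
    denom = max(p0 + p1, 1e-12)
    return SelectionTestResult(
        model="branch-site:A",
        foreground=template.foreground,
        lnl_alt=lnl_alt, lnl_null=lnl_null, lrt=lrt, df=1,
        p_value=p_chi, p_value_mixture=float(p_mix),
        omega_background=float(om0),
        omega_foreground=float(om2),
        site_classes=dict(
            p0=float(p0), p1=float(p1),
            p2a=float(rest * p0 / denom), p2b=float(rest * p1 / denom),
            omega0=float(om0), omega2=float(om2),
        ),
        converged=bool(res_alt.success and res_null.success),
    )
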