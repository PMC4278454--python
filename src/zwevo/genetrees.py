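"""Maximum-likelihood gene trees and shared/independent topology calls.

Trees are searched exhaustively over all unrooted topologies (3 for 4 tips,
15 for 5, 105 for 6), with branch lengths and the HKY85
transition/transversion ratio optimised per topology, and rooted on a
designated outgroup for reporting.  Bootstrap support is computed either by
refitting every topology on column-resampled alignments (codon triplets are
resampled to preserve frame) or by the RELL approximation (resampling
per-codon log-likelihood contributions at the original optima), which gives
near-identical supports at a fraction of the cost and is used by the large
simulation studies.

A gene tree over gametolog tips is classified "shared" when the W-linked
tips form a clade with bootstrap support at or above the threshold (the
signature of recombination suppression predating speciation), "independent"
when each species' Z+W tips cluster, and "unresolved" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .seqio import CodonAlignment

NUCS = "ACGT"
_NUC_IDX = {n: i for i, n in enumerate(NUCS)}


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Topology enumeration (unrooted, represented with a trifurcating root)
# ---------------------------------------------------------------------------

def _insertions(node, tip):
    yield (node, tip)
    if isinstance(node, tuple):
        a, b = node
        for na in _insertions(a, tip):
            yield (na, b)
        for nb in _insertions(b, tip):
            yield (a, nb)


def enumerate_topologies(n_tips: int) -> list[tuple]:
    """All unrooted topologies over tips 0..n_tips-1 (trifurcating root)."""
    if n_tips < 4:
        raise TreeError("need at least 4 tips")
    if n_tips > 8:
        raise TreeError("exhaustive search supports at most 8 tips")
    trees = [(0, 1, 2)]
    for tip in range(3, n_tips):
        new = []
        for a, b, c in trees:
            for na in _insertions(a, tip):
                new.append((na, b, c))
            for nb in _insertions(b, tip):
                new.append((a, nb, c))
            for nc in _insertions(c, tip):
                new.append((a, b, nc))
        trees = new
    return trees


def _splits_of(topology, n_tips: int) -> set[frozenset]:
    """Non-trivial bipartitions (as frozensets of tip indices, smaller side
    canonicalised by excluding tip n-1's side)."""
    out = set()

    def tipset(node):
        if isinstance(node, int):
            return {node}
        a, b = node
        return tipset(a) | tipset(b)

    def walk(node):
        if isinstance(node, int):
            return
        s = tipset(node)
        if 1 < len(s) < n_tips - 1:
            side = s if (n_tips - 1) not in s else set(range(n_tips)) - s
            out.add(frozenset(side))
        for c in node:
            walk(c)

    for child in topology:
        walk(child)
    return out


# ---------------------------------------------------------------------------
# HKY85 likelihood on a fixed topology
# ---------------------------------------------------------------------------

class _HKY:
    def __init__(self, freqs: np.ndarray):
        self.pi = freqs

    def q(self, kappa: float) -> np.ndarray:
        pi = self.pi
        q = np.zeros((4, 4))
        for i, a in enumerate(NUCS):
            for j, b in enumerate(NUCS):
                if i == j:
                    continue
                ts = (a in "AG" and b in "AG") or (a in "CT" and b in "CT")
                q[i, j] = pi[j] * (kappa if ts else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        return q / mu

    def decomp(self, kappa: float):
        q = self.q(kappa)
        d = np.sqrt(self.pi)
        b = (q * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh(0.5 * (b + b.T))
        return lam, (u.T / d[None, :]).T, u.T * d[None, :]

    def p(self, decomp, t: float) -> np.ndarray:
        lam, right, left = decomp
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 1e-300, None, out=p)
        return p


class _TopologyLik:
    """Compiled pruning structure for one topology."""

    def __init__(self, topology, tip_partials: list[np.ndarray], hky: _HKY):
        self.hky = hky
        self.n_pat = tip_partials[0].shape[1]
        # flatten: nodes in post-order; node entries (children list, branch idx)
        self.children: list[list[int]] = []
        self.tip_of: list[int | None] = []
        self.branch_of_node: list[int] = []
        order = []

        def build(node):
            if isinstance(node, int):
                idx = len(order)
                order.append(node)
                self.children.append([])
                self.tip_of.append(node)
            else:
                kids = [build(c) for c in node]
                idx = len(order)
                order.append(None)
                self.children.append(kids)
                self.tip_of.append(None)
            self.branch_of_node.append(len(self.branch_of_node))
            return idx

        roots = [build(c) for c in topology]
        self.root_children = roots
        self.n_branches = len(self.branch_of_node)
        self.tip_partials = tip_partials

    def site_loglik(self, log_bl: np.ndarray, kappa: float) -> np.ndarray:
        decomp = self.hky.decomp(kappa)
        bl = np.exp(log_bl)
        partials: list[np.ndarray] = [None] * len(self.children)
        for idx in range(len(self.children)):
            if self.tip_of[idx] is not None:
                part = self.tip_partials[self.tip_of[idx]]
            else:
                part = np.ones((4, self.n_pat))
                for k in self.children[idx]:
                    pk = self.hky.p(decomp, bl[self.branch_of_node[k]])
                    part = part * (pk @ partials[k])
            partials[idx] = part
        root = np.ones((4, self.n_pat))
        for k in self.root_children:
            pk = self.hky.p(decomp, bl[self.branch_of_node[k]])
            root = root * (pk @ partials[k])
        site_l = self.hky.pi @ root
        return np.log(np.maximum(site_l, 1e-300))


def _tip_partials(seqs: list[str], columns: list[int]) -> list[np.ndarray]:
    parts = []
    for s in seqs:
        m = np.ones((4, len(columns)))
        for ci, col in enumerate(columns):
            ch = s[col]
            if ch in _NUC_IDX:
                m[:, ci] = 0.0
                m[_NUC_IDX[ch], ci] = 1.0
        parts.append(m)
    return parts


def _compress(parts: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (pattern partials, counts,
    pattern index per original column)."""
    keys = np.vstack([np.argmax(p, axis=0) + 4 * (p.sum(axis=0) > 3.5) for p in parts])
    _, first, inverse, counts = np.unique(
        keys, axis=1, return_index=True, return_inverse=True, return_counts=True
    )
    pat_parts = [p[:, first] for p in parts]
    return pat_parts, counts.astype(float), inverse


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

@dataclass
class SupportedTree:
    tips: tuple[str, ...]
    topology: tuple
    branch_lengths: np.ndarray
    kappa: float
    lnl: float
    outgroup: str
    supports: dict[frozenset, float] = field(default_factory=dict)  # tip-label sets
    star: bool = False                      # identical sequences: arbitrary topology
    n_boot: int = 0
    _fit_cache: dict = field(default_factory=dict, repr=False)

    def split_labels(self) -> set[frozenset]:
        n = len(self.tips)
        return {
            frozenset(self.tips[i] for i in s) for s in _splits_of(self.topology, n)
        }

    def newick(self, with_support: bool = True) -> str:
        def tipset(node):
            if isinstance(node, int):
                return frozenset({self.tips[node]})
            a, b = node
            return tipset(a) | tipset(b)

        def fmt(node):
            if isinstance(node, int):
                return self.tips[node]
            parts = ",".join(fmt(c) for c in node)
            label = ""
            if with_support and self.supports:
                s = self.supports.get(tipset(node))
                if s is None:
                    s = self.supports.get(frozenset(self.tips) - tipset(node))
                if s is not None:
                    label = f"{s:.0f}"
            return f"({parts}){label}"

        body = ",".join(fmt(c) for c in self.topology)
        return f"({body});"


def _extract_records(aln) -> dict[str, str]:
    if isinstance(aln, CodonAlignment):
        cols = sorted(set(range(aln.length)) - aln.masked_columns())
        return {lab: "".join(aln[lab][c] for c in cols) for lab in aln.labels}
    return dict(aln)


def ml_tree(
    aln,
    outgroup: str,
    fix_kappa: float | None = None,
) -> SupportedTree:
    """Exhaustive ML topology search under HKY85 with empirical frequencies.

    ``aln`` is a CodonAlignment (unmasked columns used) or a label->sequence
    mapping of equal-length nucleotide strings.  The returned tree carries
    the fitted branch lengths and per-topology fit cache used by
    :func:`bootstrap_support`.
    """
    records = _extract_records(aln)
    if outgroup not in records:
        raise TreeError(f"outgroup {outgroup!r} not among tips")
    labels = sorted(records)
    n = len(labels)
    if not 4 <= n <= 8:
        raise TreeError("tree search supports 4-8 sequences")
    seqs = [records[lab] for lab in labels]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise TreeError("sequences differ in length")

    counts4 = np.zeros(4)
    for s in seqs:
        for ch, i in _NUC_IDX.items():
            counts4[i] += s.count(ch)
    freqs = counts4 / counts4.sum() if counts4.sum() else np.full(4, 0.25)
    hky = _HKY(freqs)

    parts_full = _tip_partials(seqs, list(range(length)))
    pat_parts, counts, inverse = _compress(parts_full)

    star = all(s == seqs[0] for s in seqs)

    fits = {}
    best_topo, best = None, None
    for topo in enumerate_topologies(n):
        lik = _TopologyLik(topo, pat_parts, hky)
        nb = lik.n_branches
        x0 = np.concatenate([np.full(nb, np.log(0.05)), [] if fix_kappa else [np.log(2.0)]])

        def nll(x, lik=lik, nb=nb):
            kappa = fix_kappa if fix_kappa else float(np.exp(x[nb]))
            return -float(np.dot(counts, lik.site_loglik(x[:nb], kappa)))

        bounds = [(np.log(1e-8), np.log(10.0))] * nb + (
            [] if fix_kappa else [(np.log(0.1), np.log(50.0))]
        )
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-10})
        fits[topo] = res
        if best is None or res.fun < best.fun - 1e-9:
            best, best_topo = res, topo

    nb = _TopologyLik(best_topo, pat_parts, hky).n_branches
    kappa_hat = fix_kappa if fix_kappa else float(np.exp(best.x[nb]))
    tree = SupportedTree(
        tips=tuple(labels),
        topology=best_topo,
        branch_lengths=np.exp(best.x[:nb]),
        kappa=kappa_hat,
        lnl=-float(best.fun),
        outgroup=outgroup,
        star=star,
    )
    tree._fit_cache = {
        "fits": fits, "pat_parts": pat_parts, "counts": counts, "inverse": inverse,
        "hky": hky, "length": length, "fix_kappa": fix_kappa,
    }
    return tree


def bootstrap_support(
    aln,
    outgroup: str,
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "refit",
    tree: SupportedTree | None = None,
) -> SupportedTree:
    """Bootstrap supports for the bipartitions of the ML tree.

    Codon triplets of columns are resampled with replacement so reading
    frame is preserved.  ``method="refit"`` re-optimises every topology per
    replicate; ``method="rell"`` resamples the per-codon log-likelihoods at
    the original optima (Kishino–Hasegawa), which approximates the refit
    supports closely and is dramatically faster.
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    if tree is None:
        tree = ml_tree(aln, outgroup)
    cache = tree._fit_cache
    n = len(tree.tips)
    rng = np.random.default_rng(seed)
    length = cache["length"]
    n_codons = length // 3
    inverse = cache["inverse"]
    topo_splits = {topo: _splits_of(topo, n) for topo in cache["fits"]}
    ml_splits = _splits_of(tree.topology, n)
    tally = {s: 0 for s in ml_splits}

    if method == "rell":
        # per-codon log-likelihood of each topology at its optimum
        codon_lnl = {}
        for topo, res in cache["fits"].items():
            lik = _TopologyLik(topo, cache["pat_parts"], cache["hky"])
            nb = lik.n_branches
            kappa = cache["fix_kappa"] or float(np.exp(res.x[nb]))
            site = lik.site_loglik(res.x[:nb], kappa)[inverse]
            codon_lnl[topo] = site[: n_codons * 3].reshape(n_codons, 3).sum(axis=1)
        topos = list(codon_lnl)
        mat = np.vstack([codon_lnl[t] for t in topos])  # (n_topo, n_codons)
        for _ in range(n_reps):
            w = rng.multinomial(n_codons, np.full(n_codons, 1.0 / n_codons))
            scores = mat @ w
            win = topos[int(np.argmax(scores))]
            for s in topo_splits[win]:
                if s in tally:
                    tally[s] += 1
    elif method == "refit":
        pat_of_codon = inverse[: n_codons * 3].reshape(n_codons, 3)
        n_pat = cache["pat_parts"][0].shape[1]
        for _ in range(n_reps):
            draw = rng.integers(0, n_codons, size=n_codons)
            pat_counts = np.bincount(pat_of_codon[draw].ravel(), minlength=n_pat).astype(float)
            best_topo, best_val = None, np.inf
            for topo, res in cache["fits"].items():
                lik = _TopologyLik(topo, cache["pat_parts"], cache["hky"])
                nb = lik.n_branches

                def nll(x, lik=lik, nb=nb):
                    kappa = cache["fix_kappa"] or float(np.exp(x[nb]))
                    return -float(np.dot(pat_counts, lik.site_loglik(x[:nb], kappa)))

                r = minimize(nll, res.x, method="L-BFGS-B",
                             options={"maxiter": 40, "ftol": 1e-8})
                if r.fun < best_val:
                    best_val, best_topo = r.fun, topo
            for s in topo_splits[best_topo]:
                if s in tally:
                    tally[s] += 1
    else:
        raise TreeError(f"unknown bootstrap method {method!r}")

    tree.supports = {
        frozenset(tree.tips[i] for i in s): 100.0 * c / n_reps for s, c in tally.items()
    }
    tree.n_boot = n_reps
    return tree


def classify_topology(tree: SupportedTree, support_threshold: float = 95.0) -> str:
    """Classify a gametolog gene tree as shared / independent / unresolved.

    "shared": the W tips (outgroup excluded) form a clade with support >=
    threshold — recombination suppression predates the speciation(s).
    "independent": every species with both Z and W present forms its own
    Z+W clade at the threshold.  Anything else is "unresolved".
    """
    if not tree.supports:
        raise TreeError("tree carries no bootstrap supports; run bootstrap_support first")
    tips = [t for t in tree.tips if t != tree.outgroup]
    w_tips = frozenset(t for t in tips if t.endswith("_W"))
    if not w_tips or any("_" not in t for t in tips):
        raise TreeError("tips must be labelled <taxon>_<Z|W>")
    species = {}
    for t in tips:
        species.setdefault(t.rsplit("_", 1)[0], set()).add(t)

    def support_of(split: frozenset) -> float | None:
        n = len(tree.tips)
        if len(split) < 2 or len(split) > n - 2:
            return None
        comp = frozenset(tree.tips) - split
        return tree.supports.get(split, tree.supports.get(comp))

    if len(w_tips) >= 2:
        s = support_of(w_tips)
        if s is not None and s >= support_threshold:
            return "shared"
    pair_species = [frozenset(v) for v in species.values() if len(v) == 2]
    if pair_species:
        sups = [support_of(p) for p in pair_species]
        if all(s is not None and s >= support_threshold for s in sups):
            return "independent"
    return "unresolved"
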