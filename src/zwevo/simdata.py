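"""Synthetic gametolog datasets with known truth.

The generator emulates the statistical structure of avian Z/W gametolog
data: coding sequences evolve along the species tree
(((Gg, Mg), Ap), Tg)  with splits at 30, 90 and 130 My; within each species
the Z and W copies of a locus evolve as a single sequence until the locus's
recombination-suppression time and on separate lineages afterwards.  W
branches evolve more slowly than Z branches (male-mutation bias), with the
pairwise Z+W synonymous rate summing to the molecular-clock constant
3.8e-9 per site per year, so that the expected Z–W synonymous divergence of
a locus suppressed T years ago is 3.8e-9 * T.

Sequence evolution follows an HKY mutation process layered on codons with
nonsynonymous changes damped by omega (the Muse–Gaut codon chain), sampled
exactly per branch via the transition matrix, and scaled so one unit of
branch length equals one synonymous substitution per synonymous site.

Gene-conversion tracts, sexed expression matrices (W genes female-limited)
and female-limited SNP tables can be layered on top; every locus carries a
truth record.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codon as _codon

CLOCK_RATE = 3.8e-9  # synonymous substitutions / site / year, Z+W combined

DEFAULT_SPLITS = {"GgMg": 30e6, "Galloanserae": 90e6, "root": 130e6}
INGROUP = ("Gg", "Mg", "Ap")
OUTGROUP = "Tg"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``suppression_times`` is either one taxon->years map applied to every
    locus or a list of such maps (one per locus).  Taxa sharing the same
    time, with that time at or above their species split, share a single
    suppression event (their W genes form a clade); times younger than the
    split are independent per-lineage events.
    """

    n_loci: int = 10
    cds_length: int = 900
    suppression_times: dict[str, float] | list[dict[str, float]] = field(
        default_factory=lambda: {"Gg": 90e6, "Mg": 90e6, "Ap": 90e6}
    )
    mu_w: float = CLOCK_RATE / 3.4          # W rate; mu_z/mu_w = 2.4 (male-mutation bias)
    mu_z: float = CLOCK_RATE * 2.4 / 3.4
    omega_w: float = 0.1
    omega_z: float = 0.2
    kappa: float = 2.0
    splits: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPLITS))
    exon_bp: int = 150                       # synthetic exon size (multiple of 3)
    conversion_tracts: list[tuple] = field(default_factory=list)
    seed: int = 0

    def per_locus_times(self) -> list[dict[str, float]]:
        if isinstance(self.suppression_times, dict):
            times = [dict(self.suppression_times) for _ in range(self.n_loci)]
        else:
            if len(self.suppression_times) != self.n_loci:
                raise SimulationError("suppression_times list length != n_loci")
            times = [dict(t) for t in self.suppression_times]
        return times

    def validate(self) -> None:
        if self.cds_length <= 0 or self.cds_length % 3:
            raise SimulationError("cds_length must be a positive multiple of 3")
        if self.exon_bp <= 0 or self.exon_bp % 3:
            raise SimulationError("exon_bp must be a positive multiple of 3")
        if min(self.mu_w, self.mu_z) <= 0:
            raise SimulationError("substitution rates must be positive")
        root = self.splits["root"]
        for li, tmap in enumerate(self.per_locus_times()):
            for taxon, t in tmap.items():
                if taxon not in INGROUP:
                    raise SimulationError(f"unknown taxon {taxon!r}")
                if not 0 <= t <= root:
                    raise SimulationError(
                        f"locus {li}: suppression time {t:g} outside [0, root age]"
                    )
            for _t, group in _event_groups(tmap, self.splits):
                join = _join_age_with_others(group, set(tmap), self.splits)
                if join is not None and _t > join:
                    raise SimulationError(
                        f"locus {li}: suppression at {_t:g} for {sorted(group)} predates the "
                        f"origin of their lineage (joins other W-bearing taxa at {join:g})"
                    )


def _event_groups(tmap: dict[str, float], splits: dict[str, float]) -> list[tuple[float, frozenset]]:
    """Suppression events: taxa sharing a time form one event only when the
    time is at or above their species MRCA; otherwise the events are
    independent per-lineage even if the times coincide."""
    by_time: dict[float, set[str]] = {}
    for taxon, t in tmap.items():
        by_time.setdefault(float(t), set()).add(taxon)
    events: list[tuple[float, frozenset]] = []
    for t, taxa in sorted(by_time.items()):
        remaining = set(taxa)
        for clade in ({"Gg", "Mg", "Ap"}, {"Gg", "Mg"}, {"Gg", "Ap"}, {"Mg", "Ap"}):
            if clade <= remaining and t >= _species_mrca_age(clade, splits):
                events.append((t, frozenset(clade)))
                remaining -= clade
        for tx in sorted(remaining):
            events.append((t, frozenset({tx})))
    return events


def _species_mrca_age(taxa: set[str], splits: dict[str, float]) -> float:
    if len(taxa) <= 1:
        return 0.0
    if taxa <= {"Gg", "Mg"}:
        return splits["GgMg"]
    return splits["Galloanserae"]


def _join_age_with_others(group: set[str], all_taxa: set[str], splits) -> float | None:
    others = all_taxa - group
    if not others:
        return None
    return min(_species_mrca_age(group | {o}, splits) for o in others)


# ---------------------------------------------------------------------------
# Gene-tree construction
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name: str, age: float, children=None):
        self.name = name
        self.age = age
        self.children = children or []
        self.parent = None

    def tips(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


def _link_parents(node: _Node):
    for c in node.children:
        c.parent = node
        _link_parents(c)


def _build_z_tree(splits: dict[str, float]) -> _Node:
    gg = _Node("Gg_Z", 0.0)
    mg = _Node("Mg_Z", 0.0)
    ap = _Node("Ap_Z", 0.0)
    tg = _Node(f"{OUTGROUP}_Z", 0.0)
    ggmg = _Node("anc_GgMg", splits["GgMg"], [gg, mg])
    gal = _Node("anc_Galloanserae", splits["Galloanserae"], [ggmg, ap])
    root = _Node("root", splits["root"], [gal, tg])
    _link_parents(root)
    return root


def _build_w_subtree(group: set[str], splits: dict[str, float], event_age: float) -> _Node:
    tips = {t: _Node(f"{t}_W", 0.0) for t in sorted(group)}
    if group == {"Gg", "Mg", "Ap"}:
        inner = _Node("w_anc_GgMg", splits["GgMg"], [tips["Gg"], tips["Mg"]])
        top = _Node("w_anc_all", splits["Galloanserae"], [inner, tips["Ap"]])
    elif group == {"Gg", "Mg"}:
        top = _Node("w_anc_GgMg", splits["GgMg"], [tips["Gg"], tips["Mg"]])
    elif len(group) == 1:
        (top,) = tips.values()
    else:  # {Gg, Ap} or {Mg, Ap}: MRCA is the Galloanserae split
        a, b = sorted(group)
        top = _Node("w_anc_pair", splits["Galloanserae"], [tips[a], tips[b]])
    return top


def build_gene_tree(tmap: dict[str, float], splits: dict[str, float]) -> _Node:
    """Gene tree for one locus: the species Z tree plus W lineages attached
    at their suppression times."""
    root = _build_z_tree(splits)
    events = sorted(_event_groups(tmap, splits), key=lambda e: (e[0], sorted(e[1])))
    for t, group in events:
        w_sub = _build_w_subtree(set(group), splits, t)
        # Z lineage ancestral to the group at age t
        node = _mrca_of_tips(root, {f"{g}_Z" for g in group})
        while node.parent is not None and node.parent.age <= t:
            node = node.parent
        parent = node.parent
        if parent is None:
            raise SimulationError(f"suppression time {t:g} at or above the root age")
        joint = _Node(f"supp_{t:g}", float(t), [node, w_sub])
        parent.children = [joint if c is node else c for c in parent.children]
        joint.parent = parent
        node.parent = joint
        w_sub.parent = joint
    return root


def _mrca_of_tips(root: _Node, names: set[str]) -> _Node:
    """Deepest node whose tip set covers ``names``."""
    node = root
    if not names <= _tipnames(root):
        raise SimulationError(f"tips {names} not found")
    while True:
        nxt = [c for c in node.children if names <= _tipnames(c)]
        if not nxt:
            return node
        node = nxt[0]


def _tipnames(node: _Node) -> set[str]:
    return {t.name for t in node.tips()}


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    locus: str
    suppression_times: dict[str, float]
    tracts: list[dict] = field(default_factory=list)

    def topology_class(self, taxon_a: str = "Gg", taxon_b: str = "Mg", splits=None) -> str:
        """Truth label for a two-species comparison: 'shared' iff both taxa
        descend from one suppression event."""
        ta = self.suppression_times.get(taxon_a)
        tb = self.suppression_times.get(taxon_b)
        if ta is None or tb is None:
            raise KeyError("taxon without a W in this locus")
        splits = splits or DEFAULT_SPLITS
        mrca = _species_mrca_age({taxon_a, taxon_b}, splits)
        return "shared" if (ta == tb and ta >= mrca) else "independent"


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: list[dict[str, str]]          # per locus: label -> CDS
    truth: list[LocusTruth]
    exon_map: list[tuple[int, int, int]]     # shared across loci (CDS coords)
    expression: pd.DataFrame | None = None
    expression_truth: dict[str, str] | None = None
    snps: pd.DataFrame | None = None

    def locus_names(self) -> list[str]:
        return [t.locus for t in self.truth]


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _simulate_on_tree(
    root: _Node, model: _codon.CodonModel, cfg: SimulationConfig, rng: np.random.Generator,
    n_codons: int,
) -> dict[str, np.ndarray]:
    pi = model.pi
    root_state = rng.choice(_codon.N_CODONS, size=n_codons, p=pi)
    out: dict[str, np.ndarray] = {}
    t_cache: dict[float, "object"] = {}

    def branch_params(child: _Node) -> tuple[float, float]:
        tipnames = _tipnames(child)
        if all(n.endswith("_W") for n in tipnames):
            return cfg.mu_w, cfg.omega_w
        return cfg.mu_z, cfg.omega_z

    def descend(node: _Node, state: np.ndarray):
        if not node.children:
            out[node.name] = state
            return
        for child in node.children:
            mu, omega = branch_params(child)
            years = node.age - child.age
            ds_len = mu * years
            if ds_len <= 0:
                descend(child, state.copy())
                continue
            t_codon = model.t_for_ds(ds_len, cfg.kappa, omega)
            p = model.transition_matrix(cfg.kappa, omega, t_codon)
            child_state = np.empty_like(state)
            for i in np.unique(state):
                idx = np.nonzero(state == i)[0]
                child_state[idx] = rng.choice(_codon.N_CODONS, size=len(idx), p=p[i])
            descend(child, child_state)

    descend(root, root_state)
    return out


def _decode(state: np.ndarray) -> str:
    return "".join(_codon.SENSE_CODONS[i] for i in state)


def simulate_gametolog_history(config: SimulationConfig) -> SimulatedDataset:
    """Simulate gametolog CDS sets plus truth tables for every locus."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nuc_freqs = np.full((3, 4), 0.25)
    pi = _codon.uniform_codon_frequencies()
    model = _codon.CodonModel(pi, style="mg94", nuc_freqs=nuc_freqs)
    n_codons = config.cds_length // 3

    sequences, truths = [], []
    for li, tmap in enumerate(config.per_locus_times()):
        tree = build_gene_tree(tmap, config.splits)
        states = _simulate_on_tree(tree, model, config, rng, n_codons)
        sequences.append({name: _decode(s) for name, s in sorted(states.items())})
        truths.append(LocusTruth(locus=f"locus{li:03d}", suppression_times=dict(tmap)))

    exons = [
        (ei, start, min(start + config.exon_bp, config.cds_length))
        for ei, start in enumerate(range(0, config.cds_length, config.exon_bp))
    ]
    ds = SimulatedDataset(
        config=config, sequences=sequences, truth=truths, exon_map=exons,
    )
    for tract in config.conversion_tracts:
        ds = inject_gene_conversion(ds, tract)
    return ds


def inject_gene_conversion(dataset: SimulatedDataset, tract) -> SimulatedDataset:
    """Copy the donor sequence over the recipient across [start, end).

    ``tract`` = (locus index, donor label, recipient label, start, end[, time]).
    Overlapping tracts on one recipient from different donors are rejected.
    """
    locus, donor, recipient, start, end = tract[:5]
    time = tract[5] if len(tract) > 5 else 0.0
    seqs = dataset.sequences[locus]
    if donor not in seqs or recipient not in seqs:
        raise SimulationError(f"locus {locus}: unknown tip {donor!r} or {recipient!r}")
    L = len(seqs[recipient])
    if not (0 <= start < end <= L):
        raise SimulationError(f"tract coordinates [{start}, {end}) outside CDS [0, {L})")
    for prev in dataset.truth[locus].tracts:
        if prev["recipient"] == recipient and prev["donor"] != donor:
            if not (end <= prev["start"] or start >= prev["end"]):
                raise SimulationError("overlapping contradictory conversion tracts")
    new = copy.deepcopy(dataset)
    s = new.sequences[locus]
    s[recipient] = s[recipient][:start] + s[donor][start:end] + s[recipient][end:]
    new.truth[locus].tracts.append(
        {"donor": donor, "recipient": recipient, "start": int(start), "end": int(end), "time": float(time)}
    )
    return new


def simulate_diverged_pair(
    ds_true: float,
    n_codons: int = 300,
    kappa: float = 2.0,
    omega: float = 0.2,
    seed: int = 0,
) -> dict[str, str]:
    """Two CDS separated by a total synonymous divergence of ``ds_true``.

    Used for estimator calibration: the pair diverges symmetrically from a
    stationary ancestor, half the divergence on each branch.
    """
    rng = np.random.default_rng(seed)
    model = _codon.CodonModel(
        _codon.uniform_codon_frequencies(), style="mg94", nuc_freqs=np.full((3, 4), 0.25)
    )
    root = rng.choice(_codon.N_CODONS, size=n_codons, p=model.pi)
    out = {}
    for name in ("A", "B"):
        t_codon = model.t_for_ds(ds_true / 2.0, kappa, omega)
        p = model.transition_matrix(kappa, omega, t_codon)
        child = np.empty_like(root)
        for i in np.unique(root):
            idx = np.nonzero(root == i)[0]
            child[idx] = rng.choice(_codon.N_CODONS, size=len(idx), p=p[i])
        out[name] = _decode(child)
    return out


def evolve_sequence(
    seq: str, ds: float, kappa: float = 2.0, omega: float = 0.2, seed: int = 0
) -> str:
    """A copy of ``seq`` diverged by ``ds`` synonymous substitutions/site."""
    rng = np.random.default_rng(seed)
    model = _codon.CodonModel(
        _codon.uniform_codon_frequencies(), style="mg94", nuc_freqs=np.full((3, 4), 0.25)
    )
    state = _codon.encode_codons(seq)
    if (state < 0).any():
        raise SimulationError("sequence contains gaps, stops or ambiguity")
    if ds <= 0:
        return seq
    p = model.transition_matrix(kappa, omega, model.t_for_ds(ds, kappa, omega))
    child = np.empty_like(state)
    for i in np.unique(state):
        idx = np.nonzero(state == i)[0]
        child[idx] = rng.choice(_codon.N_CODONS, size=len(idx), p=p[i])
    return _decode(child)


# ---------------------------------------------------------------------------
# Expression and SNP channels
# ---------------------------------------------------------------------------

def simulate_expression(
    dataset: SimulatedDataset,
    n_males: int = 5,
    n_females: int = 5,
    mean_fpkm: float = 20.0,
    sigma: float = 0.5,
    n_autosomal: int = 50,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Sexed expression matrix: W genes female-limited, Z/autosomal biallelic.

    Lognormal noise with log-sd ``sigma`` around ``mean_fpkm``.  Returns the
    matrix (genes x samples) and a truth map gene -> {'W','Z','A'}.
    """
    if n_males < 1 or n_females < 1:
        raise SimulationError("need at least one sample per sex")
    rng = np.random.default_rng(dataset.config.seed + 1 if seed is None else seed)
    genes, klass = [], {}
    for t in dataset.truth:
        genes.append(f"{t.locus}_W"); klass[f"{t.locus}_W"] = "W"
        genes.append(f"{t.locus}_Z"); klass[f"{t.locus}_Z"] = "Z"
    for j in range(n_autosomal):
        g = f"auto{j:03d}"
        genes.append(g); klass[g] = "A"
    samples = [f"male{i}" for i in range(n_males)] + [f"female{i}" for i in range(n_females)]
    sex = ["M"] * n_males + ["F"] * n_females
    mat = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        for si, sx in enumerate(sex):
            if klass[g] == "W" and sx == "M":
                mat[gi, si] = 0.0
            else:
                mat[gi, si] = rng.lognormal(np.log(mean_fpkm), sigma)
    df = pd.DataFrame(mat, index=genes, columns=samples)
    df.attrs["sex"] = dict(zip(samples, sex))
    dataset.expression = df
    dataset.expression_truth = klass
    return df, klass


def simulate_snps(dataset: SimulatedDataset, include_w_private: bool = True, seed: int | None = None) -> pd.DataFrame:
    """Female-limited SNP table from Z/W differences.

    Every fixed Z–W difference within a species appears as a SNP carried only
    by females (Z allele from Z, W-specific allele from W).  For loci whose
    Z and W copies are identical in a species, one segregating W-private
    variant is optionally added so that very young gametologs remain
    verifiable.
    """
    rng = np.random.default_rng(dataset.config.seed + 2 if seed is None else seed)
    rows = []
    for t, seqs in zip(dataset.truth, dataset.sequences):
        for taxon in t.suppression_times:
            z, w = seqs[f"{taxon}_Z"], seqs[f"{taxon}_W"]
            diffs = [i for i, (a, b) in enumerate(zip(z, w)) if a != b]
            for pos in diffs:
                rows.append(
                    dict(gene=t.locus, taxon=taxon, position=pos, z_allele=z[pos],
                         w_allele=w[pos], female_carriers=5, male_carriers=0)
                )
            if not diffs and include_w_private:
                pos = int(rng.integers(0, len(z)))
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[z[pos]]
                rows.append(
                    dict(gene=t.locus, taxon=taxon, position=pos, z_allele=z[pos],
                         w_allele=alt, female_carriers=2, male_carriers=0)
                )
    df = pd.DataFrame(rows, columns=["gene", "taxon", "position", "z_allele", "w_allele",
                                     "female_carriers", "male_carriers"])
    dataset.snps = df
    return df
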