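"""Inter-chromosomal gene-conversion detection on silent sites.

Gene conversion copies a tract from one chromosome onto the other, leaving
a run of identical sequence between otherwise diverged gametologs.  The
detector works on silent polymorphic sites only (alignment columns where
every sequence encodes the same amino acid but nucleotides differ), which
avoids false positives produced by selection acting on protein sequence.
Candidate fragments are maximal runs of agreement between a Z/W sequence
pair — exact runs under the strict mode (gscale 0) or penalised
maximal-scoring segments allowing mismatches (gscale 2) — and significance
comes from random permutations of the polymorphic-site columns:
sim_p = (1 + #{permutation max score >= fragment score}) / (n_perm + 1),
with a Bonferroni/Karlin–Altschul-style corrected p-value reported
alongside.  Fragments are classed inner (agreement private to the pair,
the signature of conversion between the pair's ancestors) or outer, and
exons covered by less than 50 bp of fragment span are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import codon as _codon
from .seqio import CodonAlignment
from .divergence import ml_pairwise_divergence, DivergenceEstimate

GSCALE2_MISMATCH_PENALTY = 2.5   # two mismatches cancel roughly five matches


class GeneConvError(ValueError):
    pass


@dataclass
class SilentSiteProfile:
    columns: np.ndarray              # alignment column index per site, strictly increasing
    states: np.ndarray               # (n_seq, n_sites) nucleotide characters
    labels: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.columns)

    def pair_agreement(self, a: str, b: str) -> np.ndarray:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return self.states[ia] == self.states[ib]


@dataclass
class ConversionFragment:
    pair: tuple[str, str]
    start: int                       # alignment column, half-open span
    end: int
    span_bp: int
    n_sites: int
    score: float
    klass: str = "global-outer"      # global-inner | global-outer
    sim_p: float = 1.0
    corrected_p: float = 1.0
    direction: str = "unknown"
    spanning_exons: list[int] = field(default_factory=list)
    site_indices: tuple[int, ...] = ()   # indices into the profile
    warned_no_exon_map: bool = False


# ---------------------------------------------------------------------------
# Silent polymorphic sites
# ---------------------------------------------------------------------------

def silent_polymorphic_sites(aln: CodonAlignment) -> SilentSiteProfile:
    """Columns polymorphic in nucleotide but invariant in amino acid.

    Codon columns containing gaps, ambiguity or stop codons in any sequence
    are skipped; within a qualifying codon column, each of the three
    nucleotide positions that varies is one silent polymorphic site.
    """
    labels = aln.labels
    seqs = [aln[lab] for lab in labels]
    cols, states = [], []
    for cs in aln.unmasked_codon_starts():
        codons = [s[cs : cs + 3] for s in seqs]
        if any(c not in _codon.CODON_INDEX for c in codons):
            continue
        aas = {_codon.CODON_AA[c] for c in codons}
        if len(aas) != 1:
            continue
        for k in range(3):
            nts = [c[k] for c in codons]
            if len(set(nts)) > 1:
                cols.append(cs + k)
                states.append(nts)
    return SilentSiteProfile(
        columns=np.array(cols, dtype=int),
        states=np.array(states, dtype="U1").T if states else np.empty((len(labels), 0), dtype="U1"),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Fragment finding
# ---------------------------------------------------------------------------

def _segments_gscale0(agree: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of agreement (site-index half-open, score = run length)."""
    out = []
    i, m = 0, len(agree)
    while i < m:
        if agree[i]:
            j = i
            while j + 1 < m and agree[j + 1]:
                j += 1
            out.append((i, j + 1, float(j + 1 - i)))
            i = j + 1
        i += 1
    return out


def _segments_scored(agree: np.ndarray, penalty: float) -> list[tuple[int, int, float]]:
    """Disjoint maximal-scoring segments of the +1/−penalty site sequence.

    All spans that start and end on agreement sites are scored; segments
    are selected greedily by descending score (ties: leftmost, then
    longest), discarding spans that overlap a selected one.
    """
    vals = np.where(agree, 1.0, -penalty)
    m = len(vals)
    idx = np.nonzero(agree)[0]
    spans = []
    prefix = np.concatenate([[0.0], np.cumsum(vals)])
    for a in idx:
        for b in idx[idx >= a]:
            s = prefix[b + 1] - prefix[a]
            if s > 0:
                spans.append((a, b + 1, float(s)))
    spans.sort(key=lambda t: (-t[2], t[0], -(t[1] - t[0])))
    chosen: list[tuple[int, int, float]] = []
    for a, b, s in spans:
        if all(b <= ca or a >= cb for ca, cb, _ in chosen):
            chosen.append((a, b, s))
    chosen.sort()
    return chosen


def find_fragments(
    profile: SilentSiteProfile,
    pair: tuple[str, str],
    gscale: int = 0,
    penalty: float = GSCALE2_MISMATCH_PENALTY,
) -> list[ConversionFragment]:
    """Candidate conversion fragments for one ordered sequence pair."""
    if gscale not in (0, 2):
        raise GeneConvError("gscale must be 0 or 2")
    if profile.n_sites == 0:
        return []
    agree = profile.pair_agreement(*pair)
    segs = _segments_gscale0(agree) if gscale == 0 else _segments_scored(agree, penalty)
    frags = []
    for i, j, score in segs:
        c0, c1 = int(profile.columns[i]), int(profile.columns[j - 1])
        frags.append(ConversionFragment(
            pair=pair, start=c0, end=c1 + 1, span_bp=c1 - c0 + 1,
            n_sites=int(agree[i:j].sum()), score=score,
            site_indices=tuple(range(i, j)),
        ))
    return frags


def _null_max_scores(
    agree: np.ndarray, perm_idx: np.ndarray, gscale: int, penalty: float
) -> np.ndarray:
    """Max fragment score per permutation (rows of perm_idx permute sites)."""
    arr = agree[perm_idx]                      # (P, m) bool
    if gscale == 0:
        c = arr.astype(float)
        s = np.cumsum(c, axis=1)
        reset = np.where(~arr, s, 0.0)
        runlen = s - np.maximum.accumulate(reset, axis=1)
        return runlen.max(axis=1)
    vals = np.where(arr, 1.0, -penalty)
    best = np.zeros(len(arr))
    cur = np.zeros(len(arr))
    for k in range(vals.shape[1]):
        cur = np.maximum(cur + vals[:, k], 0.0)
        best = np.maximum(best, cur)
    return best


def _classify_inner_outer(profile: SilentSiteProfile, frag: ConversionFragment) -> str:
    ia = profile.labels.index(frag.pair[0])
    ib = profile.labels.index(frag.pair[1])
    others = [k for k in range(len(profile.labels)) if k not in (ia, ib)]
    if not others:
        return "global-outer"
    private = shared = 0
    for si in frag.site_indices:
        if profile.states[ia, si] != profile.states[ib, si]:
            continue
        x = profile.states[ia, si]
        if any(profile.states[o, si] == x for o in others):
            shared += 1
        else:
            private += 1
    # Any pair-private agreement site marks exchange between these two
    # lineages specifically (inner); with none, the run is explainable by
    # ancestral retention and defaults to outer.
    return "global-inner" if private >= 1 else "global-outer"


def permutation_test(
    aln: CodonAlignment,
    profile: SilentSiteProfile | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    group_spec: dict[str, str] | None = None,
    gscale: int = 0,
    penalty: float = GSCALE2_MISMATCH_PENALTY,
) -> list[ConversionFragment]:
    """Permutation test for conversion fragments between Z and W groups.

    ``group_spec`` maps sequence labels to "Z"/"W"; only between-group
    pairs are scored.  One set of column permutations is shared across
    pairs; each fragment's sim_p compares its score with the null maxima,
    and corrected_p is a Bonferroni (over pairs) Karlin–Altschul-style
    length correction.
    """
    if profile is None:
        profile = silent_polymorphic_sites(aln)
    if profile.n_sites == 0:
        return []
    if group_spec is None:
        group_spec = {lab: ("W" if lab.endswith("_W") else "Z") for lab in profile.labels}
    z_labels = sorted(l for l in profile.labels if group_spec.get(l) == "Z")
    w_labels = sorted(l for l in profile.labels if group_spec.get(l) == "W")
    pairs = [(z, w) for z in z_labels for w in w_labels]
    if not pairs:
        raise GeneConvError("group_spec defines no between-group (Z vs W) pair")
    import warnings
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small; p-values will be coarse")

    rng = np.random.default_rng(seed)
    m = profile.n_sites
    perm_idx = np.argsort(rng.random((n_perm, m)), axis=1)

    n_pairs = len(pairs)
    out: list[ConversionFragment] = []
    for pair in pairs:
        frags = find_fragments(profile, pair, gscale=gscale, penalty=penalty)
        if not frags:
            continue
        agree = profile.pair_agreement(*pair)
        null_max = _null_max_scores(agree, perm_idx, gscale, penalty)
        p_agree = float(agree.mean())
        lam = _ka_lambda_scores(p_agree, penalty) if gscale == 2 else (
            -np.log(max(p_agree, 1e-12))
        )
        for f in frags:
            f.sim_p = float((1 + np.sum(null_max >= f.score)) / (n_perm + 1))
            expect = n_pairs * m * np.exp(-lam * f.score)
            f.corrected_p = float(min(1.0, 1.0 - np.exp(-expect)))
            f.klass = _classify_inner_outer(profile, f)
            out.append(f)
    return out


def _ka_lambda_scores(p: float, penalty: float) -> float:
    """Solve E[exp(lam * X)] = 1 for X = +1 w.p. p, -penalty w.p. 1-p."""
    from scipy.optimize import brentq
    p = min(max(p, 1e-9), 1 - 1e-9)
    f = lambda lam: p * np.exp(lam) + (1 - p) * np.exp(-lam * penalty) - 1.0
    try:
        return float(brentq(f, 1e-9, 20.0))
    except ValueError:
        return -np.log(p)


# ---------------------------------------------------------------------------
# Exon-span filter
# ---------------------------------------------------------------------------

def filter_fragments_by_exon(
    fragments: list[ConversionFragment],
    exon_map: list[tuple[int, int, int]] | None,
    min_span_bp: int = 50,
) -> list[ConversionFragment]:
    """Keep, per fragment, only exons covered by >= ``min_span_bp`` of the
    fragment span; fragments left with no exon are dropped.

    A missing exon map passes fragments through with a warning flag.
    """
    out = []
    if not exon_map:
        for f in fragments:
            f.warned_no_exon_map = True
            out.append(f)
        return out
    for f in fragments:
        spanning = []
        for eid, es, ee in exon_map:
            ov = min(f.end, ee) - max(f.start, es)
            if ov >= min_span_bp:
                spanning.append(eid)
        if spanning:
            f.spanning_exons = spanning
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# Direction of conversion
# ---------------------------------------------------------------------------

def infer_direction(
    aln: CodonAlignment,
    profile: SilentSiteProfile,
    frag: ConversionFragment,
    group_spec: dict[str, str] | None = None,
    min_votes: int = 3,
    majority: float = 0.8,
    exon_map: list[tuple[int, int, int]] | None = None,
) -> str:
    """Donor/recipient call for a conversion fragment.

    At each fragment site the pair shares one state; if that state is
    carried by reference Z sequences (other species / outgroup) but no
    reference W, the tract is Z-like (donor Z), and vice versa.  The call
    requires >= ``min_votes`` informative sites with >= ``majority``
    agreement; otherwise an ML tree of the spanning-exon columns decides,
    and failing that the direction is unknown.
    """
    z_lab, w_lab = frag.pair
    if group_spec is None:
        group_spec = {lab: ("W" if lab.endswith("_W") else "Z") for lab in profile.labels}
    ia, ib = profile.labels.index(z_lab), profile.labels.index(w_lab)
    ref_z = [profile.labels.index(l) for l in profile.labels
             if l not in frag.pair and group_spec.get(l) == "Z"]
    ref_w = [profile.labels.index(l) for l in profile.labels
             if l not in frag.pair and group_spec.get(l) == "W"]
    votes_z = votes_w = 0
    for si in frag.site_indices:
        if profile.states[ia, si] != profile.states[ib, si]:
            continue
        x = profile.states[ia, si]
        in_z = any(profile.states[k, si] == x for k in ref_z)
        in_w = any(profile.states[k, si] == x for k in ref_w)
        if in_z and not in_w:
            votes_z += 1
        elif in_w and not in_z:
            votes_w += 1
    total = votes_z + votes_w
    if total >= min_votes:
        if votes_z / total >= majority:
            return f"{z_lab}->{w_lab}"
        if votes_w / total >= majority:
            return f"{w_lab}->{z_lab}"
    # exon-tree fallback over exons covered by >= 50 bp of the fragment
    exons = exon_map or (list(aln.exon_map) if aln.exon_map else None)
    if exons and len(aln.records) >= 4:
        ranges = [(es - es % 3, ee + (-ee) % 3) for eid, es, ee in exons
                  if (frag.spanning_exons and eid in frag.spanning_exons)
                  or (not frag.spanning_exons
                      and min(frag.end, ee) - max(frag.start, es) >= 50)]
        cols = sorted({c for s, e in ranges for c in range(s, min(e, aln.length))})
        if len(cols) >= 60:
            from . import genetrees
            sub = {lab: "".join(aln[lab][c] for c in cols) for lab in aln.labels}
            outgroup = "Tg_Z" if "Tg_Z" in sub else aln.labels[-1]
            try:
                tree = genetrees.ml_tree(sub, outgroup=outgroup)
                splits = tree.split_labels()
                others_w = [l for l in aln.labels if l not in frag.pair
                            and group_spec.get(l) == "W"]
                others_z = [l for l in aln.labels if l not in frag.pair
                            and group_spec.get(l) == "Z" and l != outgroup]
                full = frozenset(aln.labels)

                def has(s):
                    return s in splits or (full - s) in splits

                # a converted pair clusters together INSIDE the donor's clade:
                # pair + W references together means the tract is W-like
                if others_w and has(frozenset([z_lab, w_lab] + others_w)):
                    return f"{w_lab}->{z_lab}"
                if others_z and has(frozenset([z_lab, w_lab] + others_z)):
                    return f"{z_lab}->{w_lab}"
                if has(frozenset(frag.pair)):
                    return "unknown (exon tree clusters by species)"
            except Exception:
                pass
    return "unknown"


# ---------------------------------------------------------------------------
# Divergence recomputation after removing converted exons
# ---------------------------------------------------------------------------

def recompute_divergence_excluding(
    aln: CodonAlignment,
    converted_exons: list[int],
    a: str | None = None,
    b: str | None = None,
    min_codons: int = 30,
) -> tuple[DivergenceEstimate, DivergenceEstimate]:
    """(before, after) ML divergence with converted exons removed."""
    if not converted_exons:
        raise GeneConvError("converted exon list is empty")
    if not aln.exon_map:
        raise GeneConvError("alignment carries no exon map")
    before = ml_pairwise_divergence(aln, a, b, min_codons=min_codons)
    ranges = [(es, ee) for eid, es, ee in aln.exon_map if eid in converted_exons]
    if not ranges:
        raise GeneConvError(f"exons {converted_exons} not in exon map")
    ranges = [(s - s % 3, e + (-e) % 3) for s, e in ranges]
    reduced = aln.drop_column_ranges(ranges)
    after = ml_pairwise_divergence(reduced, a, b, min_codons=min_codons)
    return before, after
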