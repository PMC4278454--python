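"""Similarity search, orthology and gametolog pairing.

The similarity engine is an internal Smith–Waterman nucleotide aligner
(match +2 / mismatch −3, gaps −5/−2) with a Karlin–Altschul-style e-value
calibrated over the target set, so the familiar e-value cutoff semantics
(default 1e-10) carry over without an external BLAST binary; tabular BLAST
(outfmt 6) input is also accepted through :func:`read_blast_tab`.

Gametolog pairing follows a three-step rule: a species W gene is mapped to
its reference-species W ortholog by best hit, the known reference W→Z
partner gives the reference Z gene, and the species' own Z ortholog is the
reciprocal best hit of that reference Z gene — falling back to the next
best hit when reciprocity fails (typically because young gametologs are
nearly identical).  Candidate W genes are excluded when reference coverage
< 25% AND aligned length with the Z ortholog < 150 bp (literal
conjunction; an OR variant is available), and multi-copy W paralogs are
resolved to the pair with the lowest dS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from scipy.optimize import brentq

DEFAULT_EVALUE_CUTOFF = 1e-10
_KA_K = 0.3  # Karlin–Altschul prefactor (ungapped approximation)


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    target: str
    score: float
    evalue: float
    aligned_bp: int
    target_coverage: float


@dataclass
class GametologPair:
    locus: str
    taxon: str
    w_id: str
    z_id: str | None
    z_position_mb: float | None
    pairing_route: str                # reciprocal-best | next-best-fallback | unpaired
    coverage: float | None = None     # coverage of the reference W ortholog
    aligned_length_bp: int | None = None
    reason: str | None = None


def _nt_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _ka_lambda(match: float = 2.0, mismatch: float = -3.0, p_match: float = 0.25) -> float:
    f = lambda lam: p_match * np.exp(lam * match) + (1 - p_match) * np.exp(lam * mismatch) - 1.0
    return float(brentq(f, 1e-6, 5.0))

_LAMBDA = _ka_lambda()


def _evalue(score: float, m: int, n_total: int) -> float:
    return float(_KA_K * m * n_total * np.exp(-_LAMBDA * score))


def _align(aligner: PairwiseAligner, query: str, target: str) -> tuple[float, int, float]:
    alns = aligner.align(query, target)
    if len(alns) == 0:
        return 0.0, 0, 0.0
    aln = alns[0]
    target_blocks = aln.aligned[1]
    aligned_bp = int(sum(e - s for s, e in target_blocks))
    return float(aln.score), aligned_bp, aligned_bp / max(1, len(target))


def best_hits(
    queries: dict[str, str],
    targets: dict[str, str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, list[SimilarityHit]]:
    """Hits per query with e-value <= cutoff, best score first.

    Ties are broken deterministically by target id.
    """
    if not targets:
        raise ValueError("empty target set")
    if not queries:
        raise ValueError("empty query set")
    aligner = _nt_aligner()
    n_total = sum(len(s) for s in targets.values())
    out: dict[str, list[SimilarityHit]] = {}
    for qid, qseq in queries.items():
        hits = []
        for tid, tseq in targets.items():
            score, abp, cov = _align(aligner, qseq, tseq)
            ev = _evalue(score, len(qseq), n_total)
            if ev <= evalue_cutoff:
                hits.append(SimilarityHit(qid, tid, score, ev, abp, cov))
        hits.sort(key=lambda h: (-h.score, h.target))
        out[qid] = hits
    return out


def reciprocal_best_hits(
    set_a: dict[str, str],
    set_b: dict[str, str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[tuple[str, str]]:
    """(a, b) pairs where each is the other's top-scoring hit."""
    a_hits = best_hits(set_a, set_b, evalue_cutoff)
    b_hits = best_hits(set_b, set_a, evalue_cutoff)
    pairs = []
    for a, hits in a_hits.items():
        if not hits:
            continue
        b = hits[0].target
        back = b_hits.get(b, [])
        if back and back[0].target == a:
            pairs.append((a, b))
    return sorted(pairs)


def read_blast_tab(path) -> dict[str, list[SimilarityHit]]:
    """Read BLAST outfmt-6 tabular hits as the pairing substrate."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols)
    out: dict[str, list[SimilarityHit]] = {}
    for r in df.itertuples():
        out.setdefault(r.qseqid, []).append(
            SimilarityHit(r.qseqid, r.sseqid, float(r.bitscore), float(r.evalue),
                          int(r.length), 0.0)
        )
    for hits in out.values():
        hits.sort(key=lambda h: (-h.score, h.target))
    return out


def filter_w_candidates(
    coverage: float,
    aligned_length_bp: int,
    min_coverage: float = 0.25,
    min_aligned_bp: int = 150,
    mode: str = "and",
) -> tuple[bool, str | None]:
    """Exclusion rule for short W fragments.

    Default ("and"): exclude only when BOTH coverage < min_coverage and
    aligned length < min_aligned_bp (the literal conjunction).  ``mode="or"``
    excludes when either fails.  Returns (keep, reason).
    """
    low_cov = coverage < min_coverage
    low_len = aligned_length_bp < min_aligned_bp
    exclude = (low_cov and low_len) if mode == "and" else (low_cov or low_len)
    if not exclude:
        reason = None
        if low_cov or low_len:
            reason = "borderline: " + ", ".join(
                ([f"coverage {coverage:.2f} < {min_coverage}"] if low_cov else [])
                + ([f"aligned {aligned_length_bp} bp < {min_aligned_bp}"] if low_len else [])
            )
        return True, reason
    return False, (
        f"coverage {coverage:.2f} < {min_coverage} and aligned "
        f"{aligned_length_bp} bp < {min_aligned_bp}"
    )


def pair_gametologs(
    w_genes: dict[str, str],
    reference_w: dict[str, str],
    reference_z: dict[str, str],
    ref_w_to_z: dict[str, str],
    species_genes: dict[str, str],
    taxon: str,
    z_positions_mb: dict[str, float] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[GametologPair]:
    """Three-step W→Z pairing through the reference species.

    The species' Z ortholog must not itself be one of the W candidates
    (replacing wet-lab verification of Z linkage); W candidates are removed
    from the reciprocal search space.
    """
    z_positions_mb = z_positions_mb or {}
    pairs: list[GametologPair] = []
    species_non_w = {k: v for k, v in species_genes.items() if k not in w_genes}
    for w_id in sorted(w_genes):
        # step 1: reference W ortholog
        hits_w = best_hits({w_id: w_genes[w_id]}, reference_w, evalue_cutoff)[w_id]
        if not hits_w:
            pairs.append(GametologPair(
                locus=w_id, taxon=taxon, w_id=w_id, z_id=None, z_position_mb=None,
                pairing_route="unpaired", reason="no reference W ortholog"))
            continue
        ref_w = hits_w[0].target
        coverage = hits_w[0].target_coverage
        # step 2: reference W -> reference Z
        ref_z = ref_w_to_z.get(ref_w)
        if ref_z is None or ref_z not in reference_z:
            pairs.append(GametologPair(
                locus=ref_w, taxon=taxon, w_id=w_id, z_id=None, z_position_mb=None,
                pairing_route="unpaired", coverage=coverage,
                reason="no reference ortholog"))
            continue
        # step 3: RBH of the reference Z gene in the species, W candidates excluded
        fwd = best_hits({ref_z: reference_z[ref_z]}, species_non_w, evalue_cutoff)[ref_z]
        route, z_id = "unpaired", None
        if fwd:
            cand = fwd[0].target
            back = best_hits({cand: species_non_w[cand]}, reference_z, evalue_cutoff)[cand]
            if back and back[0].target == ref_z:
                route, z_id = "reciprocal-best", cand
            elif len(fwd) > 1:
                route, z_id = "next-best-fallback", fwd[1].target
            else:
                route, z_id = "next-best-fallback", cand
        if z_id is None:
            pairs.append(GametologPair(
                locus=ref_w, taxon=taxon, w_id=w_id, z_id=None, z_position_mb=None,
                pairing_route="unpaired", coverage=coverage,
                reason="no species Z ortholog under cutoff"))
            continue
        aligner = _nt_aligner()
        _, aligned_bp, _ = _align(aligner, w_genes[w_id], species_non_w[z_id])
        pairs.append(GametologPair(
            locus=ref_w, taxon=taxon, w_id=w_id, z_id=z_id,
            z_position_mb=z_positions_mb.get(ref_z),
            pairing_route=route, coverage=coverage, aligned_length_bp=aligned_bp))
    return pairs


def resolve_paralogs(candidates: list[tuple[GametologPair, "object"]]) -> GametologPair | None:
    """Pick the gametolog pair with the lowest dS among candidate W paralogs.

    ``candidates`` holds (pair, DivergenceEstimate-or-None).  Ties break by
    longest aligned length, then lexicographic W id.  Returns None when no
    candidate has an estimable dS.
    """
    scored = [(p, e) for p, e in candidates if e is not None and np.isfinite(e.ds)]
    if not scored:
        return None
    scored.sort(key=lambda pe: (pe[1].ds, -(pe[0].aligned_length_bp or 0), pe[0].w_id))
    return scored[0][0]
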