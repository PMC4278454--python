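"""Codon-level substitution machinery shared by the simulator and estimators.

Implements the Goldman–Yang (GY94) and Muse–Gaut (MG94) parameterisations of
a reversible 61-state codon process with transition/transversion ratio kappa
and nonsynonymous/synonymous rate ratio omega.  All downstream likelihoods
(pairwise divergence, branch models, branch-site models) consume the
eigendecompositions produced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_table.stop_codons))
SENSE_CODONS = tuple(sorted(c for c in _table.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61 under the universal code
CODON_AA = {c: _table.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _single_nt_changes():
    """All ordered sense-codon pairs differing at exactly one position."""
    changes = []
    for ci, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in NUCS:
                if nt == c1[pos]:
                    continue
                c2 = c1[:pos] + nt + c1[pos + 1 :]
                if c2 in CODON_INDEX:
                    changes.append(
                        (
                            ci,
                            CODON_INDEX[c2],
                            pos,
                            nt,
                            is_transition(c1[pos], nt),
                            CODON_AA[c1] == CODON_AA[c2],
                        )
                    )
    return changes

_CHANGES = _single_nt_changes()

# Pre-built index arrays for fast matrix assembly
_CH_I = np.array([c[0] for c in _CHANGES])
_CH_J = np.array([c[1] for c in _CHANGES])
_CH_POS = np.array([c[2] for c in _CHANGES])
_CH_NT = np.array([NUC_INDEX[c[3]] for c in _CHANGES])
_CH_TS = np.array([c[4] for c in _CHANGES], dtype=bool)
_CH_SYN = np.array([c[5] for c in _CHANGES], dtype=bool)


def f3x4_frequencies(codon_columns: Iterable[str]) -> np.ndarray:
    """Codon frequencies under the F3x4 model from observed codons.

    Nucleotide frequencies are tabulated per codon position, multiplied and
    renormalised over sense codons.  A pseudo-count keeps every frequency
    positive even on short alignments.
    """
    counts = np.ones((3, 4))  # pseudo-count
    for codon in codon_columns:
        for pos, nt in enumerate(codon):
            if nt in NUC_INDEX:
                counts[pos, NUC_INDEX[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, NUC_INDEX[c[0]]] * freqs[1, NUC_INDEX[c[1]]] * freqs[2, NUC_INDEX[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


@dataclass
class RateStats:
    """Substitution-flux bookkeeping for converting t into dS and dN."""

    total_rate: float       # expected substitutions per codon per unit t (1 after scaling)
    syn_flux: float         # synonymous fraction of the flux
    nonsyn_flux: float
    syn_sites: float        # synonymous sites per codon (mutation process, omega=1)
    nonsyn_sites: float


class CodonModel:
    """A reversible codon model with cached eigendecompositions.

    Parameters
    ----------
    pi : stationary codon frequencies (length 61).
    style : "gy94" (target-codon frequency) or "mg94" (target-nucleotide
        frequency, position specific).
    """

    def __init__(self, pi: np.ndarray, style: str = "gy94", nuc_freqs: np.ndarray | None = None):
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (N_CODONS,):
            raise ValueError("pi must have one entry per sense codon")
        if np.any(pi <= 0):
            raise ValueError("codon frequencies must be strictly positive")
        self.pi = pi / pi.sum()
        self.style = style
        if style == "mg94":
            if nuc_freqs is None:
                raise ValueError("mg94 requires per-position nucleotide frequencies (3x4)")
            self.nuc_freqs = np.asarray(nuc_freqs, dtype=float)
        else:
            self.nuc_freqs = None
        self._decomp_cache: dict[tuple[float, float], tuple] = {}

    # -- rate matrix ----------------------------------------------------
    def rate_matrix(self, kappa: float, omega: float, scale: bool = True) -> np.ndarray:
        q = np.zeros((N_CODONS, N_CODONS))
        if self.style == "gy94":
            rates = self.pi[_CH_J].copy()
        else:
            rates = self.nuc_freqs[_CH_POS, _CH_NT].copy()
        rates[_CH_TS] *= kappa
        rates[_CH_SYN == False] *= omega  # noqa: E712
        q[_CH_I, _CH_J] = rates
        np.fill_diagonal(q, -q.sum(axis=1))
        if scale:
            mu = -np.dot(self.pi, np.diag(q))
            if mu > 0:
                q /= mu
        return q

    def rate_stats(self, kappa: float, omega: float) -> RateStats:
        q = self.rate_matrix(kappa, omega, scale=True)
        flux = self.pi[_CH_I] * q[_CH_I, _CH_J]
        syn_flux = float(flux[_CH_SYN].sum())
        nonsyn_flux = float(flux[~_CH_SYN].sum())
        q1 = self.rate_matrix(kappa, 1.0, scale=True)
        flux1 = self.pi[_CH_I] * q1[_CH_I, _CH_J]
        rho_s1 = float(flux1[_CH_SYN].sum()) / float(flux1.sum())
        return RateStats(
            total_rate=float(flux.sum()),
            syn_flux=syn_flux,
            nonsyn_flux=nonsyn_flux,
            syn_sites=3.0 * rho_s1,
            nonsyn_sites=3.0 * (1.0 - rho_s1),
        )

    # -- transition probabilities ---------------------------------------
    def decomposition(self, kappa: float, omega: float):
        """Eigendecomposition of the scaled Q, cached on (kappa, omega).

        Uses the similarity transform B = D Q D^-1 with D = diag(sqrt(pi)),
        which is symmetric for a reversible chain, so `eigh` applies.
        """
        key = (float(kappa), float(omega))
        hit = self._decomp_cache.get(key)
        if hit is not None:
            return hit
        q = self.rate_matrix(kappa, omega, scale=True)
        d = np.sqrt(self.pi)
        b = (q * d[:, None]) / d[None, :]
        b = 0.5 * (b + b.T)
        lam, u = np.linalg.eigh(b)
        left = u.T * d[None, :]        # U^T D
        right = (u.T / d[None, :]).T   # D^-1 U
        if len(self._decomp_cache) > 64:
            self._decomp_cache.clear()
        self._decomp_cache[key] = (lam, right, left)
        return lam, right, left

    def transition_matrix(self, kappa: float, omega: float, t: float) -> np.ndarray:
        lam, right, left = self.decomposition(kappa, omega)
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def ds_dn_from_t(self, t: float, kappa: float, omega: float) -> tuple[float, float]:
        """Convert branch length t (substitutions per codon) into dS, dN."""
        st = self.rate_stats(kappa, omega)
        ds = t * st.syn_flux / st.syn_sites if st.syn_sites > 0 else 0.0
        dn = t * st.nonsyn_flux / st.nonsyn_sites if st.nonsyn_sites > 0 else 0.0
        return ds, dn

    def t_for_ds(self, ds: float, kappa: float, omega: float) -> float:
        """Branch length (subs/codon) giving synonymous divergence ds."""
        st = self.rate_stats(kappa, omega)
        return ds * st.syn_sites / st.syn_flux


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """Codon indices; -1 marks gaps/ambiguity/stop codons."""
    out = []
    for codon in codons_of(seq):
        out.append(CODON_INDEX.get(codon, -1))
    return np.array(out, dtype=int)
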