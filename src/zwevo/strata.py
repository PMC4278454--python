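"""Evolutionary strata assignment and molecular-clock dating.

A stratum is a contiguous region of the Z chromosome whose gametologs
stopped recombining together, visible as a cluster of similar Z–W
synonymous divergence (dS) values.  Loci are compared per gene against a
reference species' orthologous gametolog: overlapping 95% confidence
intervals place the locus in the reference stratum, a significantly lower
dS marks lineage-specific (younger) suppression, and a gene-tree call of
"independent" overrides CI evidence.

Dates come from a sex-chromosome molecular clock: the combined Z+W
synonymous substitution rate of 3.8e-9 per site per year, so
T = dS / 3.8e-9 years, reported in millions of years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_CLOCK_RATE = 3.8e-9  # synonymous substitutions / site / year (Z+W)


@dataclass
class ClockConfig:
    rate: float = DEFAULT_CLOCK_RATE
    round_to_my: bool = True

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


def clock_date(ds: float, cfg: ClockConfig | None = None) -> float:
    """Divergence time in millions of years from synonymous divergence.

    Refuses dS > 1 (the saturation gate) and negative dS.
    """
    cfg = cfg or ClockConfig()
    if ds < 0:
        raise ValueError("dS must be non-negative")
    if ds > 1.0:
        raise ValueError(f"dS = {ds:g} > 1: saturated estimate, dating refused")
    t_my = ds / cfg.rate / 1e6
    return float(round(t_my)) if cfg.round_to_my else float(t_my)


@dataclass
class StratumAssignment:
    locus: str
    stratum: str                      # reference stratum label or "lineage-specific"
    basis: str                        # ci-overlap-with-reference | ci-nonoverlap-lower |
                                      # tree-independent | unassignable
    z_position_mb: float | None
    ds: float
    ci95_ds: tuple[float, float]
    conflict: bool = False            # CI overlap but tree says independent
    reason: str | None = None


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def assign_strata(
    pairs: list[dict],
    reference: dict[str, dict],
    tree_calls: dict[str, str] | None = None,
    mode: str = "per-gene",
) -> list[StratumAssignment]:
    """Assign each locus to a stratum by CI comparison.

    ``pairs``: dicts with keys locus, ds, ci95_ds, z_position_mb.
    ``reference``: locus -> dict(ds, ci95_ds, stratum) for the orthologous
    reference-species gametolog.
    ``tree_calls``: optional locus -> shared/independent/unresolved; a
    high-support "independent" call overrides CI overlap (the tree
    evidence outranks divergence similarity), with the conflict flagged.
    ``mode``: "per-gene" (default) compares against the orthologous
    reference locus; "pooled" compares against the pooled CI envelope of
    the reference stratum the ortholog belongs to.
    """
    tree_calls = tree_calls or {}
    if mode not in ("per-gene", "pooled"):
        raise ValueError("mode must be 'per-gene' or 'pooled'")
    if mode == "pooled":
        envelope: dict[str, list[float]] = {}
        for ref in reference.values():
            lo, hi = ref["ci95_ds"]
            env = envelope.setdefault(ref["stratum"], [lo, hi])
            env[0], env[1] = min(env[0], lo), max(env[1], hi)
        reference = {
            locus: dict(ds=ref["ds"], stratum=ref["stratum"],
                        ci95_ds=tuple(envelope[ref["stratum"]]))
            for locus, ref in reference.items()
        }
    out = []
    for p in pairs:
        locus = p["locus"]
        z = p.get("z_position_mb")
        if z is None:
            out.append(StratumAssignment(
                locus=locus, stratum="unassigned", basis="unassignable",
                z_position_mb=None, ds=p["ds"], ci95_ds=p["ci95_ds"],
                reason="no Z position"))
            continue
        ref = reference.get(locus)
        if ref is None:
            out.append(StratumAssignment(
                locus=locus, stratum="unassigned", basis="unassignable",
                z_position_mb=z, ds=p["ds"], ci95_ds=p["ci95_ds"],
                reason="no reference ortholog"))
            continue
        call = tree_calls.get(locus, "unresolved")
        overlap = _intervals_overlap(tuple(p["ci95_ds"]), tuple(ref["ci95_ds"]))
        if call == "independent":
            out.append(StratumAssignment(
                locus=locus, stratum="lineage-specific", basis="tree-independent",
                z_position_mb=z, ds=p["ds"], ci95_ds=p["ci95_ds"],
                conflict=overlap))
        elif overlap:
            out.append(StratumAssignment(
                locus=locus, stratum=ref["stratum"], basis="ci-overlap-with-reference",
                z_position_mb=z, ds=p["ds"], ci95_ds=p["ci95_ds"]))
        elif p["ds"] < ref["ds"]:
            out.append(StratumAssignment(
                locus=locus, stratum="lineage-specific", basis="ci-nonoverlap-lower",
                z_position_mb=z, ds=p["ds"], ci95_ds=p["ci95_ds"]))
        else:
            out.append(StratumAssignment(
                locus=locus, stratum="unassigned", basis="unassignable",
                z_position_mb=z, ds=p["ds"], ci95_ds=p["ci95_ds"],
                reason="dS above reference with disjoint CI"))
    return out


def summarize_strata(
    assignments: list[StratumAssignment],
    clock: ClockConfig | None = None,
) -> pd.DataFrame:
    """Per-stratum table: Z interval (Mb), dS range and clock-dated range.

    Saturated members (dS > 1) are excluded from the date columns.
    """
    clock = clock or ClockConfig()
    rows = []
    strata: dict[str, list[StratumAssignment]] = {}
    for a in assignments:
        if a.basis == "unassignable":
            continue
        strata.setdefault(a.stratum, []).append(a)
    for label, members in strata.items():
        ds_vals = [m.ds for m in members]
        datable = [d for d in ds_vals if d <= 1.0]
        rows.append(dict(
            stratum=label,
            n_loci=len(members),
            z_start_mb=min(m.z_position_mb for m in members),
            z_end_mb=max(m.z_position_mb for m in members),
            ds_min=min(ds_vals),
            ds_max=max(ds_vals),
            date_min_my=clock_date(min(datable), clock) if datable else float("nan"),
            date_max_my=clock_date(max(datable), clock) if datable else float("nan"),
        ))
    df = pd.DataFrame(rows, columns=["stratum", "n_loci", "z_start_mb", "z_end_mb",
                                     "ds_min", "ds_max", "date_min_my", "date_max_my"])
    return df.sort_values("z_start_mb", ignore_index=True) if len(df) else df
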