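"""Expression-based W-linkage classification and Z/W distinctness checks.

W-linked genes are carried only by females (ZW), so in sexed expression
data they are female-limited; recently formed gametologs that still
cross-map can instead appear strongly female-biased.  Both patterns flag
putative W linkage.  For nearly identical gametolog pairs (dS < 0.02) the
Z and W annotations are verified to be distinct sequences using fixed Z/W
differences or female-limited SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import CodonAlignment

VERIFY_DS_THRESHOLD = 0.02   # pairs below this dS require SNP/fixed-difference support


@dataclass
class WCandidate:
    gene: str
    klass: str                 # female-limited | strongly-female-biased | not-candidate
    mean_female: float
    mean_male: float
    bias_ratio: float | None


def classify_w_candidates(
    expr: pd.DataFrame,
    sex: dict[str, str] | None = None,
    min_female_expr: float = 1.0,
    max_male_expr: float = 0.0,
    min_bias_ratio: float = 10.0,
) -> list[WCandidate]:
    """Classify genes from a genes x samples abundance matrix.

    female-limited: every male sample <= ``max_male_expr`` (values rounded
    to 2 decimals first) and mean female expression >= ``min_female_expr``.
    strongly-female-biased: female/male mean ratio >= ``min_bias_ratio``
    with nonzero male mean.  Sample sexes come from ``sex`` or from the
    matrix's ``attrs['sex']``.
    """
    sex = sex or expr.attrs.get("sex")
    if sex is None:
        raise ValueError("no sample sex labels provided")
    males = [s for s in expr.columns if sex[s] == "M"]
    females = [s for s in expr.columns if sex[s] == "F"]
    if not males or not females:
        raise ValueError("need at least one sample of each sex")
    if (expr.values < 0).any():
        raise ValueError("negative abundance values")
    out = []
    for gene, row in expr.iterrows():
        male_vals = np.round(row[males].to_numpy(dtype=float), 2)
        mean_f = float(row[females].mean())
        mean_m = float(row[males].mean())
        ratio = (mean_f / mean_m) if mean_m > 0 else None
        if (male_vals <= max_male_expr).all() and mean_f >= min_female_expr:
            klass = "female-limited"
        elif ratio is not None and ratio >= min_bias_ratio:
            klass = "strongly-female-biased"
        else:
            klass = "not-candidate"
        out.append(WCandidate(gene, klass, mean_f, mean_m, ratio))
    return out


def verify_distinct_gametologs(
    aln: CodonAlignment,
    snp_table: pd.DataFrame | None = None,
    z_label: str | None = None,
    w_label: str | None = None,
    gene: str | None = None,
    taxon: str | None = None,
) -> tuple[bool, str]:
    """Check that annotated Z and W sequences are genuinely distinct.

    Verified when the pair shows at least one fixed difference, or when a
    female-limited SNP (no male carriers) attests a W-specific allele.
    Returns (verified, evidence).
    """
    if z_label is None or w_label is None:
        if len(aln.records) != 2:
            raise ValueError("specify z_label and w_label")
        z_label, w_label = aln.labels
    z, w = aln[z_label], aln[w_label]
    fixed = sum(1 for a, b in zip(z, w) if a != b and a != "-" and b != "-")
    if fixed >= 1:
        return True, f"{fixed} fixed Z/W difference(s)"
    if snp_table is not None and len(snp_table):
        sub = snp_table
        if gene is not None:
            sub = sub[sub["gene"] == gene]
        if taxon is not None and "taxon" in sub.columns:
            sub = sub[sub["taxon"] == taxon]
        for r in sub.itertuples():
            if r.male_carriers == 0 and r.female_carriers > 0:
                pos = int(r.position)
                if 0 <= pos < len(z) and z[pos] == r.z_allele and r.w_allele != r.z_allele:
                    return True, f"female-limited SNP at {pos} ({r.z_allele}->{r.w_allele})"
    return False, "no fixed difference or female-limited SNP"
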