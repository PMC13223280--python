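"""Benchmarking functional calls against clinical and functional standards.

Sensitivity/specificity of a model's seven-level categories against ClinVar
P/LP vs B/LB labels or homology-directed-repair (HDR) assay
abnormal/normal labels, under two definitions:

* ``conservative`` — sensitivity counts only ``P_Strong`` calls as detected
  pathogenic; specificity counts ``B_Strong`` or ``B_Moderate`` as detected
  benign (the high-confidence categories).
* ``all_categories`` — any pathogenic-side call vs any benign-side call.

A "discrepant" variant is one whose call sits on the opposite side of its
standard; Uncertain calls dilute sensitivity/specificity (they stay in the
denominator) but are not conflicts.

Also provides the pooled 2x2 carrier-burden association test (Fisher's
exact test with a Wald CI on the log odds ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .categories import category_side

TRUTH_COLUMNS = {"clinvar": "clinvar_standard", "hdr": "hdr_standard"}
POSITIVE_LABELS = {"clinvar": "P/LP", "hdr": "abnormal"}
NEGATIVE_LABELS = {"clinvar": "B/LB", "hdr": "normal"}


@dataclass
class PerformanceReport:
    truth_source: str
    definition: str
    n_standards_evaluated: int
    n_pathogenic_standards: int
    n_benign_standards: int
    sensitivity: float | None
    specificity: float | None
    discrepant_variants: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "truth_source": self.truth_source,
            "definition": self.definition,
            "n_standards_evaluated": self.n_standards_evaluated,
            "n_pathogenic_standards": self.n_pathogenic_standards,
            "n_benign_standards": self.n_benign_standards,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "discrepant_variants": list(self.discrepant_variants),
        }


def evaluate(calls: pd.DataFrame, standards: pd.DataFrame,
             truth_source: str = "clinvar",
             definition: str = "conservative") -> PerformanceReport:
    """Score a call table against one standards source.

    Parameters
    ----------
    calls : DataFrame with variant_id and category.
    standards : DataFrame with variant_id and the truth column for
        ``truth_source`` (the variants table qualifies).
    truth_source : {"clinvar", "hdr"}
    definition : {"conservative", "all_categories"}
    """
    if truth_source not in TRUTH_COLUMNS:
        raise ValueError(f"truth_source must be one of {set(TRUTH_COLUMNS)}")
    if definition not in ("conservative", "all_categories"):
        raise ValueError("definition must be 'conservative' or "
                         "'all_categories'")
    col = TRUTH_COLUMNS[truth_source]
    merged = calls[["variant_id", "category"]].merge(
        standards[["variant_id", col]], on="variant_id")
    merged = merged[merged[col].isin(
        [POSITIVE_LABELS[truth_source], NEGATIVE_LABELS[truth_source]])]
    is_path = merged[col] == POSITIVE_LABELS[truth_source]
    side = pd.Series(category_side(merged["category"].to_numpy()),
                     index=merged.index)

    if definition == "conservative":
        detected_path = merged["category"] == "P_Strong"
        detected_ben = merged["category"].isin(["B_Strong", "B_Moderate"])
    else:
        detected_path = side == "P"
        detected_ben = side == "B"

    n_path = int(is_path.sum())
    n_ben = int((~is_path).sum())
    sens = float(detected_path[is_path].mean()) if n_path else None
    spec = float(detected_ben[~is_path].mean()) if n_ben else None

    opposite = (is_path & (side == "B")) | (~is_path & (side == "P"))
    discrepant = merged.loc[opposite, "variant_id"].tolist()
    return PerformanceReport(
        truth_source=truth_source,
        definition=definition,
        n_standards_evaluated=len(merged),
        n_pathogenic_standards=n_path,
        n_benign_standards=n_ben,
        sensitivity=sens,
        specificity=spec,
        discrepant_variants=discrepant,
    )


def pooled_burden_or(a: int, b: int, c: int, d: int) -> dict:
    """Pooled 2x2 carrier-burden test.

    Table layout: a = case carriers, b = case non-carriers, c = control
    carriers, d = control non-carriers. Returns the sample odds ratio
    (Haldane +0.5 continuity correction when any cell is zero), the
    two-sided Fisher exact p-value, and a 95% Wald CI on the log odds
    ratio. If any row or column of the table is entirely zero the odds
    ratio is undefined and reported as None.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.floor(cells)):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = cells
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return {"odds_ratio": None, "p_value": p, "ci95": None,
                "continuity_corrected": False}
    corrected = bool(np.any(cells == 0))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return {
        "odds_ratio": float(or_),
        "p_value": p,
        "ci95": (float(lo), float(hi)),
        "continuity_corrected": corrected,
    }
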