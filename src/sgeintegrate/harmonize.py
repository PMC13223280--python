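"""Cross-assay harmonization of raw functional scores.

The two source screens report depletion-type scores on different scales.
Before the integrated models can pool replicates, the second assay is mapped
onto the first assay's scale by the affine transform that sends the second
assay's synonymous-control and nonsense-control medians onto the first
assay's. Medians are used because the residual noise is heavy-tailed.
Replicate-level differences are deliberately left in place: absorbing them
is the job of the model's replicate-by-exon random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

_CONTROL_CLASSES = ("synonymous", "nonsense")


@dataclass
class HarmonizedDataset:
    """Observations with a ``rescaled_score`` column plus the anchors used."""

    observations: pd.DataFrame
    anchors: dict


class AssayHarmonizer(BaseEstimator, TransformerMixin):
    """Rescale one assay's scores onto a reference assay's scale.

    Learns, from control-variant medians, the affine map sending the source
    assay's {synonymous median, nonsense median} onto the reference assay's.
    Reference-assay scores pass through unchanged.

    Parameters
    ----------
    source_assay, reference_assay : str
        Assay labels in the ``assay`` column of the score table.
    min_controls : int
        Minimum number of distinct control variants of each class required
        per assay (default 5).

    Attributes
    ----------
    slope_, intercept_ : float
        The fitted affine map (slope is required to be positive so rank
        order within the source assay is preserved).
    anchors_ : dict
        Per-assay control medians before and after rescaling.
    """

    def __init__(self, source_assay: str = "A2", reference_assay: str = "A1",
                 min_controls: int = 5):
        self.source_assay = source_assay
        self.reference_assay = reference_assay
        self.min_controls = min_controls

    def _control_medians(self, scores, variants, assay):
        merged = scores[scores["assay"] == assay].merge(
            variants[["variant_id", "consequence"]], on="variant_id"
        )
        medians = {}
        for cls in _CONTROL_CLASSES:
            sub = merged[merged["consequence"] == cls]
            n_ctrl = sub["variant_id"].nunique()
            if n_ctrl < self.min_controls:
                raise ValueError(
                    f"assay {assay!r} has {n_ctrl} {cls} control variants "
                    f"with observations; >= {self.min_controls} required"
                )
            medians[cls] = float(sub["raw_score"].median())
        return medians

    def fit(self, scores: pd.DataFrame, variants: pd.DataFrame):
        ref = self._control_medians(scores, variants, self.reference_assay)
        src = self._control_medians(scores, variants, self.source_assay)
        src_span = src["synonymous"] - src["nonsense"]
        ref_span = ref["synonymous"] - ref["nonsense"]
        if src_span == 0 or ref_span == 0:
            raise ValueError("degenerate anchors: synonymous and nonsense "
                             "medians coincide")
        slope = ref_span / src_span
        if slope <= 0:
            raise ValueError(
                "anchor medians imply a non-positive slope; the source assay "
                "scores run in the opposite direction to the reference"
            )
        self.slope_ = slope
        self.intercept_ = ref["synonymous"] - slope * src["synonymous"]
        self.anchors_ = {self.reference_assay: ref, self.source_assay: src}
        return self

    def transform(self, scores: pd.DataFrame) -> pd.DataFrame:
        out = scores.copy()
        is_src = out["assay"] == self.source_assay
        out["rescaled_score"] = np.where(
            is_src,
            self.intercept_ + self.slope_ * out["raw_score"],
            out["raw_score"],
        )
        return out


def rescale_assay(
    scores: pd.DataFrame,
    variants: pd.DataFrame,
    source_assay: str = "A2",
    reference_assay: str = "A1",
) -> HarmonizedDataset:
    """Functional wrapper around :class:`AssayHarmonizer`."""
    h = AssayHarmonizer(source_assay, reference_assay).fit(scores, variants)
    obs = h.transform(scores)
    rescaled = {}
    for assay, med in h.anchors_.items():
        if assay == source_assay:
            rescaled[assay] = {
                cls: h.intercept_ + h.slope_ * m for cls, m in med.items()
            }
        else:
            rescaled[assay] = dict(med)
    anchors = {
        "raw": h.anchors_,
        "rescaled": rescaled,
        "slope": h.slope_,
        "intercept": h.intercept_,
        "source_assay": source_assay,
        "reference_assay": reference_assay,
    }
    return HarmonizedDataset(observations=obs, anchors=anchors)


def merge_replicates(harmonized: HarmonizedDataset) -> pd.DataFrame:
    """One row per (variant, assay, replicate) observation, across assays.

    Variants observed in only one assay are flagged (``single_assay``), not
    dropped; a ``--common-only`` style filter is the caller's choice.
    """
    obs = harmonized.observations.copy()
    n_assays = obs.groupby("variant_id")["assay"].nunique()
    obs["single_assay"] = obs["variant_id"].map(n_assays == 1)
    return obs.sort_values(
        ["variant_id", "assay", "replicate"], kind="stable"
    ).reset_index(drop=True)
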