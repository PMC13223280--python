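"""Concordance between two sets of seven-level functional categories.

Two uses: the primary concordance model (between the two source screens'
published categories) and the secondary concordance model (between the two
integrated models). Concordance is judged at the side level — any
pathogenic strength counts as P, any benign strength as B, Uncertain as
VUS — matching how discordant variants are excluded from functional-weight
assignment. Exact seven-level category agreement is reported separately.
"""

from __future__ import annotations

import logging

import pandas as pd

from .categories import CATEGORIES, category_side

logger = logging.getLogger(__name__)


def _pairs_frame(pairs: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "category_a", "category_b"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns {sorted(missing)}")
    ok = pairs["category_a"].notna() & pairs["category_b"].notna()
    dropped = pairs.loc[~ok, "variant_id"]
    if len(dropped):
        logger.info("excluding %d variants with a missing category",
                    len(dropped))
    out = pairs.loc[ok].copy()
    out["side_a"] = category_side(out["category_a"].to_numpy())
    out["side_b"] = category_side(out["category_b"].to_numpy())
    return out


def make_pairs(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two call tables into a category-pair table."""
    a = calls_a[["variant_id", "category"]].rename(
        columns={"category": "category_a"})
    b = calls_b[["variant_id", "category"]].rename(
        columns={"category": "category_b"})
    return a.merge(b, on="variant_id", how="inner")


def concordant_set(pairs: pd.DataFrame):
    """Split paired categories into concordant and discordant variants.

    Returns
    -------
    concordant : DataFrame with a ``consensus_side`` column (P, B or VUS).
    discordant : DataFrame carrying both categories for reporting.
    counts : dict with per-side concordant counts and totals.
    """
    df = _pairs_frame(pairs)
    agree = df["side_a"] == df["side_b"]
    concordant = df.loc[agree].copy()
    concordant["consensus_side"] = concordant["side_a"]
    discordant = df.loc[~agree].copy()
    counts = {
        "n_input": int(len(df)),
        "n_concordant": int(len(concordant)),
        "n_discordant": int(len(discordant)),
        "by_side": {
            side: int((concordant["consensus_side"] == side).sum())
            for side in ("P", "B", "VUS")
        },
    }
    return concordant, discordant, counts


def category_agreement(pairs: pd.DataFrame):
    """Exact seven-level agreement fraction and the 7x7 confusion matrix."""
    df = _pairs_frame(pairs)
    if len(df) == 0:
        return float("nan"), pd.DataFrame(
            0, index=list(CATEGORIES), columns=list(CATEGORIES))
    frac = float((df["category_a"] == df["category_b"]).mean())
    confusion = (
        pd.crosstab(df["category_a"], df["category_b"])
        .reindex(index=list(CATEGORIES), columns=list(CATEGORIES),
                 fill_value=0)
    )
    return frac, confusion
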