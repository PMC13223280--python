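"""Seven-level functional evidence categories and OddsPath strength thresholds.

Both integrated models (the Bayesian hierarchical VarCall fit and the
two-component Gaussian mixture) express the strength of functional evidence
as an odds of pathogenicity (a Bayes factor / likelihood ratio) and compare
it against powers of a canonical odds constant, following the Bayesian
reading of the ACMG/AMP evidence strengths: strong evidence corresponds to
``C**(1/2)``, moderate to ``C**(1/4)`` and supporting to ``C**(1/8)`` with
``C = 350`` by default; benign strengths use the reciprocals.
"""

from __future__ import annotations

import numpy as np

# Ordered from most benign to most pathogenic.
CATEGORIES = (
    "B_Strong",
    "B_Moderate",
    "B_Supporting",
    "Uncertain",
    "P_Supporting",
    "P_Moderate",
    "P_Strong",
)

PATHOGENIC_CATEGORIES = frozenset({"P_Strong", "P_Moderate", "P_Supporting"})
BENIGN_CATEGORIES = frozenset({"B_Strong", "B_Moderate", "B_Supporting"})

#: Canonical odds-of-pathogenicity constant whose fractional powers set the
#: strength thresholds. A configuration default, not a fitted quantity.
ODDS_PATH_CONSTANT = 350.0


def strength_thresholds(constant: float = ODDS_PATH_CONSTANT) -> dict[str, float]:
    """Pathogenic-side thresholds; benign side uses their reciprocals."""
    return {
        "strong": constant ** 0.5,
        "moderate": constant ** 0.25,
        "supporting": constant ** 0.125,
    }


def categorize_bf(bf, constant: float = ODDS_PATH_CONSTANT):
    """Map a Bayes factor (odds of pathogenicity) to a seven-level category.

    Parameters
    ----------
    bf : float or array-like of float
        Positive odds of pathogenicity. Values ``>= constant**(1/2)`` are
        ``P_Strong``, ``>= constant**(1/4)`` ``P_Moderate``, ``>= constant**(1/8)``
        ``P_Supporting``; the benign side is symmetric with ``<=`` on the
        reciprocal thresholds; everything between is ``Uncertain``.

    Returns
    -------
    str or ndarray of str
        Scalar in, scalar out.
    """
    arr = np.asarray(bf, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("Bayes factors must be positive and finite")
    th = strength_thresholds(constant)
    out = np.full(arr.shape, "Uncertain", dtype=object)
    out[arr >= th["supporting"]] = "P_Supporting"
    out[arr >= th["moderate"]] = "P_Moderate"
    out[arr >= th["strong"]] = "P_Strong"
    out[arr <= 1.0 / th["supporting"]] = "B_Supporting"
    out[arr <= 1.0 / th["moderate"]] = "B_Moderate"
    out[arr <= 1.0 / th["strong"]] = "B_Strong"
    if np.isscalar(bf) or arr.ndim == 0:
        return str(out.item() if arr.ndim == 0 else out[0])
    return out.astype(str)


def category_side(category) -> str | np.ndarray:
    """Collapse a seven-level category to its side: ``P``, ``B`` or ``VUS``."""

    def one(c: str) -> str:
        if c in PATHOGENIC_CATEGORIES:
            return "P"
        if c in BENIGN_CATEGORIES:
            return "B"
        if c == "Uncertain":
            return "VUS"
        raise ValueError(f"unknown category: {c!r}")

    if isinstance(category, str):
        return one(category)
    return np.asarray([one(c) for c in category], dtype=object).astype(str)


def posterior_to_bf(pp, prior: float):
    """Convert a posterior probability of pathogenicity to a Bayes factor.

    BF = posterior odds / prior odds. ``pp`` must lie in [0, 1] (callers are
    responsible for clamping degenerate 0/1 posteriors first); the prior must
    lie strictly inside (0, 1).
    """
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    arr = np.asarray(pp, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    prior_odds = prior / (1.0 - prior)
    with np.errstate(divide="ignore"):
        post_odds = arr / (1.0 - arr)
    bf = post_odds / prior_odds
    if np.isscalar(pp) or arr.ndim == 0:
        return float(bf)
    return bf
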