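"""Integrated GMM model.

Per-variant functional scores (the mean of all harmonized replicate scores
across both assays) are fit with a two-component Gaussian mixture by EM.
Component identity is calibrated on controls: the component carrying the
higher mean responsibility among nonsense variants is the non-functional
one, synonymous variants anchoring the functional side. The probability of
impact on function (PIF) combines the component likelihood ratio with a
prior probability of pathogenicity (default 0.2); the likelihood ratio is
the odds of pathogenicity compared against the same seven-level OddsPath
strength thresholds used by the VarCall model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .categories import ODDS_PATH_CONSTANT, categorize_bf
from .varcall import _as_observations

__all__ = ["FunctionalGMM", "fit_gmm", "pif_and_categorize"]

_VAR_FLOOR = 1e-6
_LOGLR_CAP = 700.0


def _em_once(x, mu0, mu1, var0, var1, w1, max_iter, tol):
    """Run EM from one start; returns params + log-likelihood trace.

    Component 1 is whichever the caller seeds lower; labels are assigned
    later from control responsibilities, not from the fitted order.
    """
    n = x.size
    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        log_p0 = np.log1p(-w1) + norm.logpdf(x, mu0, np.sqrt(var0))
        log_p1 = np.log(w1) + norm.logpdf(x, mu1, np.sqrt(var1))
        m = np.maximum(log_p0, log_p1)
        ll = float(np.sum(m + np.log(np.exp(log_p0 - m) + np.exp(log_p1 - m))))
        trace.append(ll)
        r1 = 1.0 / (1.0 + np.exp(np.clip(log_p0 - log_p1, -700, 700)))
        n1 = r1.sum()
        if n1 < 1e-12 or n - n1 < 1e-12:
            break
        w1 = n1 / n
        mu1 = float((r1 * x).sum() / n1)
        mu0 = float(((1 - r1) * x).sum() / (n - n1))
        var1 = max(float((r1 * (x - mu1) ** 2).sum() / n1), _VAR_FLOOR)
        var0 = max(float(((1 - r1) * (x - mu0) ** 2).sum() / (n - n1)),
                   _VAR_FLOOR)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return dict(mu0=mu0, mu1=mu1, var0=var0, var1=var1, w1=w1,
                loglik=trace[-1], trace=trace)


class FunctionalGMM(BaseEstimator):
    """Two-component Gaussian mixture over per-variant summary scores.

    Parameters
    ----------
    prior_pathogenic : float
        Prior used in the PIF posterior; it does not constrain the fitted
        mixture weight.
    combiner : {"mean", "median"}
        Replicate combiner producing the per-variant summary score.
    n_restarts, max_iter, tol : EM controls; the best-log-likelihood
        restart is kept and the log-likelihood trace is asserted
        non-decreasing.
    seed : int; odds_constant : float.

    Attributes (after ``fit``)
    --------------------------
    m_f_, m_n_, s_f_, s_n_, w_n_ : fitted component parameters, labeled so
        the non-functional component is the one nonsense controls load on.
    summary_scores_ : Series of per-variant scores used.
    loglik_trace_ : list of float, from the winning restart.
    calls_ : DataFrame with variant_id, pp (PIF), bf (likelihood ratio),
        category, model_tag.
    """

    def __init__(self, prior_pathogenic: float = 0.2, combiner: str = "mean",
                 n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-8,
                 seed: int = 0, odds_constant: float = ODDS_PATH_CONSTANT):
        self.prior_pathogenic = prior_pathogenic
        self.combiner = combiner
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.odds_constant = odds_constant

    def fit(self, harmonized, variants: pd.DataFrame):
        if not 0.0 < self.prior_pathogenic < 1.0:
            raise ValueError("prior_pathogenic must be in (0, 1)")
        if self.combiner not in ("mean", "median"):
            raise ValueError("combiner must be 'mean' or 'median'")
        obs = _as_observations(harmonized)
        summary = (obs.groupby("variant_id")["rescaled_score"]
                   .agg(self.combiner).sort_index())
        x = summary.to_numpy(float)
        if x.size < 2 or np.ptp(x) < 1e-12:
            raise ValueError("summary scores are degenerate (constant); "
                             "a two-component mixture cannot be fit")

        rng = np.random.default_rng(self.seed)
        best = None
        for k in range(self.n_restarts):
            if k == 0:  # quantile start: stable for well-separated data
                mu0, mu1 = np.quantile(x, [0.75, 0.1])
            else:
                mu0, mu1 = rng.choice(x, size=2, replace=False)
            v = max(float(np.var(x)) / 4.0, _VAR_FLOOR)
            fitk = _em_once(x, float(mu0), float(mu1), v, v, 0.3,
                            self.max_iter, self.tol)
            if not np.isfinite(fitk["loglik"]):
                continue
            if best is None or fitk["loglik"] > best["loglik"]:
                best = fitk
        if best is None:
            raise RuntimeError("every EM restart degenerated")
        diffs = np.diff(best["trace"])
        if np.any(diffs < -1e-6):
            raise RuntimeError("EM log-likelihood decreased; fit invalid")

        # Label components by nonsense-control responsibility.
        cons = variants.set_index("variant_id")["consequence"]
        cons = cons.reindex(summary.index)
        nonsense = (cons == "nonsense").to_numpy()
        if not nonsense.any():
            raise ValueError("no nonsense controls; components cannot be "
                             "labeled")
        r1 = self._resp1(x, best)
        if r1[nonsense].mean() >= 0.5:
            nf, fn = ("1", "0")
        else:
            nf, fn = ("0", "1")
        self.m_n_ = best[f"mu{nf}"]
        self.s_n_ = float(np.sqrt(best[f"var{nf}"]))
        self.m_f_ = best[f"mu{fn}"]
        self.s_f_ = float(np.sqrt(best[f"var{fn}"]))
        self.w_n_ = best["w1"] if nf == "1" else 1.0 - best["w1"]
        self.loglik_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        self.summary_scores_ = summary
        self.variant_ids_ = summary.index.to_numpy()

        pif, lr = self._pif(x)
        self.pif_ = pif
        self.lr_ = lr
        self.category_ = categorize_bf(lr, self.odds_constant)
        self.calls_ = pd.DataFrame({
            "variant_id": self.variant_ids_,
            "pp": pif,
            "bf": lr,
            "category": self.category_,
            "model_tag": "gmm",
        })
        return self

    @staticmethod
    def _resp1(x, params):
        log_p0 = (np.log1p(-params["w1"])
                  + norm.logpdf(x, params["mu0"], np.sqrt(params["var0"])))
        log_p1 = (np.log(params["w1"])
                  + norm.logpdf(x, params["mu1"], np.sqrt(params["var1"])))
        return 1.0 / (1.0 + np.exp(np.clip(log_p0 - log_p1, -700, 700)))

    def _pif(self, x):
        """Likelihood ratio f_N/f_F of the component densities and PIF."""
        log_lr = (norm.logpdf(x, self.m_n_, self.s_n_)
                  - norm.logpdf(x, self.m_f_, self.s_f_))
        lr = np.exp(np.clip(log_lr, -_LOGLR_CAP, _LOGLR_CAP))
        pi = self.prior_pathogenic
        pif = lr * pi / (lr * pi + (1.0 - pi))
        return pif, lr

    def predict_proba(self, scores=None) -> np.ndarray:
        """PIF for the fitted variants, or for new summary scores."""
        self._check_fitted()
        if scores is None:
            return self.pif_.copy()
        pif, _ = self._pif(np.asarray(scores, float))
        return pif

    def predict(self, scores=None) -> np.ndarray:
        self._check_fitted()
        if scores is None:
            return self.category_.copy()
        _, lr = self._pif(np.asarray(scores, float))
        return categorize_bf(lr, self.odds_constant)

    def _check_fitted(self):
        if not hasattr(self, "calls_"):
            raise AttributeError("model is not fitted; call fit() first")


def fit_gmm(harmonized, variants: pd.DataFrame, seed: int = 0,
            **params) -> FunctionalGMM:
    """Fit the mixture; keyword arguments mirror the constructor."""
    return FunctionalGMM(seed=seed, **params).fit(harmonized, variants)


def pif_and_categorize(fit: FunctionalGMM, prior: float | None = None
                       ) -> pd.DataFrame:
    """PIF, likelihood ratio and category table from a converged fit.

    ``prior`` overrides the fit's prior in the PIF posterior only; the
    likelihood ratio (and hence the category) is prior-free.
    """
    fit._check_fitted()
    pi = fit.prior_pathogenic if prior is None else prior
    if not 0.0 < pi < 1.0:
        raise ValueError("prior must be in (0, 1)")
    lr = fit.lr_
    pif = lr * pi / (lr * pi + (1.0 - pi))
    return pd.DataFrame({
        "variant_id": fit.variant_ids_,
        "pif": pif,
        "likelihood_ratio": lr,
        "odds_path": lr,
        "category": fit.category_,
        "model_tag": "gmm",
    })
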