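"""Metropolis-within-Gibbs sampler for the hierarchical variant-effect model.

Model, for observation i on variant v(i) in batch m(i) (a replicate-by-exon
cell within one assay), with harmonized score y_i:

    y_i   = b_{m(i)} + exp(g_{m(i)}) * theta_{v(i)} + tau * t_nu
    theta_v | z_v = 0  ~  Normal(mu_f, sigma_f^2)      (functional)
    theta_v | z_v = 1  ~  Normal(mu_n, sigma_n^2)      (non-functional)
    z_v ~ Bernoulli(pi), fixed to 0/1 for control variants
    b_m ~ Normal(0, sigma_b^2),  g_m ~ Normal(0, sigma_g^2)

The t error is handled through its Gamma scale-mixture representation
(per-observation precision multipliers lambda_i ~ Gamma(nu/2, nu/2)), which
makes every update except g_m and nu conjugate. g_m and nu get random-walk
Metropolis steps. The component means are kept ordered (mu_n < mu_f) by
truncated-normal updates, preventing label switching.

Priors: Normal on the component means centred on the control medians with a
wide scale; Inverse-Gamma(2, .) on all variances (conditionally conjugate);
Gamma(2, 0.1) truncated to nu > 2 on the t degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

_VAR_FLOOR = 1e-12


def _t_loglik(r: np.ndarray, tau2: float, nu: float) -> float:
    """Sum of log t_nu(0, tau) densities at residuals r (lam collapsed)."""
    n = r.size
    const = (gammaln(0.5 * (nu + 1.0)) - gammaln(0.5 * nu)
             - 0.5 * np.log(nu * np.pi * tau2))
    return float(n * const
                 - 0.5 * (nu + 1.0) * np.log1p(r * r / (nu * tau2)).sum())


def _trunc_norm(rng, mean, sd, lower=-np.inf, upper=np.inf):
    """One draw from Normal(mean, sd^2) truncated to (lower, upper)."""
    a = ndtr((lower - mean) / sd) if np.isfinite(lower) else 0.0
    b = ndtr((upper - mean) / sd) if np.isfinite(upper) else 1.0
    if b - a < 1e-12:  # numerically degenerate window; clamp to nearest bound
        return float(np.clip(mean, lower + 1e-9, upper - 1e-9))
    u = rng.uniform(a, b)
    return float(mean + sd * ndtri(u))


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def gibbs_varcall(
    y: np.ndarray,
    v_idx: np.ndarray,
    m_idx: np.ndarray,
    z_fixed: np.ndarray,
    prior_pi: float,
    *,
    m0_f: float,
    m0_n: float,
    n_chains: int = 2,
    n_warmup: int = 500,
    n_samples: int = 1000,
    thin: int = 1,
    seed: int = 0,
    use_batch: bool = True,
    fix: dict | None = None,
) -> dict:
    """Run the sampler and return pooled posterior summaries plus chains.

    Parameters
    ----------
    y, v_idx, m_idx : arrays of length N
        Harmonized scores with variant and batch integer indices.
    z_fixed : int array of length V
        -1 for free variants, 0/1 to pin the pathogenicity indicator
        (synonymous controls 0, nonsense controls 1).
    prior_pi : float
        Prior probability of pathogenicity for free variants.
    m0_f, m0_n : float
        Prior centres for the component means (control medians).
    use_batch : bool
        If False the batch effects are clamped at zero (oracle mode).
    fix : dict, optional
        Hold any of ``mu_f, mu_n, sigma_f, sigma_n, tau, nu`` fixed at the
        given value instead of sampling it.

    Returns
    -------
    dict with keys ``pp`` (posterior P(z=1) per variant), ``theta_mean``,
    ``theta_sd``, ``hyper`` (dict of per-chain hyperparameter draw arrays,
    shape (chains, samples)), ``pp_chain`` (chains, V), ``n_draws``.
    """
    fix = dict(fix or {})
    y = np.asarray(y, float)
    v_idx = np.asarray(v_idx)
    m_idx = np.asarray(m_idx)
    n_obs = y.size
    n_var = int(v_idx.max()) + 1
    n_batch = int(m_idx.max()) + 1 if use_batch else 1
    free = z_fixed < 0
    data_var = max(float(np.var(y)), _VAR_FLOOR)

    # Prior hyperparameters (weakly informative, scale-aware).
    s0_mu2 = 25.0 * data_var              # component-mean prior variance
    a_sig, b_sig = 2.0, 0.25 * data_var   # component variances
    a_tau, b_tau = 2.0, 0.05 * data_var   # residual variance
    # Batch-effect variances get a small prior scale so they shrink to
    # zero when the data carry no batch structure.
    a_bat, b_bat = 2.0, 1e-4
    nu_shape, nu_rate = 2.0, 0.1

    hyper_names = ["mu_f", "mu_n", "sigma_f", "sigma_n", "tau",
                   "nu", "sigma_b", "sigma_g"]
    hyper = {k: np.empty((n_chains, n_samples)) for k in hyper_names}
    pp_chain = np.zeros((n_chains, n_var))
    theta_sum = np.zeros(n_var)
    theta_sumsq = np.zeros(n_var)

    # Per-variant means for initialization.
    obs_count = np.bincount(v_idx, minlength=n_var).astype(float)
    obs_count[obs_count == 0] = 1.0
    var_mean = np.bincount(v_idx, weights=y, minlength=n_var) / obs_count

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)

    for chain in range(n_chains):
        rng = np.random.default_rng(chain_seeds[chain])
        mu_f = fix.get("mu_f", m0_f + 0.05 * rng.standard_normal())
        mu_n = fix.get("mu_n", m0_n + 0.05 * rng.standard_normal())
        if mu_n >= mu_f:
            mu_n = mu_f - 0.1
        sig2_f = fix.get("sigma_f", np.sqrt(0.1 * data_var)) ** 2
        sig2_n = fix.get("sigma_n", np.sqrt(0.1 * data_var)) ** 2
        tau2 = fix.get("tau", np.sqrt(0.05 * data_var)) ** 2
        nu = float(fix.get("nu", 6.0))
        b = np.zeros(n_batch)
        g = np.zeros(n_batch)
        sig2_b = 1e-3
        sig2_g = 1e-3
        lam = np.ones(n_obs)
        theta = var_mean.copy()
        z = np.where(free, (var_mean < 0.5 * (mu_f + mu_n)).astype(int),
                     np.maximum(z_fixed, 0))
        g_step = np.full(n_batch, 0.1)
        tau_step, nu_step = 0.1, 0.5

        for it in range(n_warmup + n_samples * thin):
            warming = it < n_warmup
            w = np.exp(g[m_idx]) if use_batch else np.ones(n_obs)
            boff = b[m_idx] if use_batch else 0.0
            r = y - boff - w * theta[v_idx]

            # --- residual scale and t df: marginal MH with the scale
            # mixture collapsed (valid because lam is redrawn right after).
            # Several alternating sweeps per iteration: each is O(N) and
            # cheap, and they decorrelate the (tau, nu) pair from lam.
            for _ in range(5):
                if "tau" not in fix:
                    ll_cur = _t_loglik(r, tau2, nu)
                    lt_prop = np.log(tau2) + tau_step * rng.standard_normal()
                    tau2_prop = np.exp(lt_prop)
                    # InvGamma(a_tau, b_tau) prior on tau2 + log Jacobian.
                    lp_cur = -a_tau * np.log(tau2) - b_tau / tau2
                    lp_prop = -a_tau * np.log(tau2_prop) - b_tau / tau2_prop
                    acc = (_t_loglik(r, tau2_prop, nu) + lp_prop
                           - ll_cur - lp_cur)
                    ok = np.log(rng.random()) < acc
                    if ok:
                        tau2 = tau2_prop
                    if warming:
                        tau_step *= np.exp(
                            0.05 * ((1.0 if ok else 0.0) - 0.44))
                if "nu" not in fix:
                    ll_cur = _t_loglik(r, tau2, nu)
                    eta = np.log(nu - 2.0)
                    eta_prop = eta + nu_step * rng.standard_normal()
                    nu_prop = 2.0 + np.exp(eta_prop)
                    # Gamma prior on nu truncated >2, plus log Jacobian.
                    lp_cur = ((nu_shape - 1.0) * np.log(nu) - nu_rate * nu
                              + np.log(nu - 2.0))
                    lp_prop = ((nu_shape - 1.0) * np.log(nu_prop)
                               - nu_rate * nu_prop + np.log(nu_prop - 2.0))
                    acc = (_t_loglik(r, tau2, nu_prop) + lp_prop
                           - ll_cur - lp_cur)
                    ok = np.log(rng.random()) < acc
                    if ok:
                        nu = nu_prop
                    if warming:
                        nu_step *= np.exp(
                            0.05 * ((1.0 if ok else 0.0) - 0.44))

            # --- lambda (t scale mixture) ---
            rate = 0.5 * (nu + r * r / tau2)
            lam = rng.gamma(0.5 * (nu + 1.0), 1.0 / rate)

            # --- theta ---
            prior_var = np.where(z == 1, sig2_n, sig2_f)
            prior_mean = np.where(z == 1, mu_n, mu_f)
            prec = np.bincount(v_idx, weights=lam * w * w, minlength=n_var) / tau2
            mean_num = (
                np.bincount(v_idx, weights=lam * w * (y - boff), minlength=n_var)
                / tau2
            )
            post_prec = 1.0 / prior_var + prec
            post_mean = (prior_mean / prior_var + mean_num) / post_prec
            theta = post_mean + rng.standard_normal(n_var) / np.sqrt(post_prec)

            # --- z (free variants only) ---
            log_odds = (
                np.log(prior_pi) - np.log1p(-prior_pi)
                + _norm_logpdf(theta, mu_n, sig2_n)
                - _norm_logpdf(theta, mu_f, sig2_f)
            )
            p1 = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
            draw = (rng.random(n_var) < p1).astype(int)
            z = np.where(free, draw, z)

            # --- component means (ordered mu_n < mu_f) ---
            in_n = z == 1
            n_n, n_f = int(in_n.sum()), int((~in_n).sum())
            sum_n = float(theta[in_n].sum())
            sum_f = float(theta[~in_n].sum())
            if "mu_n" not in fix:
                post_prec = 1.0 / s0_mu2 + n_n / sig2_n
                post_mean = (m0_n / s0_mu2 + sum_n / sig2_n) / post_prec
                mu_n = _trunc_norm(rng, post_mean, post_prec ** -0.5, upper=mu_f)
            if "mu_f" not in fix:
                post_prec = 1.0 / s0_mu2 + n_f / sig2_f
                post_mean = (m0_f / s0_mu2 + sum_f / sig2_f) / post_prec
                mu_f = _trunc_norm(rng, post_mean, post_prec ** -0.5, lower=mu_n)

            # --- component variances ---
            if "sigma_n" not in fix:
                ssq = float(((theta[in_n] - mu_n) ** 2).sum())
                sig2_n = max(
                    1.0 / rng.gamma(a_sig + 0.5 * n_n, 1.0 / (b_sig + 0.5 * ssq)),
                    _VAR_FLOOR,
                )
            if "sigma_f" not in fix:
                ssq = float(((theta[~in_n] - mu_f) ** 2).sum())
                sig2_f = max(
                    1.0 / rng.gamma(a_sig + 0.5 * n_f, 1.0 / (b_sig + 0.5 * ssq)),
                    _VAR_FLOOR,
                )

            if use_batch:
                # --- location batch effects (conjugate) ---
                u = y - np.exp(g[m_idx]) * theta[v_idx]
                prec_m = (
                    np.bincount(m_idx, weights=lam, minlength=n_batch) / tau2
                    + 1.0 / sig2_b
                )
                mean_m = (
                    np.bincount(m_idx, weights=lam * u, minlength=n_batch) / tau2
                ) / prec_m
                b = mean_m + rng.standard_normal(n_batch) / np.sqrt(prec_m)

                # --- log-scale batch effects (random-walk MH, vectorized
                # over batches; a few sweeps to cut autocorrelation) ---
                th_v = theta[v_idx]
                for _ in range(5):
                    g_prop = g + g_step * rng.standard_normal(n_batch)
                    r_cur = y - b[m_idx] - np.exp(g[m_idx]) * th_v
                    r_prop = y - b[m_idx] - np.exp(g_prop[m_idx]) * th_v
                    ll_cur = np.bincount(
                        m_idx, weights=-0.5 * lam * r_cur * r_cur / tau2,
                        minlength=n_batch,
                    )
                    ll_prop = np.bincount(
                        m_idx, weights=-0.5 * lam * r_prop * r_prop / tau2,
                        minlength=n_batch,
                    )
                    log_acc = (ll_prop - ll_cur
                               - 0.5 * (g_prop ** 2 - g ** 2) / sig2_g)
                    accept = np.log(rng.random(n_batch)) < log_acc
                    g = np.where(accept, g_prop, g)
                    if warming:
                        g_step *= np.exp(
                            0.05 * (accept.astype(float) - 0.44))

                # --- batch-effect scales ---
                sig2_b = max(
                    1.0 / rng.gamma(
                        a_bat + 0.5 * n_batch,
                        1.0 / (b_bat + 0.5 * float((b * b).sum())),
                    ),
                    _VAR_FLOOR,
                )

                # Interweaving step (ASIS) for the location effects: with
                # u = b / sigma_b held fixed, jointly rescale (sigma_b, b).
                s_cur = np.sqrt(sig2_b)
                if s_cur > 1e-8:
                    u_b = b / s_cur
                    resid_b = y - np.exp(g[m_idx]) * theta[v_idx]

                    def _loc_scale_logpost(s):
                        rr = resid_b - s * u_b[m_idx]
                        ll = -0.5 * float((lam * rr * rr).sum()) / tau2
                        s2 = s * s
                        lp = -(a_bat + 1.0) * np.log(s2) - b_bat / s2
                        return ll + lp + 2.0 * np.log(s)  # Jacobian

                    lp_cur = _loc_scale_logpost(s_cur)
                    for _ in range(5):
                        s_prop = s_cur * np.exp(0.3 * rng.standard_normal())
                        lp_prop = _loc_scale_logpost(s_prop)
                        if np.log(rng.random()) < lp_prop - lp_cur:
                            s_cur, lp_cur = s_prop, lp_prop
                    b = u_b * s_cur
                    sig2_b = s_cur * s_cur
                sig2_g = max(
                    1.0 / rng.gamma(
                        a_bat + 0.5 * n_batch,
                        1.0 / (b_bat + 0.5 * float((g * g).sum())),
                    ),
                    _VAR_FLOOR,
                )

                # Interweaving step (ASIS): with u = g / sigma_g held
                # fixed, jointly rescale (sigma_g, g). Breaks the tight
                # coupling that makes sigma_g mix slowly when the scale
                # effects are weakly identified.
                s_cur = np.sqrt(sig2_g)
                if s_cur > 1e-8:
                    u_g = g / s_cur
                    resid0 = y - b[m_idx]
                    th_v = theta[v_idx]

                    def _scale_logpost(s):
                        rr = resid0 - np.exp(s * u_g[m_idx]) * th_v
                        ll = -0.5 * float((lam * rr * rr).sum()) / tau2
                        s2 = s * s
                        lp = -(a_bat + 1.0) * np.log(s2) - b_bat / s2
                        return ll + lp + 2.0 * np.log(s)  # Jacobian

                    lp_cur = _scale_logpost(s_cur)
                    for _ in range(5):
                        s_prop = s_cur * np.exp(0.3 * rng.standard_normal())
                        lp_prop = _scale_logpost(s_prop)
                        if np.log(rng.random()) < lp_prop - lp_cur:
                            s_cur, lp_cur = s_prop, lp_prop
                    g = u_g * s_cur
                    sig2_g = s_cur * s_cur

            if it >= n_warmup and (it - n_warmup) % thin == 0:
                s = (it - n_warmup) // thin
                hyper["mu_f"][chain, s] = mu_f
                hyper["mu_n"][chain, s] = mu_n
                hyper["sigma_f"][chain, s] = np.sqrt(sig2_f)
                hyper["sigma_n"][chain, s] = np.sqrt(sig2_n)
                hyper["tau"][chain, s] = np.sqrt(tau2)
                hyper["nu"][chain, s] = nu
                hyper["sigma_b"][chain, s] = np.sqrt(sig2_b)
                hyper["sigma_g"][chain, s] = np.sqrt(sig2_g)
                pp_chain[chain] += z
                theta_sum += theta
                theta_sumsq += theta * theta

    pp_chain /= n_samples
    n_draws = n_chains * n_samples
    theta_mean = theta_sum / n_draws
    theta_var = np.maximum(theta_sumsq / n_draws - theta_mean ** 2, 0.0)
    return {
        "pp": pp_chain.mean(axis=0),
        "pp_chain": pp_chain,
        "theta_mean": theta_mean,
        "theta_sd": np.sqrt(theta_var),
        "hyper": hyper,
        "n_draws": n_draws,
    }
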