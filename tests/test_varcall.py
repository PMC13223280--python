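import numpy as np
import pandas as pd
import pytest

from sgeintegrate import (
    SimulationConfig,
    VarCallModel,
    posterior_to_bf,
    prior_sensitivity,
    rescale_assay,
    simulate_screen,
)


def _consequences(model, variants):
    return (variants.set_index("variant_id")["consequence"]
            .reindex(model.variant_ids_))


def test_pinned_controls_have_extreme_posteriors(screen500, varcall500):
    variants, _, _ = screen500
    cons = _consequences(varcall500, variants)
    syn = (cons == "synonymous").to_numpy()
    non = (cons == "nonsense").to_numpy()
    assert np.all(varcall500.pp_raw_[syn] == 0.0)
    assert np.all(varcall500.pp_raw_[non] == 1.0)
    # After clamping, the controls carry maximal-strength finite evidence.
    assert set(varcall500.category_[syn]) == {"B_Strong"}
    assert set(varcall500.category_[non]) == {"P_Strong"}
    assert np.all(np.isfinite(varcall500.bf_))


def test_component_means_recovered_within_3_posterior_sd(varcall500):
    cfg = SimulationConfig()  # generator defaults used by the fixture
    assert abs(varcall500.mu_f_ - cfg.mu_functional) < 3 * varcall500.mu_f_sd_
    assert abs(varcall500.mu_n_ - cfg.mu_nonfunctional) < 3 * varcall500.mu_n_sd_


def test_fit_converged_with_diagnostics(varcall500):
    assert varcall500.converged_
    assert set(varcall500.diagnostics_["rhat"]) == set(
        varcall500.diagnostics_["ess"])
    assert max(varcall500.diagnostics_["rhat"].values()) <= 1.05


def test_bf_is_posterior_over_prior_odds(varcall500):
    pp = varcall500.pp_
    inside = (pp > 0) & (pp < 1)
    pi = varcall500.prior_pathogenic
    expected = (pp[inside] / (1 - pp[inside])) / (pi / (1 - pi))
    np.testing.assert_allclose(varcall500.bf_[inside], expected, atol=1e-9)


def test_pp_nonincreasing_in_mean_score(screen500, varcall500, harmonized500):
    variants, _, _ = screen500
    cons = _consequences(varcall500, variants)
    free = ~cons.isin(["synonymous", "nonsense"]).to_numpy()
    means = (harmonized500.observations.groupby("variant_id")["rescaled_score"]
             .mean().reindex(varcall500.variant_ids_).to_numpy())
    order = np.argsort(means[free])
    pp_sorted = varcall500.pp_[free][order]
    # Monotone up to Monte Carlo noise on the posterior probabilities.
    assert np.all(np.diff(pp_sorted) <= 0.02)


def test_batch_free_data_shrinks_batch_scales():
    cfg = SimulationConfig(n_variants=150, batch_location_sd=0.0,
                           batch_logscale_sd=0.0, seed=31)
    variants, scores, _ = simulate_screen(cfg)
    hd = rescale_assay(scores, variants)
    m = VarCallModel(seed=5, n_warmup=400, n_samples=600).fit(hd, variants)
    sigma_b_med = float(np.median(m.hyper_draws_["sigma_b"]))
    sigma_g_med = float(np.median(m.hyper_draws_["sigma_g"]))
    assert sigma_b_med < 0.1 * m.tau_
    assert sigma_g_med < 1.0  # log-scale effects likewise collapse


def test_missing_controls_raise(screen500):
    variants, scores, _ = screen500
    keep = variants[variants["consequence"] != "nonsense"]
    sub = scores[scores["variant_id"].isin(keep["variant_id"])]
    with pytest.raises(ValueError, match="nonsense"):
        VarCallModel(n_warmup=10, n_samples=10).fit(sub, keep)


def test_calls_table_schema(varcall500):
    assert list(varcall500.calls_.columns) == [
        "variant_id", "pp", "bf", "category", "model_tag"]
    assert (varcall500.calls_["model_tag"] == "varcall").all()
    assert varcall500.calls_["variant_id"].is_unique


def test_predict_matches_calls(varcall500):
    ids = varcall500.variant_ids_[[5, 2, 9]]
    np.testing.assert_allclose(varcall500.predict_proba(ids),
                               varcall500.pp_[[5, 2, 9]])
    assert list(varcall500.predict(ids)) == list(varcall500.category_[[5, 2, 9]])


def test_prior_sensitivity_categories_stable(small_screen):
    variants, scores, _ = small_screen
    hd = rescale_assay(scores, variants)
    out = prior_sensitivity(hd, variants, priors=(0.2, 0.1), seed=9,
                            n_warmup=400, n_samples=600)
    assert out["concordance"] >= 0.95


def test_identical_priors_give_full_concordance(small_screen):
    variants, scores, _ = small_screen
    hd = rescale_assay(scores, variants)
    out = prior_sensitivity(hd, variants, priors=(0.2, 0.2), seed=9,
                            n_warmup=200, n_samples=300)
    assert out["concordance"] == 1.0


def test_invalid_spec_rejected(harmonized500, screen500):
    variants, _, _ = screen500
    with pytest.raises(ValueError):
        VarCallModel(prior_pathogenic=0.0).fit(harmonized500, variants)
    with pytest.raises(ValueError):
        VarCallModel(n_chains=1).fit(harmonized500, variants)
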