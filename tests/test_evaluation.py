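import numpy as np
import pandas as pd
import pytest

from sgeintegrate import evaluate, pooled_burden_or


def _calls(pairs):
    return pd.DataFrame(pairs, columns=["variant_id", "category"])


def _standards(pairs, col="clinvar_standard"):
    df = pd.DataFrame(pairs, columns=["variant_id", col])
    other = ("hdr_standard" if col == "clinvar_standard"
             else "clinvar_standard")
    df[other] = "none"
    return df


def test_perfect_calls_score_one():
    calls = _calls([("v1", "P_Strong"), ("v2", "B_Strong")])
    std = _standards([("v1", "P/LP"), ("v2", "B/LB")])
    rep = evaluate(calls, std, "clinvar", "conservative")
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.discrepant_variants == []


def test_single_miss_arithmetic():
    # 90 of 91 pathogenic standards detected: sensitivity 90/91.
    calls = _calls([(f"p{i}", "P_Strong") for i in range(90)]
                   + [("p90", "Uncertain")]
                   + [("b0", "B_Moderate")])
    std = _standards([(f"p{i}", "P/LP") for i in range(91)]
                     + [("b0", "B/LB")])
    rep = evaluate(calls, std, "clinvar", "conservative")
    assert rep.sensitivity == pytest.approx(90 / 91)
    assert rep.specificity == 1.0


def test_uncertain_call_dilutes_but_is_not_discrepant():
    calls = _calls([("v1", "Uncertain"), ("v2", "B_Strong")])
    std = _standards([("v1", "P/LP"), ("v2", "P/LP")])
    rep = evaluate(calls, std, "clinvar", "conservative")
    assert rep.sensitivity == 0.0
    assert rep.discrepant_variants == ["v2"]  # opposite side only


def test_conservative_never_beats_all_categories():
    rng = np.random.default_rng(8)
    cats = ["P_Strong", "P_Moderate", "P_Supporting", "Uncertain",
            "B_Supporting", "B_Moderate", "B_Strong"]
    for trial in range(20):
        n = 40
        calls = _calls([(f"v{i}", rng.choice(cats)) for i in range(n)])
        std = _standards(
            [(f"v{i}", rng.choice(["P/LP", "B/LB"])) for i in range(n)])
        cons = evaluate(calls, std, "clinvar", "conservative")
        allc = evaluate(calls, std, "clinvar", "all_categories")
        assert cons.sensitivity <= allc.sensitivity + 1e-12
        assert cons.specificity <= allc.specificity + 1e-12


def test_evaluation_invariant_to_input_order():
    rng = np.random.default_rng(4)
    calls = _calls([(f"v{i}", rng.choice(["P_Strong", "B_Strong"]))
                    for i in range(30)])
    std = _standards([(f"v{i}", rng.choice(["P/LP", "B/LB"]))
                      for i in range(30)], col="hdr_standard")
    std["hdr_standard"] = std["hdr_standard"].map(
        {"P/LP": "abnormal", "B/LB": "normal"})
    a = evaluate(calls, std, "hdr", "all_categories")
    b = evaluate(calls.iloc[::-1], std.sample(frac=1, random_state=1),
                 "hdr", "all_categories")
    assert a.sensitivity == b.sensitivity
    assert a.specificity == b.specificity


def test_absent_polarity_reports_none_not_zero():
    calls = _calls([("v1", "P_Strong")])
    std = _standards([("v1", "P/LP")])
    rep = evaluate(calls, std, "clinvar", "conservative")
    assert rep.specificity is None
    assert rep.n_benign_standards == 0


@pytest.mark.parametrize(
    "table, expected_or",
    [((10, 90, 10, 990), 11.0), ((1, 1, 1, 1), 1.0)],
)
def test_pooled_or_arithmetic(table, expected_or):
    out = pooled_burden_or(*table)
    assert out["odds_ratio"] == pytest.approx(expected_or)
    if table == (1, 1, 1, 1):
        assert out["p_value"] == pytest.approx(1.0)


def test_zero_cell_continuity_correction():
    out = pooled_burden_or(5, 0, 2, 100)
    expected = (5.5 * 100.5) / (0.5 * 2.5)
    assert out["continuity_corrected"]
    assert out["odds_ratio"] == pytest.approx(expected)


def test_degenerate_table_reports_absent_or():
    out = pooled_burden_or(0, 0, 5, 5)
    assert out["odds_ratio"] is None
    with pytest.raises(ValueError):
        pooled_burden_or(-1, 2, 3, 4)


def test_type_i_error_under_null():
    # Carrier rate identical in cases and controls: the two-sided Fisher
    # test should reject at most ~5% of the time at alpha = 0.05.
    rng = np.random.default_rng(123)
    n_sim, alpha, rate = 1000, 0.05, 0.05
    n_case = n_ctrl = 400
    rejections = 0
    for _ in range(n_sim):
        a = rng.binomial(n_case, rate)
        c = rng.binomial(n_ctrl, rate)
        out = pooled_burden_or(a, n_case - a, c, n_ctrl - c)
        rejections += out["p_value"] < alpha
    assert rejections / n_sim <= 0.06
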