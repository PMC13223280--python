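import itertools

import numpy as np
import pandas as pd
import pytest

from sgeintegrate.acmg import (
    EvidenceCode,
    EvidenceProfile,
    build_profile,
    classify,
    frequency_evidence,
    functional_evidence,
    insilico_evidence,
    parse_preassigned,
    points_to_class,
    run_classification,
)


@pytest.mark.parametrize(
    "category, code, strength, points",
    [
        ("P_Strong", "PS3", "strong", 4),
        ("P_Moderate", "PS3", "moderate", 2),
        ("P_Supporting", "PS3", "supporting", 1),
        ("B_Supporting", "BS3", "supporting", -1),
        ("B_Moderate", "BS3", "moderate", -2),
        ("B_Strong", "BS3", "strong", -4),
    ],
)
def test_functional_code_strength_capped_at_strong(category, code, strength,
                                                   points):
    c = functional_evidence(category)
    assert (c.code, c.strength, c.points) == (code, strength, points)


def test_uncertain_gets_no_functional_code():
    assert functional_evidence("Uncertain") is None


@pytest.mark.parametrize(
    "faf, code, points",
    [
        (0.002, "BA1", -8),
        (0.0005, "BS1", -4),
        (0.00005, "BS1_Supporting", -1),
        (0.00001, None, None),
        (None, "PM2_Supporting", 1),
        (float("nan"), "PM2_Supporting", 1),
    ],
)
def test_frequency_code_thresholds(faf, code, points):
    c = frequency_evidence(faf)
    if code is None:
        assert c is None
    else:
        assert (c.code, c.points) == (code, points)


def test_frequency_rejects_out_of_range():
    with pytest.raises(ValueError):
        frequency_evidence(1.5)


@pytest.mark.parametrize(
    "bayesdel, splice, code, points",
    [
        (0.35, False, "PP3", 2),
        (0.30, False, "PP3", 2),
        (0.20, False, None, None),
        (0.05, False, "BP4", -1),
        (0.05, True, "PP3", 1),     # splice flag dominates the benign score
        (None, True, "PP3", 1),
        (None, False, None, None),
    ],
)
def test_insilico_codes(bayesdel, splice, code, points):
    c = insilico_evidence(bayesdel, splice)
    if code is None:
        assert c is None
    else:
        assert (c.code, c.points) == (code, points)


def test_point_bands_partition_all_totals():
    boundaries = {-7: "B", -6: "LB", -2: "LB", -1: "VUS", 5: "VUS",
                  6: "LP", 9: "LP", 10: "P"}
    for total, expected in boundaries.items():
        assert points_to_class(total) == expected
    for total in range(-30, 31):
        cls = points_to_class(total)
        assert cls in {"P", "LP", "VUS", "LB", "B"}
    # bands are contiguous and ordered
    order = ["B", "LB", "VUS", "LP", "P"]
    seq = [points_to_class(t) for t in range(-30, 31)]
    assert sorted(set(seq), key=order.index) == order
    assert all(order.index(a) <= order.index(b)
               for a, b in zip(seq, seq[1:]))


CODE_POOL = [
    EvidenceCode("PVS1", "very_strong", "preassigned"),
    EvidenceCode("PS3", "strong"),
    EvidenceCode("PM2_Supporting", "supporting"),
    EvidenceCode("PM3", "moderate", "preassigned"),
    EvidenceCode("PP3", "moderate"),
    EvidenceCode("BP5", "supporting", "preassigned"),
]


def test_brute_force_over_code_subsets():
    for r in range(len(CODE_POOL) + 1):
        for subset in itertools.combinations(CODE_POOL, r):
            profile = EvidenceProfile("v1", list(subset))
            out = classify(profile)
            expected_total = sum(c.points for c in subset)
            assert out["total_points"] == expected_total
            assert out["class"] == points_to_class(expected_total)


def test_adding_evidence_moves_class_monotonically():
    order = ["B", "LB", "VUS", "LP", "P"]
    benign = EvidenceCode("BS3", "strong")
    pathogenic = EvidenceCode("PS1", "strong", "preassigned")
    for r in range(4):
        for subset in itertools.combinations(CODE_POOL[2:], r):
            base = classify(EvidenceProfile("v", list(subset)))["class"]
            with_b = classify(
                EvidenceProfile("v", list(subset) + [benign]))["class"]
            with_p = classify(
                EvidenceProfile("v", list(subset) + [pathogenic]))["class"]
            assert order.index(with_b) <= order.index(base)
            assert order.index(with_p) >= order.index(base)


@pytest.mark.parametrize(
    "codes",
    [
        [EvidenceCode("PS3", "strong"), EvidenceCode("BS3", "strong")],
        [EvidenceCode("BA1", "stand_alone"), EvidenceCode("BS1", "strong")],
        [EvidenceCode("BA1", "stand_alone"),
         EvidenceCode("PM2_Supporting", "supporting")],
        [EvidenceCode("PP3", "moderate"), EvidenceCode("BP4", "supporting")],
    ],
)
def test_mutually_exclusive_codes_rejected(codes):
    with pytest.raises(ValueError, match="mutually exclusive"):
        classify(EvidenceProfile("v1", codes))


def test_invalid_strength_for_polarity_rejected():
    with pytest.raises(ValueError):
        EvidenceCode("PS3", "stand_alone").points
    with pytest.raises(ValueError):
        EvidenceCode("BS3", "very_strong").points


def test_parse_preassigned_round_trip():
    codes = parse_preassigned("PVS1:very_strong;PM3:moderate")
    assert [(c.code, c.points, c.source) for c in codes] == [
        ("PVS1", 8, "preassigned"), ("PM3", 2, "preassigned")]
    assert parse_preassigned("") == []
    with pytest.raises(ValueError, match="malformed"):
        parse_preassigned("PVS1")


def test_discordance_override():
    profile = EvidenceProfile("v1", [EvidenceCode("PS3", "strong"),
                                     EvidenceCode("PVS1", "very_strong",
                                                  "preassigned")])
    # P-side call conflicting with a benign ClinVar standard -> override.
    out = classify(profile, call_category="P_Strong",
                   clinvar_standard="B/LB")
    assert out["class"] == "VUS_discordant"
    # Concordant standard: points decide.
    out2 = classify(profile, call_category="P_Strong",
                    clinvar_standard="P/LP")
    assert out2["class"] == "P"
    # No standards: the override never fires.
    out3 = classify(profile, call_category="P_Strong")
    assert out3["class"] == "P"
    # HDR normal conflicts with a pathogenic call.
    out4 = classify(profile, call_category="P_Strong", hdr_standard="normal")
    assert out4["class"] == "VUS_discordant"


def test_uncertain_call_never_triggers_override():
    profile = EvidenceProfile("v1", [EvidenceCode("BA1", "stand_alone")])
    out = classify(profile, call_category="Uncertain",
                   clinvar_standard="P/LP", hdr_standard="abnormal")
    assert out["class"] == "B"


def _variants_frame(rows):
    cols = ["variant_id", "consequence", "bayesdel", "spliceai_flag", "faf",
            "preassigned_codes", "clinvar_standard", "hdr_standard"]
    return pd.DataFrame(rows, columns=cols)


def test_run_classification_functional_only_fixture():
    variants = _variants_frame([
        ("v1", "missense", 0.2, False, 5e-6, "", "none", "none"),
        ("v2", "missense", 0.2, False, 5e-6, "", "none", "none"),
    ])
    calls = pd.DataFrame({"variant_id": ["v1", "v2"],
                          "category": ["P_Strong", "B_Strong"]})
    table, summary = run_classification(variants, calls)
    assert (table["class_without_functional"] == "VUS").all()
    assert summary["without_functional"]["classified_fraction"] == 0.0
    assert list(table["class_with_functional"]) == ["VUS", "LB"]
    assert summary["with_functional"]["n_classified"] == 1  # the LB call


def test_run_classification_all_benign_ba1():
    variants = _variants_frame([
        (f"v{i}", "missense", 0.2, False, 0.01, "", "none", "none")
        for i in range(4)
    ])
    calls = pd.DataFrame({"variant_id": [f"v{i}" for i in range(4)],
                          "category": ["Uncertain"] * 4})
    table, summary = run_classification(variants, calls)
    assert (table["class_with_functional"] == "B").all()
    assert (table["class_without_functional"] == "B").all()


def test_functional_data_increases_classified_fraction(screen500,
                                                       varcall500):
    variants, _, _ = screen500
    table, summary = run_classification(variants, varcall500.calls_)
    assert (summary["with_functional"]["classified_fraction"]
            > summary["without_functional"]["classified_fraction"])


def test_missing_call_classified_without_functional():
    variants = _variants_frame([
        ("v1", "missense", 0.5, False, None, "", "none", "none")])
    calls = pd.DataFrame({"variant_id": [], "category": []})
    table, _ = run_classification(variants, calls)
    assert table["class_with_functional"].iloc[0] == \
        table["class_without_functional"].iloc[0]


def test_build_profile_prefers_preassigned_families():
    var = pd.Series({"variant_id": "v1", "preassigned_codes": "BA1:stand_alone",
                     "faf": float("nan"), "bayesdel": 0.5,
                     "spliceai_flag": False})
    profile = build_profile(var, None)
    names = [c.code for c in profile.codes]
    assert "BA1" in names and "PM2_Supporting" not in names
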