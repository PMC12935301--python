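"""Evidence combination (categorical and points modes) and ClinVar comparison."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from chd4var.acmg_engine import (
    CombinationConfig,
    EvidenceSet,
    PAPER_MODE,
    classify_all,
    combine_categorical,
    combine_points,
    compare_to_clinvar,
    evidence_for,
)
from chd4var.variant_model import Classification, EvidenceCode, Strength

C = Classification
HONOR = CombinationConfig(pp3_tier_handling="honor_tier")
POINTS = CombinationConfig(mode="points")
STRICT = CombinationConfig(conflict_policy="richards_vus")


def ev(*codes):
    return EvidenceSet.of(*codes)


@pytest.mark.parametrize(
    "codes, expected",
    [
        (("PS2", "PS3", "PM2", "PP3_moderate"), C.PATHOGENIC),
        (("PS2", "PM2", "PP3_strong"), C.LIKELY_PATHOGENIC),  # tier collapsed
        (("PM2", "BS2", "BP4_moderate"), C.LIKELY_BENIGN),
        (("PS2", "PM2", "BP4_moderate"), C.LIKELY_PATHOGENIC),
        ((), C.VUS),
        (("PM2", "PM6"), C.VUS),
        (("PS2", "PM2"), C.LIKELY_PATHOGENIC),
        (("PM2", "PM6", "PP2", "PP3_moderate"), C.LIKELY_PATHOGENIC),
        (("PVS1", "PM2"), C.LIKELY_PATHOGENIC),
        (("PVS1", "PS2"), C.PATHOGENIC),
        (("BA1",), C.BENIGN),
        (("BS1", "BS2"), C.BENIGN),
        (("BP1", "BP4"), C.LIKELY_BENIGN),
    ],
)
def test_combine_categorical_examples(codes, expected):
    assert combine_categorical(ev(*codes), PAPER_MODE) == expected


def test_honor_tier_upgrades_strong_pp3():
    """With the tier honored, PP3_strong counts as a second strong criterion."""
    e = ev("PS2", "PM2", "PP3_strong")
    assert combine_categorical(e, PAPER_MODE) == C.LIKELY_PATHOGENIC
    assert combine_categorical(e, HONOR) == C.PATHOGENIC


def test_strict_conflict_policy_returns_vus():
    e = ev("PS2", "PM2", "BP4_moderate")
    assert combine_categorical(e, STRICT) == C.VUS
    assert combine_categorical(e, PAPER_MODE) == C.LIKELY_PATHOGENIC


@pytest.mark.parametrize(
    "codes, cfg, expected_cls, expected_points",
    [
        (("PS2", "PS3", "PM2", "PP3_supporting"), POINTS, C.PATHOGENIC, 11),
        (("PM2", "BS2", "BP4_moderate"),
         CombinationConfig(mode="points", pp3_tier_handling="honor_tier"),
         C.LIKELY_BENIGN, -4),
        ((), POINTS, C.VUS, 0),
        (("PS2", "PM2", "BP4_moderate"), POINTS, C.VUS, 5),
    ],
)
def test_combine_points_examples(codes, cfg, expected_cls, expected_points):
    assert combine_points(ev(*codes), cfg) == (expected_cls, expected_points)


def test_evidence_set_rejects_duplicates_and_pp3_bp4_conflict():
    with pytest.raises(ValueError, match="duplicate"):
        ev("PS2", "PS2")
    with pytest.raises(ValueError, match="PP3 and BP4"):
        ev("PP3", "BP4")


def test_unknown_code_raises():
    with pytest.raises(ValueError):
        ev("PS9")


def test_acmg_column_golden(missense):
    """Study-mode classification reproduces the published verdict for all 33 rows."""
    table, hist = classify_all(missense, PAPER_MODE)
    expected = {"P": "Pathogenic", "LP": "Likely pathogenic",
                "LB": "Likely benign", "VUS": "VUS"}
    for v, got in zip(missense, table["classification"]):
        assert got == expected[v.annotations["acmg"]], v.id
    assert hist == {"Pathogenic": 7, "Likely pathogenic": 19,
                    "Likely benign": 1, "VUS": 6}


def test_combined_evidence_matches_published_criteria_strings(missense):
    """Curated codes plus the recomputed PP3/BP4 equal the published criteria set."""
    for v in missense:
        got = {c.code for c in evidence_for(v).codes}
        published = {tok for tok in v.annotations["_evidence_raw"].split("+")}
        assert got == published, v.id


def test_points_mode_diverges_only_at_v1608i(missense):
    cat, _ = classify_all(missense, PAPER_MODE)
    pts, _ = classify_all(missense, POINTS)
    diverging = [a for a, b, c in zip(cat["variant"], cat["classification"],
                                      pts["classification"]) if b != c]
    assert diverging == ["p.V1608I"]
    row = pts[pts["variant"] == "p.V1608I"].iloc[0]
    assert row["classification"] == "VUS" and row["points"] == 5


def test_classify_all_empty():
    table, hist = classify_all([])
    assert len(table) == 0 and hist == {}


_PATHOGENIC_CODES = ["PVS1", "PS2", "PS3", "PM2", "PM6", "PP2", "PP3"]
_ALL_CODES = _PATHOGENIC_CODES + ["BS2", "BP4"]


def test_rule_table_exhaustive_over_small_evidence_sets():
    """Every evidence set of <= 6 distinct codes classifies without error."""
    seen = set()
    for r in range(7):
        for combo in itertools.combinations(_ALL_CODES, r):
            if "PP3" in combo and "BP4" in combo:
                continue
            seen.add(combine_categorical(ev(*combo), PAPER_MODE))
            combine_points(ev(*combo), POINTS)
    assert seen <= set(Classification)
    assert C.PATHOGENIC in seen and C.VUS in seen


@settings(max_examples=200, derandomize=True)
@given(
    base=st.lists(st.sampled_from(_PATHOGENIC_CODES), unique=True, max_size=5),
    extra=st.sampled_from(_PATHOGENIC_CODES),
)
def test_adding_pathogenic_evidence_never_lowers_class(base, extra):
    if extra in base:
        return
    before = combine_categorical(ev(*base), PAPER_MODE)
    after = combine_categorical(ev(*base, extra), PAPER_MODE)
    assert after >= before


@settings(max_examples=100, derandomize=True)
@given(base=st.lists(st.sampled_from(["BA1", "BS1", "BS2", "BP1", "BP4"]),
                     unique=True, max_size=3),
       extra=st.sampled_from(["BA1", "BS1", "BS2", "BP1", "BP4"]))
def test_adding_benign_evidence_never_raises_class(base, extra):
    if extra in base:
        return
    before = combine_categorical(ev(*base), PAPER_MODE)
    after = combine_categorical(ev(*base, extra), PAPER_MODE)
    assert after <= before


def test_combine_is_pure():
    e = ev("PS2", "PM2", "PP3_strong")
    assert all(combine_categorical(e, PAPER_MODE) == C.LIKELY_PATHOGENIC
               for _ in range(5))


@pytest.mark.parametrize(
    "ours, label, expected",
    [
        (C.PATHOGENIC, "VUS", "Upgraded"),
        (C.VUS, "LP", "Downgraded"),
        (C.LIKELY_PATHOGENIC, "P/LP", "Unchanged"),
        (C.PATHOGENIC, "P/LP", "Unchanged"),
        (C.VUS, "P/LP", "Downgraded"),
        (C.LIKELY_PATHOGENIC, "NP", "First classification"),
        (C.PATHOGENIC, "CS", "Upgraded"),
        (C.VUS, "CS", "Unchanged"),
        (C.LIKELY_BENIGN, "VUS", "Downgraded"),
    ],
)
def test_compare_to_clinvar(ours, label, expected):
    assert compare_to_clinvar(ours, label) == expected


def test_compare_to_clinvar_unknown_label():
    with pytest.raises(ValueError):
        compare_to_clinvar(C.VUS, "maybe")


def test_clinvar_comparison_column_golden(missense):
    """The comparison column reproduces the published Table recount:
    12 unchanged, 10 first classifications, 4 upgrades, 7 downgrades."""
    table, _ = classify_all(missense, PAPER_MODE)
    for v, got in zip(missense, table["comparison"]):
        assert got == v.annotations["comparison"], v.id
    tally = table["comparison"].value_counts().to_dict()
    assert tally == {"Unchanged": 12, "First classification": 10,
                     "Upgraded": 4, "Downgraded": 7}


def test_config_yaml_roundtrip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("mode: points\nconflict_policy: richards_vus\n"
                 "thresholds: {pathogenic: 12, likely_pathogenic: 6, "
                 "likely_benign: -1, benign: -7}\n")
    cfg = CombinationConfig.from_yaml(p)
    assert cfg.mode == "points" and cfg.conflict_policy == "richards_vus"
    assert cfg.thresholds["pathogenic"] == 12
    # with the raised pathogenic band, 11 points is only likely pathogenic
    assert combine_points(ev("PS2", "PS3", "PM2", "PP3"), cfg)[0] == C.LIKELY_PATHOGENIC
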