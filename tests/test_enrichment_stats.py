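"""Exact 2x2 statistics: hypergeometric pmf, Fisher test, Katz CI, enrich()."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hs

from chd4var.enrichment_stats import (
    ContingencyTable2x2,
    STUDY_TABLE,
    STUDY_TABLE_AS_WRITTEN,
    enrich,
    feasible_range,
    fisher_exact_two_sided,
    hypergeom_pmf,
    odds_ratio_katz_ci,
)


def exact_two_sided_p(t: ContingencyTable2x2) -> float:
    """Brute-force oracle: exact rational enumeration over all tables with the
    observed margins, summing those no more probable than the observed one."""
    r1, r2, c1, c2 = t.margins
    n = r1 + r2
    lo, hi = feasible_range(t.margins)
    weights = {k: comb(c1, k) * comb(c2, r1 - k) for k in range(lo, hi + 1)}
    obs = weights[t.a]
    total = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(total, comb(n, r1)))


def test_pmf_example_exact_value():
    # C(28,19)*C(7,1)/C(35,20)
    assert hypergeom_pmf(19, (20, 15, 28, 7)) == pytest.approx(0.014886, abs=5e-7)


def test_pmf_degenerate_margin():
    # with no "no" outcomes at all, the only feasible table has probability one
    assert hypergeom_pmf(5, (5, 3, 8, 0)) == pytest.approx(1.0)


def test_pmf_infeasible_cell_raises():
    with pytest.raises(ValueError, match="infeasible"):
        hypergeom_pmf(21, (20, 15, 28, 7))


def test_pmf_normalizes_over_feasible_range_random_margins():
    rng = np.random.default_rng(20260930)
    for _ in range(100):
        n = int(rng.integers(2, 80))
        r1 = int(rng.integers(1, n))
        c1 = int(rng.integers(1, n))
        margins = (r1, n - r1, c1, n - c1)
        lo, hi = feasible_range(margins)
        total = sum(hypergeom_pmf(k, margins) for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_pmf_matches_scipy_hypergeom():
    margins = (20, 15, 28, 7)
    lo, hi = feasible_range(margins)
    for k in range(lo, hi + 1):
        assert hypergeom_pmf(k, margins) == pytest.approx(
            st.hypergeom.pmf(k, 35, 28, 20), rel=1e-12)


def test_fisher_study_table():
    assert fisher_exact_two_sided(STUDY_TABLE) == pytest.approx(0.0274, abs=5e-5)


def test_fisher_symmetric_table_is_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)


def test_fisher_transpose_invariance():
    t = STUDY_TABLE
    assert fisher_exact_two_sided(t) == pytest.approx(
        fisher_exact_two_sided(t.transpose()), rel=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(a=hs.integers(0, 12), b=hs.integers(0, 12),
       c=hs.integers(0, 12), d=hs.integers(0, 12))
def test_fisher_invariant_under_row_and_column_swaps(a, b, c, d):
    if a + b + c + d == 0:
        return
    p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
    for swapped in [(c, d, a, b), (b, a, d, c), (d, c, b, a)]:
        assert fisher_exact_two_sided(ContingencyTable2x2(*swapped)) == \
            pytest.approx(p, rel=1e-9)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(a=hs.integers(0, 15), b=hs.integers(0, 15),
       c=hs.integers(0, 15), d=hs.integers(0, 15))
def test_fisher_matches_exact_enumeration_and_scipy(a, b, c, d):
    if a + b + c + d == 0:
        return
    t = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(t)
    assert p == pytest.approx(exact_two_sided_p(t), rel=1e-9)
    assert p == pytest.approx(st.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-9)


def test_fisher_double_one_sided_option():
    p = fisher_exact_two_sided(STUDY_TABLE, method="double_one_sided")
    upper = sum(hypergeom_pmf(k, STUDY_TABLE.margins) for k in (19, 20))
    assert p == pytest.approx(min(1.0, 2 * upper), rel=1e-9)


def test_katz_ci_study_table():
    res = odds_ratio_katz_ci(STUDY_TABLE, 0.05)
    assert res.odds_ratio == pytest.approx(12.67, abs=5e-3)
    assert res.ci_low == pytest.approx(1.321, abs=5e-4)
    assert res.ci_high == pytest.approx(121.47, abs=5e-2)
    assert res.ci_low <= res.odds_ratio <= res.ci_high


def test_katz_ci_symmetric_about_one_on_log_scale():
    res = odds_ratio_katz_ci(ContingencyTable2x2(1, 1, 1, 1))
    assert res.odds_ratio == pytest.approx(1.0)
    assert math.log(res.ci_low) == pytest.approx(-math.log(res.ci_high), rel=1e-9)


def test_katz_ci_zero_cell_undefined_unless_haldane():
    t = ContingencyTable2x2(10, 0, 5, 5)
    res = odds_ratio_katz_ci(t)
    assert math.isnan(res.odds_ratio) and not res.defined
    res_h = odds_ratio_katz_ci(t, haldane=True)
    assert res_h.defined and res_h.ci_low < res_h.odds_ratio < res_h.ci_high


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError, match="empty"):
        ContingencyTable2x2(0, 0, 0, 0)


def test_study_tables_disambiguation():
    """Only the 15-informative-other-domain table reproduces the published
    statistics; the prose's 16-variant count does not."""
    assert fisher_exact_two_sided(STUDY_TABLE) == pytest.approx(0.027, abs=5e-4)
    assert fisher_exact_two_sided(STUDY_TABLE_AS_WRITTEN) != pytest.approx(0.027, abs=5e-4)
    res = odds_ratio_katz_ci(STUDY_TABLE_AS_WRITTEN)
    assert res.odds_ratio != pytest.approx(12.67, abs=0.01)


def test_enrich_fixture(study_variants, arch):
    res = enrich(study_variants, "ATPase_motor_region", arch)
    assert res.table.cells == (19, 1, 9, 6)
    assert res.excluded_unknowns == 1  # the splice variant has no protein span
    assert res.p_two_sided == pytest.approx(0.0274, abs=5e-5)
    assert res.odds_ratio == pytest.approx(12.67, abs=5e-3)


def test_enrich_all_unknown_raises(study_variants, arch):
    from dataclasses import replace
    from chd4var.variant_model import PhenotypeAnnotation

    blanked = [replace(v, phenotype=PhenotypeAnnotation("unknown"))
               for v in study_variants]
    with pytest.raises(ValueError, match="empty table"):
        enrich(blanked, "ATPase_motor_region", arch)


def test_enrich_zero_margin_reported_undefined(arch):
    from dataclasses import replace
    from chd4var.variant_model import PhenotypeAnnotation

    def flagged(v, flag):
        return replace(v, phenotype=PhenotypeAnnotation(flag))

    from chd4var import load_study_fixture
    vs = [flagged(v, "yes") for v in load_study_fixture() if v.residue_span]
    res = enrich(vs, "ATPase_motor_region", arch)
    assert math.isnan(res.odds_ratio)
    assert any("margin" in n for n in res.notes)


def test_ci_coverage_at_study_cell_sizes():
    """Katz 95% interval covers the true OR in >= 90% of all-positive tables
    simulated at the study's group sizes and rates (20/15, 0.95/0.60)."""
    rng = np.random.default_rng(7)
    p1, p2 = 0.95, 0.60
    true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
    covered = usable = 0
    for _ in range(1000):
        a = rng.binomial(20, p1)
        c = rng.binomial(15, p2)
        t = ContingencyTable2x2(int(a), 20 - int(a), int(c), 15 - int(c))
        if 0 in t.cells:
            continue
        usable += 1
        res = odds_ratio_katz_ci(t)
        covered += res.ci_low <= true_or <= res.ci_high
    assert usable > 300
    assert covered / usable >= 0.90
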