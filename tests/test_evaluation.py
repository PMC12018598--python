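"""Diagnostic metrics, odds ratios, logistic fits, AUC, kappa, tests of
association."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from penrisk import (
    CIConvention,
    DegenerateDataError,
    GradingSystem,
    GroupedContingency,
    HistopathProfile,
    PatientRecord,
    PTStage,
    RiskGroup,
    SeparationError,
    TumorStaging,
    TwoByTwo,
    association_test,
    cohens_kappa,
    diagnostic_metrics,
    dichotomize,
    expand_fixture_to_records,
    fit_logistic,
    group_odds_ratios,
    odds_ratio_2x2,
    ordinal_auc,
    round_half_up,
    simulate_cohort,
    SimulationConfig,
)


def contingency(cells, system=GradingSystem.PROPOSED):
    return GroupedContingency(
        counts={g: c for g, c in zip((RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH), cells)},
        system=system,
    )


# ---------------------------------------------------------------------------
# dichotomization and diagnostic metrics


def test_dichotomize_fixture_cells(fixture):
    assert dichotomize(fixture.proposed) == TwoByTwo(tp=100, fn=2, fp=95, tn=109)
    assert dichotomize(fixture.eau) == TwoByTwo(tp=102, fn=0, fp=173, tn=31)
    assert dichotomize(contingency([(0, 0), (0, 0), (0, 0)])) == TwoByTwo(0, 0, 0, 0)


def test_dichotomize_margins_identity(fixture):
    table = dichotomize(fixture.proposed)
    assert table.tp + table.fn == fixture.proposed.n_pos
    assert table.tn + table.fp == fixture.proposed.n_neg


def test_metric_points_are_exact_ratios(fixture):
    m = diagnostic_metrics(dichotomize(fixture.proposed), CIConvention.COHORT_N, total_n=306)
    assert m.sensitivity.point == pytest.approx(100 / 102, abs=0)
    assert m.specificity.point == pytest.approx(109 / 204, abs=0)
    assert m.ppv.point == pytest.approx(100 / 195, abs=0)
    assert m.npv.point == pytest.approx(109 / 111, abs=0)


def test_wilson_interval_matches_statsmodels(fixture):
    from statsmodels.stats.proportion import proportion_confint

    m = diagnostic_metrics(dichotomize(fixture.proposed), CIConvention.WILSON)
    lo, hi = proportion_confint(100, 102, method="wilson")
    assert m.sensitivity.ci == pytest.approx((lo, hi), abs=1e-12)


def test_conventional_wald_width_shrinks_monotonically_with_n():
    widths = []
    for scale in (1, 4, 16, 64):
        table = TwoByTwo(tp=30 * scale, fn=10 * scale, fp=20 * scale, tn=40 * scale)
        m = diagnostic_metrics(table, CIConvention.CONVENTIONAL_WALD)
        widths.append(m.sensitivity.ci[1] - m.sensitivity.ci[0])
        assert m.sensitivity.point == pytest.approx(0.75)
    assert widths == sorted(widths, reverse=True)
    assert widths[-1] < widths[0] / 7  # ~ sqrt(64) shrinkage


def test_zero_denominator_metric_flagged_not_zero():
    m = diagnostic_metrics(TwoByTwo(tp=0, fn=0, fp=5, tn=5), CIConvention.CONVENTIONAL_WALD)
    assert not m.sensitivity.defined
    assert math.isnan(m.sensitivity.point)
    assert m.specificity.defined


# ---------------------------------------------------------------------------
# odds ratios


def test_odds_ratio_symmetric_null():
    est = odds_ratio_2x2((10, 10), (10, 10))
    assert est.point == pytest.approx(1.0)
    assert est.ci[0] < 1.0 < est.ci[1]


def test_odds_ratio_zero_numerator_cell_reports_unbounded_ci():
    est = odds_ratio_2x2((0, 31), (92, 128))  # EAU low vs high
    assert est.point == 0.0
    assert est.ci == (0.0, math.inf)
    assert "zero cell" in est.notes


def test_odds_ratio_haldane_correction_finite():
    est = odds_ratio_2x2((0, 31), (92, 128), haldane_correction=True)
    assert 0 < est.point < 1
    assert est.ci[1] < math.inf


def test_odds_ratio_degenerate_margin():
    with pytest.raises(DegenerateDataError):
        odds_ratio_2x2((0, 0), (5, 5))


def test_logistic_fit_equals_closed_form_on_pseudo_cohort(fixture, expanded_records):
    """One-factor saturated logistic: IRLS odds ratios equal the 2x2
    cross-product ratios to 1e-6 relative."""
    fit = fit_logistic(expanded_records)
    closed = group_odds_ratios(fixture.proposed)
    for group, term in ((RiskGroup.INTERMEDIATE, "risk_group[intermediate]"),
                        (RiskGroup.HIGH, "risk_group[high]")):
        assert fit[term].point == pytest.approx(closed[group].point, rel=1e-6)
        assert fit[term].ci == pytest.approx(closed[group].ci, rel=1e-4)


@settings(max_examples=20, deadline=None)
@given(
    cells=st.tuples(*[st.integers(1, 30) for _ in range(6)]),
    seed=st.integers(0, 2**16),
)
def test_logistic_closed_form_equivalence_property(cells, seed):
    """On any small 3-group cohort the saturated one-factor logistic
    reproduces the crude cross-product odds ratios."""
    from penrisk import StudyFixture, reference_fixture

    ct = contingency([(cells[0], cells[1]), (cells[2], cells[3]), (cells[4], cells[5])])
    base = reference_fixture()
    fx = StudyFixture(proposed=ct, eau=base.eau)
    records = expand_fixture_to_records(fx, seed=seed)
    fit = fit_logistic(records)
    closed = group_odds_ratios(ct)
    assert fit["risk_group[intermediate]"].point == pytest.approx(
        closed[RiskGroup.INTERMEDIATE].point, rel=1e-6)
    assert fit["risk_group[high]"].point == pytest.approx(closed[RiskGroup.HIGH].point, rel=1e-6)


def test_logistic_constant_outcome_degenerate():
    profile = HistopathProfile(1, 1, False, False)
    records = [
        PatientRecord(f"K{i}", TumorStaging(PTStage.pT2, None), profile, lnm=True) for i in range(6)
    ]
    with pytest.raises(DegenerateDataError):
        fit_logistic(records)


def test_logistic_perfect_separation_reported():
    low = HistopathProfile(1, 1, False, False)
    high = HistopathProfile(4, 3, True, True)
    records = [
        PatientRecord(f"S{i}", TumorStaging(PTStage.pT2, None), low if i < 6 else high, lnm=i >= 6)
        for i in range(12)
    ]
    with pytest.raises((SeparationError, RuntimeError)):
        fit_logistic(records)


def test_logistic_parameter_recovery_on_synthetic_cohort():
    """Score-model fit on a simulated cohort (n=5000) recovers the
    generating (beta0, beta1) within 3 standard errors."""
    cfg = SimulationConfig(n_patients=5000, beta0=-3.0, beta1=1.4, seed=20240901)
    fit = fit_logistic(simulate_cohort(cfg), predictor="score")
    z = stats.norm.ppf(0.975)
    for term, truth in (("const", cfg.beta0), ("score", cfg.beta1)):
        beta = math.log(fit[term].point)
        se = (math.log(fit[term].ci[1]) - math.log(fit[term].ci[0])) / (2 * z)
        assert abs(beta - truth) < 3 * se


# ---------------------------------------------------------------------------
# ordinal AUC


def test_auc_fixture_values_match_tie_corrected_fractions(fixture):
    # exact Mann-Whitney fractions derived from the contingency cells
    assert ordinal_auc(fixture.proposed).point == pytest.approx(17846.5 / 20808, abs=1e-12)
    assert ordinal_auc(fixture.eau).point == pytest.approx(13415 / 20808, abs=1e-12)


def test_auc_matches_sklearn_on_expanded_labels(fixture):
    """Independent oracle: sklearn ROC AUC over per-patient ordinal labels."""
    from sklearn.metrics import roc_auc_score

    for ct in (fixture.proposed, fixture.eau):
        y, x = [], []
        for level, group in enumerate((RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH)):
            pos, neg = ct.cells(group)
            y += [1] * pos + [0] * neg
            x += [level] * (pos + neg)
        assert ordinal_auc(ct).point == pytest.approx(roc_auc_score(y, x), abs=1e-12)


def test_auc_perfect_separation_and_degenerate_cases():
    assert ordinal_auc(contingency([(0, 10), (0, 0), (10, 0)])).point == 1.0
    # all patients in one group: pure ties, no discrimination
    assert ordinal_auc(contingency([(0, 0), (17, 23), (0, 0)])).point == 0.5
    with pytest.raises(DegenerateDataError):
        ordinal_auc(contingency([(0, 5), (0, 5), (0, 5)]))


@settings(max_examples=30, deadline=None)
@given(cells=st.tuples(*[st.integers(0, 40) for _ in range(6)]))
def test_auc_depends_only_on_group_order(cells):
    """AUC is a rank statistic: any strictly monotone relabeling of the
    ordinal group values leaves it unchanged (oracle: sklearn on labels)."""
    from sklearn.metrics import roc_auc_score

    ct = contingency([(cells[0], cells[1]), (cells[2], cells[3]), (cells[4], cells[5])])
    if ct.n_pos == 0 or ct.n_neg == 0:
        return
    for relabel in ([0, 1, 2], [0, 10, 11], [-5, 0, 100]):
        y, x = [], []
        for value, group in zip(relabel, (RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH)):
            pos, neg = ct.cells(group)
            y += [1] * pos + [0] * neg
            x += [value] * (pos + neg)
        assert ordinal_auc(ct).point == pytest.approx(roc_auc_score(y, x), abs=1e-12)


def test_auc_hanley_mcneil_ci_ordering(fixture):
    est = ordinal_auc(fixture.proposed)
    assert 0 < est.ci[0] < est.point < est.ci[1] <= 1


# ---------------------------------------------------------------------------
# kappa


def test_kappa_identity_and_hand_computed_table():
    assert cohens_kappa(list("abcabc"), list("abcabc")).point == pytest.approx(1.0)
    # hand-computed 3x3 cross-table:
    #   [[20, 5, 0], [10, 30, 5], [0, 5, 25]], n = 100
    #   p_o = 0.75; p_e = (25*30 + 45*40 + 30*30)/100^2 = 0.345
    #   kappa = (0.75 - 0.345)/(1 - 0.345) = 0.405/0.655
    a, b = [], []
    table = [[20, 5, 0], [10, 30, 5], [0, 5, 25]]
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            a += [i] * count
            b += [j] * count
    assert cohens_kappa(a, b).point == pytest.approx(0.405 / 0.655, abs=1e-10)


def test_kappa_matches_sklearn_oracle():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(42)
    a = rng.integers(0, 3, 500).tolist()
    b = rng.integers(0, 3, 500).tolist()
    ours = cohens_kappa(a, b).point
    assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
    assert abs(ours) < 0.1  # independent labelings agree only by chance


def test_kappa_undefined_when_both_raters_constant_and_equal():
    est = cohens_kappa(["x"] * 5, ["x"] * 5)
    assert math.isnan(est.point)
    assert "undefined" in est.notes


def test_kappa_length_mismatch():
    with pytest.raises(ValueError):
        cohens_kappa([1, 2], [1])


# ---------------------------------------------------------------------------
# association tests


def test_association_fixture_strongly_significant(fixture):
    est = association_test(fixture.proposed)
    assert est.p_value < 0.001
    assert est.kind.value == "chi2"


def test_association_identical_rows_null():
    est = association_test(contingency([(10, 20), (20, 40), (5, 10)]))
    assert est.point == pytest.approx(0.0, abs=1e-12)
    assert est.p_value == pytest.approx(1.0)


def test_fisher_fallback_matches_hypergeometric_enumeration():
    """Small 2x2 (3/1 vs 1/3): exact p equals the brute-force sum over the
    hypergeometric outcome distribution."""
    ct = contingency([(3, 1), (1, 3), (0, 0)])
    est = association_test(ct)
    assert "exact" in est.notes.lower()
    # enumeration oracle: margins rows (4,4), first column total 4
    pmf = [stats.hypergeom.pmf(a, 8, 4, 4) for a in range(5)]
    p_obs = pmf[3]
    expected = sum(p for p in pmf if p <= p_obs + 1e-12)
    assert est.p_value == pytest.approx(expected, abs=1e-12)
    assert est.p_value == pytest.approx(34 / 70, abs=1e-12)


def test_freeman_halton_matches_independent_oracles():
    """3x2 exact test by exhaustive enumeration vs two independent
    oracles: an in-test multivariate-hypergeometric enumeration coded with
    binomial coefficients, and scipy's R x C fisher_exact (Monte Carlo,
    seeded, compared at resampling accuracy)."""
    from math import comb

    table = [(3, 1), (2, 4), (1, 5)]
    est = association_test(contingency(table))
    assert "Freeman-Halton" in est.notes

    rows = [sum(r) for r in table]
    c1 = sum(r[0] for r in table)
    n = sum(rows)
    denom = comb(n, c1)

    def prob(firsts):
        num = 1
        for r, a in zip(rows, firsts):
            num *= comb(r, a)
        return num / denom

    p_obs = prob([r[0] for r in table])
    exact = sum(
        prob((a, b, c1 - a - b))
        for a in range(rows[0] + 1)
        for b in range(rows[1] + 1)
        if 0 <= c1 - a - b <= rows[2] and prob((a, b, c1 - a - b)) <= p_obs * (1 + 1e-9)
    )
    assert est.p_value == pytest.approx(exact, abs=1e-12)

    mc = stats.fisher_exact(
        np.array(table), method=stats.MonteCarloMethod(rng=np.random.default_rng(0))
    ).pvalue
    assert est.p_value == pytest.approx(mc, abs=0.02)  # ~4 MC standard errors


def test_association_drops_empty_group_and_strict_errors(caplog):
    ct = contingency([(30, 40), (25, 15), (0, 0)])
    with caplog.at_level("WARNING"):
        est = association_test(ct)
    assert est.p_value is not None
    with pytest.raises(DegenerateDataError):
        association_test(ct, strict=True)


# ---------------------------------------------------------------------------
# crosstab conservation property (grading + aggregation + dichotomization)


@settings(max_examples=25, deadline=None)
@given(data=st.data())
def test_pipeline_conservation_property(data):
    """Cell conservation holds for arbitrary simulated cohorts under both
    classifiers."""
    from penrisk import crosstab

    n = data.draw(st.integers(5, 60))
    seed = data.draw(st.integers(0, 2**20))
    records = simulate_cohort(SimulationConfig(n_patients=n, seed=seed))
    for system in (GradingSystem.PROPOSED, GradingSystem.EAU):
        ct = crosstab(records, system)
        assert ct.total == n
        table = dichotomize(ct)
        assert table.tp + table.fn == ct.n_pos
        assert table.tn + table.fp == ct.n_neg


def test_round_half_up():
    assert round_half_up(177.125, 2) == 177.13
    assert round_half_up(0.855, 2) == 0.86
    assert round_half_up(-1.005, 2) == -1.01
    assert round_half_up(0.6447, 2) == 0.64
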