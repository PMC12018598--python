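"""Diagnostic evaluation of a three-level risk grading against a binary
outcome (inguinal lymph node metastasis).

Implements the full evaluation pipeline applied to the grading systems:

* dichotomization of the 3x2 grouped contingency (test-positive =
  intermediate + high risk) and the four diagnostic proportions with
  Wald or Wilson confidence intervals;
* crude odds ratios from 2x2 tables (cross-product ratio with Woolf
  log-scale Wald CI) and logistic-regression odds ratios (statsmodels,
  Newton/IRLS) with optional covariate adjustment;
* ordinal ROC AUC via the tie-corrected Mann-Whitney statistic with a
  Hanley-McNeil confidence interval;
* unweighted Cohen's kappa for agreement between two graders/systems;
* chi-square / exact tests of association between risk group and outcome.

CI conventions for the diagnostic proportions
---------------------------------------------
``conventional_wald`` uses each metric's own denominator in the variance
(the textbook Wald interval); ``wilson`` is the Wilson score interval.
``cohort_n`` uses the full cohort size as variance denominator for all
four metrics — a nonstandard convention, provided because it is the one
under which the published intervals of the reference study are reproduced
exactly. Reports always label the convention used.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GroupedContingency, PatientRecord, to_dataframe, classify_record
from .grading import GradingSystem, RiskGroup, RISK_ORDER

logger = logging.getLogger(__name__)

#: 97.5% normal quantile used for every 95% interval.
Z95 = float(stats.norm.ppf(0.975))


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on this input."""


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect separation)."""


class CIConvention(str, enum.Enum):
    COHORT_N = "cohort_n"
    CONVENTIONAL_WALD = "conventional_wald"
    WILSON = "wilson"


class EffectKind(str, enum.Enum):
    ODDS_RATIO = "odds_ratio"
    AUC = "auc"
    KAPPA = "kappa"
    CHI2 = "chi2"
    FISHER_P = "fisher_p"


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with optional 95% CI and provenance notes."""

    kind: EffectKind
    point: float
    ci: Optional[Tuple[float, float]] = None
    p_value: Optional[float] = None
    reference_level: Optional[str] = None
    notes: str = ""


@dataclass(frozen=True)
class MetricEstimate:
    """One diagnostic proportion: point value in [0, 1] with a clipped
    95% CI; ``defined`` is False when the denominator is zero."""

    point: float
    ci: Tuple[float, float]
    defined: bool = True

    def as_percent(self) -> Tuple[float, float, float]:
        return self.point * 100.0, self.ci[0] * 100.0, self.ci[1] * 100.0


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    ci_convention: CIConvention
    n: int


@dataclass(frozen=True)
class TwoByTwo:
    """Dichotomized test-vs-disease table. Test-positive = intermediate or
    high risk; disease = LNM."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def dichotomize(contingency: GroupedContingency) -> TwoByTwo:
    """Collapse the 3-level contingency: low risk is test-negative,
    intermediate + high are test-positive."""
    lo_pos, lo_neg = contingency.cells(RiskGroup.LOW)
    int_pos, int_neg = contingency.cells(RiskGroup.INTERMEDIATE)
    hi_pos, hi_neg = contingency.cells(RiskGroup.HIGH)
    return TwoByTwo(tp=int_pos + hi_pos, fn=lo_pos, fp=int_neg + hi_neg, tn=lo_neg)


def _proportion_ci(k: int, n: int, convention: CIConvention, n_eff: int) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(point=math.nan, ci=(math.nan, math.nan), defined=False)
    p = k / n
    if convention is CIConvention.WILSON:
        # statsmodels' proportion_confint implements the same formula; kept
        # inline to avoid a hard dependency in this hot path
        denom = 1 + Z95**2 / n
        center = (p + Z95**2 / (2 * n)) / denom
        half = Z95 * math.sqrt(p * (1 - p) / n + Z95**2 / (4 * n**2)) / denom
        lo, hi = center - half, center + half
    else:
        m = n_eff if convention is CIConvention.COHORT_N else n
        half = Z95 * math.sqrt(p * (1 - p) / m)
        lo, hi = p - half, p + half
    return MetricEstimate(point=p, ci=(max(lo, 0.0), min(hi, 1.0)))


def diagnostic_metrics(
    table: TwoByTwo,
    ci_convention: Union[CIConvention, str] = CIConvention.COHORT_N,
    total_n: Optional[int] = None,
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV with 95% CIs.

    ``total_n`` (the full cohort size) is required under the ``cohort_n``
    convention, where it replaces each metric's own denominator in the
    Wald variance. A metric with a zero denominator is returned undefined
    (NaN, ``defined=False``) rather than silently zero.
    """
    convention = CIConvention(ci_convention)
    if convention is CIConvention.COHORT_N:
        if total_n is None:
            total_n = table.total
        if total_n <= 0:
            raise DegenerateDataError("cohort_n convention requires a positive total_n")
    n_eff = total_n or 0
    return DiagnosticMetrics(
        sensitivity=_proportion_ci(table.tp, table.tp + table.fn, convention, n_eff),
        specificity=_proportion_ci(table.tn, table.tn + table.fp, convention, n_eff),
        ppv=_proportion_ci(table.tp, table.tp + table.fp, convention, n_eff),
        npv=_proportion_ci(table.tn, table.tn + table.fn, convention, n_eff),
        ci_convention=convention,
        n=table.total,
    )


# ---------------------------------------------------------------------------
# odds ratios


def odds_ratio_2x2(
    exposed: Tuple[int, int],
    reference: Tuple[int, int],
    haldane_correction: bool = False,
) -> EffectEstimate:
    """Crude odds ratio of outcome for ``exposed`` vs ``reference`` groups,
    each given as ``(outcome_pos, outcome_neg)`` counts.

    OR = (a*d)/(b*c) with the Woolf log-scale Wald CI
    ``exp(ln OR +/- z*sqrt(1/a + 1/b + 1/c + 1/d))``. A zero cell in the
    numerator yields OR 0 with an unbounded CI ``(0, inf)``; with
    ``haldane_correction`` 0.5 is added to every cell instead.
    """
    a, b = exposed
    c, d = reference
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if (a + b) == 0 or (c + d) == 0:
        raise DegenerateDataError("a group with zero total has no defined odds")
    if haldane_correction and 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    if 0 in (a, d) and not haldane_correction:
        note = "zero cell: OR degenerate, CI unbounded"
        point = 0.0 if a == 0 else math.inf
        return EffectEstimate(kind=EffectKind.ODDS_RATIO, point=point, ci=(0.0, math.inf), notes=note)
    if 0 in (b, c) and not haldane_correction:
        return EffectEstimate(
            kind=EffectKind.ODDS_RATIO, point=math.inf, ci=(0.0, math.inf), notes="zero cell: OR infinite"
        )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - Z95 * se), math.exp(math.log(or_) + Z95 * se)
    return EffectEstimate(kind=EffectKind.ODDS_RATIO, point=or_, ci=(lo, hi))


def group_odds_ratios(contingency: GroupedContingency) -> Dict[RiskGroup, EffectEstimate]:
    """Crude per-group odds ratios versus the low risk group."""
    ref = contingency.cells(RiskGroup.LOW)
    out = {}
    for g in (RiskGroup.INTERMEDIATE, RiskGroup.HIGH):
        est = odds_ratio_2x2(contingency.cells(g), ref)
        out[g] = EffectEstimate(
            kind=est.kind, point=est.point, ci=est.ci, reference_level=RiskGroup.LOW.value, notes=est.notes
        )
    return out


def fit_logistic(
    records: Sequence[PatientRecord],
    system: GradingSystem = GradingSystem.PROPOSED,
    covariates: Sequence[str] = (),
    predictor: str = "risk_group",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> Dict[str, EffectEstimate]:
    """Logistic regression of LNM on risk group (or raw score), optionally
    adjusted.

    Maximum-likelihood fit by Newton-Raphson / IRLS (statsmodels ``Logit``),
    zero-initialized, converged when the relative log-likelihood change
    falls below ``tol`` (at most ``max_iter`` iterations). With the default
    ``predictor="risk_group"`` the group is reference-coded against low
    risk; ``predictor="score"`` fits the total point score as a linear term
    (the dose-response model; proposed system only). ``covariates`` may
    include ``"pt_stage"`` (reference pT1) and ``"age"`` (linear, per
    year).

    Returns exponentiated coefficients (odds ratios) with Wald CIs, keyed
    by term. Perfect separation raises :class:`SeparationError`; a constant
    outcome raises :class:`DegenerateDataError`. Quasi-separation (an
    essentially infinite coefficient) is flagged in the estimate's notes
    rather than silently reported as converged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning
    import warnings

    usable = [r for r in records if r.lnm is not None]
    if not usable:
        raise DegenerateDataError("no records with an LNM outcome")
    y = np.array([1.0 if r.lnm else 0.0 for r in usable])
    if y.min() == y.max():
        raise DegenerateDataError("outcome is constant; logistic model degenerate")

    df = to_dataframe(usable)
    df["risk_group"] = [classify_record(r, system).value for r in usable]
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    terms: List[str] = []
    if predictor == "risk_group":
        for level in (RiskGroup.INTERMEDIATE, RiskGroup.HIGH):
            name = f"risk_group[{level.value}]"
            X[name] = (df["risk_group"] == level.value).astype(float)
            terms.append(name)
    elif predictor == "score":
        if system is not GradingSystem.PROPOSED:
            raise ValueError("the point score exists only in the proposed system")
        from .grading import score_profile

        X["score"] = [float(score_profile(r.profile)) for r in usable]
        terms.extend(["const", "score"])  # const reported: baseline odds at score 0
    else:
        raise ValueError(f"unsupported predictor {predictor!r}")
    for cov in covariates:
        if cov == "pt_stage":
            for stage in sorted(set(df["pt_stage"]) - {"pT1"}):
                name = f"pt_stage[{stage}]"
                X[name] = (df["pt_stage"] == stage).astype(float)
                terms.append(name)
        elif cov == "age":
            if df["age"].isna().any():
                raise DegenerateDataError("age adjustment requested but age missing for some records")
            X["age"] = df["age"].astype(float)
            terms.append("age")
        else:
            raise ValueError(f"unsupported covariate {cov!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            model = sm.Logit(y, X)
            result = model.fit(
                method="newton", start_params=np.zeros(X.shape[1]), maxiter=max_iter, tol=tol, disp=False
            )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation detected: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(final log-likelihood {result.llf:.6g})"
        )

    params, bse = result.params, result.bse
    out: Dict[str, EffectEstimate] = {}
    for term in terms:
        beta, se = float(params[term]), float(bse[term])
        note = ""
        if abs(beta) > 15 or se > 100:  # log-odds this size signal quasi-separation
            note = "quasi-separation: coefficient effectively unbounded"
        out[term] = EffectEstimate(
            kind=EffectKind.ODDS_RATIO,
            point=math.exp(beta),
            ci=(math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
            reference_level="low" if term.startswith("risk_group") else None,
            notes=note,
        )
    return out


# ---------------------------------------------------------------------------
# ordinal ROC / AUC


def ordinal_auc(contingency: GroupedContingency) -> EffectEstimate:
    """AUC of the 3-level risk group as an ordinal marker for LNM.

    Tie-corrected Mann-Whitney statistic over the ordering
    low < intermediate < high::

        AUC = [#(case > control) + 0.5 * #(ties)] / (n_pos * n_neg)

    which equals the trapezoidal area under the empirical ROC curve of the
    three-level score. The 95% CI is Hanley-McNeil, clipped to [0, 1].
    """
    cases = [contingency.cells(g)[0] for g in RISK_ORDER]
    controls = [contingency.cells(g)[1] for g in RISK_ORDER]
    n_pos, n_neg = sum(cases), sum(controls)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC requires at least one case and one control")
    greater = sum(cases[i] * controls[j] for i in range(3) for j in range(3) if i > j)
    ties = sum(cases[i] * controls[i] for i in range(3))
    auc = (greater + 0.5 * ties) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    half = Z95 * math.sqrt(max(var, 0.0))
    return EffectEstimate(
        kind=EffectKind.AUC,
        point=auc,
        ci=(max(auc - half, 0.0), min(auc + half, 1.0)),
        notes="Hanley-McNeil CI",
    )


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> EffectEstimate:
    """Unweighted Cohen's kappa between two labelings of the same records:
    ``(p_o - p_e) / (1 - p_e)`` with observed agreement p_o and chance
    agreement p_e from the marginal label distributions."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise DegenerateDataError("kappa undefined on empty input")
    cats = sorted(set(labels_a) | set(labels_b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(labels_a, labels_b):
        table[idx[a], idx[b]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0 - 1e-15:
        return EffectEstimate(
            kind=EffectKind.KAPPA, point=math.nan, notes="undefined: both raters constant and equal (p_e = 1)"
        )
    return EffectEstimate(kind=EffectKind.KAPPA, point=(p_o - p_e) / (1 - p_e))


# ---------------------------------------------------------------------------
# association tests


def _freeman_halton_rx2(table: np.ndarray) -> float:
    """Exact p-value for an r x 2 table by exhaustive enumeration of all
    tables with the observed margins (generalized Fisher test). Feasible at
    desk scale (small r, moderate counts)."""
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    log_fact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))

    def log_prob(first_col: Tuple[int, ...]) -> float:
        lp = sum(log_fact[r] for r in rows) + log_fact[c1] + log_fact[n - c1] - log_fact[n]
        for r, a in zip(rows, first_col):
            lp -= log_fact[a] + log_fact[r - a]
        return lp

    observed_lp = log_prob(tuple(int(x) for x in table[:, 0]))
    ranges = [range(0, int(r) + 1) for r in rows]
    p = 0.0
    for combo in itertools.product(*ranges):
        if sum(combo) != c1:
            continue
        lp = log_prob(combo)
        if lp <= observed_lp + 1e-10:
            p += math.exp(lp)
    return min(p, 1.0)


def association_test(
    contingency: GroupedContingency,
    min_expected: float = 5.0,
    strict: bool = False,
) -> EffectEstimate:
    """Test of association between risk group and LNM status.

    Pearson chi-square without continuity correction on the r x 2 table;
    automatic fallback to an exact test (Fisher for 2 x 2, exhaustive
    Freeman-Halton for r x 2) when any expected cell is below
    ``min_expected``. Empty rows are dropped with a warning (error in
    strict mode)."""
    table = contingency.as_table()
    keep = table.sum(axis=1) > 0
    if not keep.all():
        dropped = [g.value for g, k in zip(RISK_ORDER, keep) if not k]
        if strict:
            raise DegenerateDataError(f"empty risk group(s): {', '.join(dropped)}")
        logger.warning("dropping empty risk group(s): %s", ", ".join(dropped))
        table = table[keep]
    if table.shape[0] < 2 or (table.sum(axis=0) > 0).sum() < 2:
        raise DegenerateDataError("association test needs at least 2 nonempty rows and columns")

    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < min_expected).any():
        if table.shape[0] == 2:
            p = float(stats.fisher_exact(table)[1])
            note = "Fisher's exact (2x2)"
        else:
            p = _freeman_halton_rx2(table)
            note = "Freeman-Halton exact (enumeration)"
        return EffectEstimate(kind=EffectKind.FISHER_P, point=p, p_value=p, notes=note)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return EffectEstimate(
        kind=EffectKind.CHI2, point=float(chi2), p_value=float(p), notes=f"Pearson chi-square, dof={dof}"
    )


# ---------------------------------------------------------------------------
# presentation helpers


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (the convention of the published tables;
    float round() is round-half-even)."""
    from decimal import Decimal, ROUND_HALF_UP

    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))
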