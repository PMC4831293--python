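"""Dose-response meta-analysis of categorical parity data.

Each category is assigned a scalar dose (number of live births): the
reference is 0, a single-value range is itself, a bounded range takes its
midpoint, and an open-ended top range extends the width of the adjacent
bounded range. Within each study the category log relative risks are
regressed on dose through the origin (the reference anchors zero) by
generalized least squares, under a selectable covariance model for the
shared-reference correlation. Study slopes are then pooled across studies;
curvature is modelled by a restricted cubic spline with three knots and
tested against the linear model with a likelihood-ratio statistic on one
degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ExposureCategory, StudyReport
from .effects import Z95, LogEffect, log_effect_from_ci
from .exceptions import (
    DomainError,
    InsufficientDataError,
    NoDataError,
    SingularDesignError,
)
from .pooling import PooledResult, pool_auto
from .pseudocounts import gl_pseudocounts, hamling_pseudocounts, shared_variance

__all__ = [
    "DoseAssignment",
    "TrendResult",
    "assign_doses",
    "reconstruct_covariance",
    "study_linear_trend",
    "pooled_linear_trend",
    "rcs_basis",
    "pooled_knots",
    "nonlinearity_test",
    "dose_response_analysis",
    "trend_table",
    "spline_curve",
]

log = logging.getLogger(__name__)

CovMethod = Literal["independent", "gl_counts", "hamling"]
DoseRule = Literal["reference_zero", "single_value", "midpoint", "open_ended"]


@dataclass(frozen=True)
class DoseAssignment:
    """Assigned doses for one report's categories, in printed order."""

    doses: tuple[float, ...]
    rules: tuple[DoseRule, ...]

    def nonreference(self, report: StudyReport) -> np.ndarray:
        return np.array(
            [d for d, c in zip(self.doses, report.categories) if not c.is_reference]
        )


def assign_doses(report: StudyReport) -> DoseAssignment:
    """Assign a scalar dose to every category of a validated report.

    Open-ended top ranges get ``lower + w/2`` where ``w`` is the width
    (upper - lower) of the adjacent bounded range below; when that neighbour
    is a single value (width 0) or absent, a width of one live birth is
    assumed and a warning logged.
    """
    doses: list[float] = []
    rules: list[DoseRule] = []
    prev_width: float | None = None
    for cat in report.categories:
        if cat.is_reference:
            doses.append(0.0)
            rules.append("reference_zero")
        elif cat.upper is None:
            width = prev_width if prev_width else 1.0
            if prev_width is None:
                log.warning(
                    "%s: open-ended category %r has no bounded neighbour; "
                    "assuming width 1",
                    report.report_id, cat.label,
                )
            doses.append(cat.lower + width / 2.0)
            rules.append("open_ended")
        elif cat.lower == cat.upper:
            doses.append(float(cat.lower))
            rules.append("single_value")
            prev_width = 0.0
        else:
            doses.append((cat.lower + cat.upper) / 2.0)
            rules.append("midpoint")
            prev_width = float(cat.upper - cat.lower)
    if np.any(np.diff(doses) <= 0):
        raise DomainError(f"{report.report_id}: assigned doses are not strictly increasing")
    return DoseAssignment(tuple(doses), tuple(rules))


def _category_effects(report: StudyReport) -> tuple[np.ndarray, np.ndarray]:
    cats = report.exposure_categories
    if not cats:
        raise NoDataError(f"{report.report_id}: no non-reference categories")
    effs = [
        log_effect_from_ci(c.rr, c.lcl, c.ucl, report.report_id, c.label) for c in cats
    ]
    return np.array([e.y for e in effs]), np.array([e.se for e in effs]) ** 2


def reconstruct_covariance(
    report: StudyReport,
    doses: DoseAssignment | None = None,
    method: CovMethod = "independent",
) -> np.ndarray:
    """Covariance matrix of the report's non-reference category log-RRs.

    ``independent`` is the diagonal of the printed variances. ``gl_counts``
    fits Greenland-Longnecker pseudo-counts from the per-category
    denominators (which must be present); ``hamling`` solves the pseudo-count
    system from the effect sizes, CIs and report totals. Both correlated
    methods fill the off-diagonal with the shared-reference variance
    component of the fitted table.
    """
    y, var = _category_effects(report)
    if method == "independent":
        return np.diag(var)
    if method == "hamling":
        table = hamling_pseudocounts(report, y, var)
        v0 = min(table.v0, 0.999 * float(var.min()))
        return _filled(var, v0)
    if method == "gl_counts":
        cats = report.exposure_categories
        ref = report.reference
        if any(c.n_noncases_or_persontime is None for c in cats) or (
            ref.n_noncases_or_persontime is None
        ):
            raise NoDataError(
                f"{report.report_id}: gl_counts needs per-category denominators"
            )
        # odds model margins are category totals (cases + noncases); the rate
        # model uses person-time directly
        if report.design == "case_control":
            if any(c.n_cases is None for c in cats) or ref.n_cases is None:
                raise NoDataError(
                    f"{report.report_id}: gl_counts needs per-category case counts"
                )
            denoms = np.array(
                [c.n_cases + c.n_noncases_or_persontime for c in cats], dtype=float
            )
            ref_denom = float(ref.n_cases + ref.n_noncases_or_persontime)
        else:
            denoms = np.array([c.n_noncases_or_persontime for c in cats], dtype=float)
            ref_denom = float(ref.n_noncases_or_persontime)
        total = report.total_cases
        if all(c.n_cases is not None for c in cats) and ref.n_cases is not None:
            total = ref.n_cases + sum(c.n_cases for c in cats)
        table = gl_pseudocounts(report, y, denoms, ref_denom, total_cases=total)
        v0 = min(table.v0, 0.999 * float(var.min()))
        return _filled(var, v0)
    raise ValueError(f"unknown covariance method {method!r}")


def _filled(var: np.ndarray, v0: float) -> np.ndarray:
    c = np.full((var.size, var.size), v0)
    np.fill_diagonal(c, var)
    return c


def study_linear_trend(
    report: StudyReport,
    doses: DoseAssignment | None = None,
    cov: np.ndarray | None = None,
) -> tuple[float, float]:
    """GLS slope of log-RR on dose through the origin for one report.

    Returns ``(slope, se_slope)`` in log-RR per live birth. The reference
    category enters as the origin; only non-reference categories carry data.
    """
    doses = doses or assign_doses(report)
    y, var = _category_effects(report)
    x = doses.nonreference(report)
    c = np.diag(var) if cov is None else np.asarray(cov, dtype=float)
    try:
        ci = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"{report.report_id}: singular covariance") from exc
    xtcx = float(x @ ci @ x)
    if xtcx <= 0:
        raise SingularDesignError(f"{report.report_id}: degenerate dose design")
    slope = float(x @ ci @ y) / xtcx
    return slope, xtcx ** -0.5


@dataclass
class TrendResult:
    """Per-study and pooled dose-response results."""

    per_study: list[tuple[str, float, float]]          # (report_id, slope, se)
    pooled: PooledResult
    knots: tuple[float, float, float] | None = None
    spline_coefs: tuple[float, float] | None = None    # pooled (b1, b2)
    spline_cov: np.ndarray | None = None
    lr_stat: float | None = None
    p_nonlinear: float | None = None
    p_wald_nonlinear: float | None = None

    @property
    def pooled_slope(self) -> float:
        return self.pooled.y_pooled

    @property
    def rr_per_birth(self) -> float:
        return self.pooled.rr

    @property
    def ci95(self) -> tuple[float, float]:
        return self.pooled.ci95

    @property
    def p_linear(self) -> float:
        return self.pooled.p_value


def _eligible(reports: Sequence[StudyReport]) -> list[StudyReport]:
    return [r for r in reports if r.exposure_categories]


def _covariance_or_fallback(
    report: StudyReport, doses: DoseAssignment, method: CovMethod
) -> np.ndarray:
    """Per-study covariance; independence fallback when reconstruction fails."""
    from .exceptions import ConvergenceError

    try:
        return reconstruct_covariance(report, doses, method)
    except ConvergenceError as exc:
        log.warning(
            "%s: %s covariance reconstruction failed (%s); using independence",
            report.report_id, method, exc,
        )
        return reconstruct_covariance(report, doses, "independent")


def pooled_linear_trend(
    reports: Sequence[StudyReport],
    cov_method: CovMethod = "independent",
    model: Literal["auto", "fixed", "random"] = "auto",
) -> TrendResult:
    """Two-stage linear trend: per-study GLS slopes pooled across studies."""
    from .pooling import pool_fixed, pool_random_dl

    eligible = _eligible(reports)
    if len(eligible) < 2:
        raise InsufficientDataError("pooled trend needs at least 2 reports with categories")
    per_study = []
    effects = []
    for report in eligible:
        doses = assign_doses(report)
        cov = _covariance_or_fallback(report, doses, cov_method)
        slope, se = study_linear_trend(report, doses, cov)
        per_study.append((report.report_id, slope, se))
        effects.append(LogEffect(slope, se, report.report_id, "per-birth slope"))
    pooler = {"auto": pool_auto, "fixed": pool_fixed, "random": pool_random_dl}[model]
    return TrendResult(per_study=per_study, pooled=pooler(effects))


def rcs_basis(
    dose: float | np.ndarray, knots: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis (Harrell normalization) for 3 knots.

    Returns ``(b1, b2)`` where ``b1`` is the dose itself and ``b2`` the
    single nonlinear term, linear outside the boundary knots.
    """
    k1, k2, k3 = knots
    if not k1 < k2 < k3:
        raise DomainError(f"knots must be strictly increasing, got {knots}")
    d = np.asarray(dose, dtype=float)

    def cube(x):
        return np.maximum(x, 0.0) ** 3

    b2 = (
        cube(d - k1)
        - cube(d - k2) * (k3 - k1) / (k3 - k2)
        + cube(d - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return d, b2


def pooled_knots(
    reports: Sequence[StudyReport],
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
) -> tuple[float, float, float]:
    """Knots at percentiles of the pooled non-reference dose distribution.

    The distribution is the unweighted multiset of assigned doses across all
    studies; percentiles interpolate linearly between order statistics.
    """
    doses = np.concatenate(
        [assign_doses(r).nonreference(r) for r in _eligible(reports)]
    )
    k1, k2, k3 = np.percentile(doses, percentiles)
    if not k1 < k2 < k3:
        raise DomainError(f"degenerate dose distribution: knots {k1, k2, k3}")
    return float(k1), float(k2), float(k3)


def nonlinearity_test(
    reports: Sequence[StudyReport],
    knots: tuple[float, float, float] | None = None,
    cov_method: CovMethod = "independent",
) -> TrendResult:
    """Spline-vs-linear likelihood-ratio test with pooled spline coefficients.

    Both models are fitted to the same category-level data and covariance
    structure by GLS with coefficients common across studies (fixed-effect
    multivariate pooling of the per-study moment matrices). The
    likelihood-ratio statistic is the drop in the GLS deviance from adding
    the nonlinear spline term, referred to chi-square on 1 df; the Wald test
    on the pooled nonlinear coefficient is reported as a cross-check.
    """
    eligible = _eligible(reports)
    knots = knots or pooled_knots(eligible)
    all_doses = np.concatenate([assign_doses(r).nonreference(r) for r in eligible])
    if np.unique(all_doses).size < 3:
        raise InsufficientDataError(
            "nonlinearity test needs at least 3 distinct dose values"
        )

    xtx2 = np.zeros((2, 2))
    xty2 = np.zeros(2)
    xtx1 = 0.0
    xty1 = 0.0
    ycy = 0.0
    for report in eligible:
        doses = assign_doses(report)
        x = doses.nonreference(report)
        y, _var = _category_effects(report)
        c = _covariance_or_fallback(report, doses, cov_method)
        ci = np.linalg.inv(c)
        b1, b2 = rcs_basis(x, knots)
        design = np.column_stack([b1, b2])
        xtx2 += design.T @ ci @ design
        xty2 += design.T @ ci @ y
        xtx1 += float(x @ ci @ x)
        xty1 += float(x @ ci @ y)
        ycy += float(y @ ci @ y)

    coef2 = np.linalg.solve(xtx2, xty2)
    dev_spline = ycy - float(coef2 @ xty2)
    coef1 = xty1 / xtx1
    dev_linear = ycy - coef1 * xty1
    lr = max(0.0, dev_linear - dev_spline)
    p_nl = float(stats.chi2.sf(lr, 1))
    cov2 = np.linalg.inv(xtx2)
    wald_z = coef2[1] / np.sqrt(cov2[1, 1])
    p_wald = float(2 * stats.norm.sf(abs(wald_z)))

    trend = pooled_linear_trend(eligible, cov_method=cov_method)
    trend.knots = knots
    trend.spline_coefs = (float(coef2[0]), float(coef2[1]))
    trend.spline_cov = cov2
    trend.lr_stat = float(lr)
    trend.p_nonlinear = p_nl
    trend.p_wald_nonlinear = p_wald
    return trend


def dose_response_analysis(
    reports: Sequence[StudyReport],
    cov_method: CovMethod = "independent",
    knots: tuple[float, float, float] | None = None,
) -> TrendResult:
    """Complete dose-response analysis: linear trend, spline, and LR test."""
    return nonlinearity_test(reports, knots=knots, cov_method=cov_method)


def trend_table(result: TrendResult) -> pd.DataFrame:
    """Per-study slopes with a pooled row, in RR-per-birth units."""
    rows = [
        {
            "report_id": rid,
            "slope": s,
            "se_slope": se,
            "rr_per_birth": float(np.exp(s)),
            "lcl": float(np.exp(s - Z95 * se)),
            "ucl": float(np.exp(s + Z95 * se)),
        }
        for rid, s, se in result.per_study
    ]
    p = result.pooled
    rows.append(
        {
            "report_id": "POOLED",
            "slope": p.y_pooled,
            "se_slope": p.se_pooled,
            "rr_per_birth": p.rr,
            "lcl": p.ci95[0],
            "ucl": p.ci95[1],
        }
    )
    return pd.DataFrame(rows)


def spline_curve(result: TrendResult, step: float = 0.1, max_dose: float | None = None) -> pd.DataFrame:
    """Fitted spline curve sampled on a dose grid, with pointwise 95% bands."""
    if result.spline_coefs is None:
        raise NoDataError("no spline fit in this TrendResult")
    k1, _, k3 = result.knots
    hi = max_dose if max_dose is not None else k3 + 2.0
    grid = np.arange(0.0, hi + step / 2, step)
    b1, b2 = rcs_basis(grid, result.knots)
    design = np.column_stack([b1, b2])
    yhat = design @ np.array(result.spline_coefs)
    var = np.einsum("ij,jk,ik->i", design, result.spline_cov, design)
    se = np.sqrt(var)
    return pd.DataFrame(
        {
            "dose": grid,
            "rr": np.exp(yhat),
            "lcl": np.exp(yhat - Z95 * se),
            "ucl": np.exp(yhat + Z95 * se),
        }
    )
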