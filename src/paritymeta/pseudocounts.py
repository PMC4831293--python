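"""Pseudo-count reconstruction for correlated category-specific log relative risks.

Category-specific estimates within one study share the nulliparous reference
group, so their log relative risks are positively correlated. When only
summarized data are available the correlation can be recovered by fitting a
table of *pseudo-counts* that is consistent with the printed effect sizes,
their confidence intervals, and the study's marginal totals. Two classical
routes are implemented:

* Greenland-Longnecker (``gl_counts``): requires per-category denominators
  (subjects or person-time) plus the total case count; fits the pseudo case
  counts so the crude table reproduces the adjusted relative risks.
* Hamling (``hamling``): requires only the effect sizes, CIs and the study
  totals; solves for the reference-group pseudo cells such that every
  category's variance and relative risk are reproduced and the margins match.

In both cases the shared-reference variance component is

    odds model (case-control):  v0 = 1/a0 + 1/b0
    rate model (cohort-type):   v0 = 1/a0

where ``a0``/``b0`` are reference-group pseudo cases/noncases, and the
covariance between any two category log-RRs is ``v0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .catalog import StudyReport
from .exceptions import ConvergenceError, InsufficientDataError

__all__ = ["PseudoTable", "hamling_pseudocounts", "gl_pseudocounts", "shared_variance"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoTable:
    """Fitted pseudo-counts for one study's exposure categories.

    ``cases``/``denoms`` run over the non-reference categories in order;
    ``ref_cases``/``ref_denom`` are the reference cell. ``model`` is ``"odds"``
    (denominators are noncase counts) or ``"rate"`` (person-time, arbitrary
    scale). ``v0`` is the shared reference variance component.
    """

    cases: np.ndarray
    denoms: np.ndarray
    ref_cases: float
    ref_denom: float
    model: str

    @property
    def v0(self) -> float:
        if self.model == "odds":
            return 1.0 / self.ref_cases + 1.0 / self.ref_denom
        return 1.0 / self.ref_cases

    def covariance(self, variances: np.ndarray) -> np.ndarray:
        """Covariance matrix of the category log-RRs given their variances."""
        v = np.asarray(variances, dtype=float)
        c = np.full((v.size, v.size), self.v0)
        np.fill_diagonal(c, v)
        return c


def _model_for(report: StudyReport) -> str:
    return "odds" if report.design == "case_control" else "rate"


def _rate_solve(variances: np.ndarray, total_cases: float) -> float:
    """Solve a0 + sum_i 1/(var_i - 1/a0) = total_cases for the reference cases.

    The equation generally has two roots; the smaller reference count is
    returned, matching populations in which the reference (nulliparous) group
    is the minority.
    """
    vmin = float(np.min(variances))

    def f(a0: float) -> float:
        v0 = 1.0 / a0
        if v0 >= vmin:
            return np.inf
        return a0 + float(np.sum(1.0 / (variances - v0))) - total_cases

    lo = 1.0 / vmin
    grid = np.geomspace(lo * (1 + 1e-6), max(total_cases * 2.0, lo * 10.0), 4096)
    vals = np.array([f(a) for a in grid])
    neg = np.flatnonzero(vals < 0)
    if neg.size == 0:
        raise ConvergenceError(
            "rate-model pseudo-counts infeasible: total cases cannot be "
            "distributed consistently with the printed variances",
            {"total_cases": total_cases, "min_variance": vmin},
        )
    i = neg[0]
    return optimize.brentq(f, grid[i - 1], grid[i])


def _odds_cells(a0, b0, ors, variances):
    v0 = 1.0 / a0 + 1.0 / b0
    s = variances - v0
    if np.any(s <= 0):
        return None
    r = (b0 / a0) / ors          # noncase:case ratio in each category
    return (1 + 1 / r) / s, (1 + r) / s


def hamling_pseudocounts(
    report: StudyReport,
    log_rrs: np.ndarray,
    variances: np.ndarray,
) -> PseudoTable:
    """Fit pseudo-counts from effect sizes, CIs and the report's totals.

    For case-control reports the margins are ``total_cases`` and
    ``total_subjects`` (controls); two reference cells are solved
    simultaneously. For cohort-type reports a single reference case count is
    solved against ``total_cases`` under the person-time (rate) model.

    Raises :class:`ConvergenceError` when no pseudo table fits the margins —
    typical when adjustment has moved the printed estimates far from any crude
    table.
    """
    log_rrs = np.asarray(log_rrs, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if log_rrs.size == 0:
        raise InsufficientDataError("no categories to reconstruct")

    if _model_for(report) == "rate":
        a0 = _rate_solve(variances, float(report.total_cases))
        cases = 1.0 / (variances - 1.0 / a0)
        # person-time implied by the rate ratios (arbitrary reference scale 1)
        denoms = cases / (a0 * np.exp(log_rrs))
        return PseudoTable(cases, denoms, a0, 1.0, "rate")

    ors = np.exp(log_rrs)
    m_cases, m_controls = float(report.total_cases), float(report.total_subjects)

    def resid(x):
        a0, b0 = np.exp(x)
        cells = _odds_cells(a0, b0, ors, variances)
        if cells is None:
            return np.array([1e6, 1e6])
        ai, bi = cells
        return np.array([a0 + ai.sum() - m_cases, b0 + bi.sum() - m_controls])

    # the margin system can have several roots; gather them from a grid of
    # starts and keep the smallest reference cell (the largest shared-variance
    # component, i.e. the conservative correction — and the reference group is
    # the minority in the populations this models)
    fracs = (0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.7)
    roots: list[tuple[float, float]] = []
    for fa in fracs:
        for fb in fracs:
            x0 = np.log([max(m_cases * fa, 1e-3), max(m_controls * fb, 1e-3)])
            x, _info, ier, _msg = optimize.fsolve(resid, x0, full_output=True)
            if ier != 1:
                continue
            err = float(np.max(np.abs(resid(x))))
            if err > 1e-6 * max(m_cases, m_controls):
                continue
            a0, b0 = np.exp(x)
            if not (0 < a0 < m_cases and 0 < b0 < m_controls):
                continue
            if not any(abs(a0 - r[0]) < 1e-4 * m_cases for r in roots):
                roots.append((float(a0), float(b0)))
    if not roots:
        raise ConvergenceError(
            "odds-model pseudo-counts did not converge on the study margins",
            {"report_id": report.report_id},
        )
    a0, b0 = min(roots)
    ai, bi = _odds_cells(a0, b0, ors, variances)
    return PseudoTable(ai, bi, a0, b0, "odds")


def gl_pseudocounts(
    report: StudyReport,
    log_rrs: np.ndarray,
    denominators: np.ndarray,
    ref_denominator: float,
    total_cases: float | None = None,
    max_iter: int = 1000,
) -> PseudoTable:
    """Greenland-Longnecker pseudo cases from per-category denominators.

    ``denominators`` are subject counts (odds model) or person-time (rate
    model) for the non-reference categories; ``ref_denominator`` the same for
    the reference. The pseudo case counts are chosen so the crude table
    reproduces the adjusted relative risks while the total case count matches.
    The fit reduces to a one-dimensional root-find on the reference case
    count, solved by bisection within ``max_iter`` iterations.
    """
    log_rrs = np.asarray(log_rrs, dtype=float)
    denominators = np.asarray(denominators, dtype=float)
    total = float(report.total_cases if total_cases is None else total_cases)
    model = _model_for(report)
    rr = np.exp(log_rrs)

    if model == "rate":
        # a_i = denom_i * (a0/ref_denom) * RR_i is linear in a0
        slope = float(np.sum(denominators / ref_denominator * rr))
        a0 = total / (1.0 + slope)
        cases = denominators * (a0 / ref_denominator) * rr
        return PseudoTable(cases, denominators, a0, ref_denominator, "rate")

    def cases_given(a0: float) -> np.ndarray:
        odds0 = a0 / (ref_denominator - a0)
        odds = odds0 * rr
        return denominators * odds / (1.0 + odds)

    def f(a0: float) -> float:
        return a0 + float(cases_given(a0).sum()) - total

    lo, hi = 1e-9, ref_denominator * (1 - 1e-9)
    if f(lo) > 0 or f(hi) < 0:
        raise ConvergenceError(
            "Greenland-Longnecker fit infeasible: total cases outside the "
            "range attainable from the given denominators",
            {"report_id": report.report_id, "total_cases": total},
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12 * ref_denominator:
            break
    else:
        raise ConvergenceError(
            "Greenland-Longnecker bisection did not converge",
            {"report_id": report.report_id, "bracket": (lo, hi)},
        )
    a0 = 0.5 * (lo + hi)
    ai = cases_given(a0)
    # odds-model noncase cells
    return PseudoTable(ai, denominators - ai, a0, ref_denominator - a0, "odds")


def shared_variance(report: StudyReport, log_rrs, variances) -> float:
    """Shared reference variance component v0, or 0.0 when unrecoverable.

    Convenience wrapper used by the category collapse and by covariance
    reconstruction: attempts the Hamling fit from the report totals and falls
    back to independence (v0 = 0) with a logged warning when no pseudo table
    fits the margins.
    """
    try:
        table = hamling_pseudocounts(report, np.asarray(log_rrs), np.asarray(variances))
    except ConvergenceError as exc:
        log.warning(
            "%s: pseudo-count reconstruction failed (%s); treating categories "
            "as independent", report.report_id, exc,
        )
        return 0.0
    # numerical guard: v0 must stay below every category variance
    return min(table.v0, 0.999 * float(np.min(variances)))
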