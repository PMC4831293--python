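"""Log relative risks with standard errors — the currency of pooling.

Printed RR (lcl-ucl) rows convert to a log effect by ``y = ln RR`` with
``se = (ln ucl - ln lcl) / (2 z)`` where z is the two-sided 95% normal
quantile. Reports that print several parous categories but no overall
"Parous" row are collapsed to a single parous-vs-nulliparous contrast by
generalized least squares; because the categories share the nulliparous
reference group, the default collapse reconstructs the shared variance
component from the study totals (see :mod:`paritymeta.pseudocounts`) rather
than treating the categories as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .catalog import ExposureCategory, StudyReport
from .exceptions import DegenerateIntervalError, DomainError, NoDataError
from .pseudocounts import shared_variance

__all__ = ["Z95", "LogEffect", "log_effect_from_ci", "combine_categories", "parous_contrast"]

# two-sided 95% standard-normal quantile at full precision (not the rounded 1.96)
Z95 = 1.959964

CollapseMethod = Literal["shared_ref", "independent"]


@dataclass(frozen=True)
class LogEffect:
    """A log relative risk and its standard error."""

    y: float
    se: float
    report_id: str = ""
    contrast_label: str = ""

    def __post_init__(self):
        if not self.se > 0:
            raise DomainError(f"standard error must be positive, got {self.se}")

    @property
    def rr(self) -> float:
        return float(np.exp(self.y))

    @property
    def ci95(self) -> tuple[float, float]:
        return float(np.exp(self.y - Z95 * self.se)), float(np.exp(self.y + Z95 * self.se))


def log_effect_from_ci(
    rr: float, lcl: float, ucl: float, report_id: str = "", contrast_label: str = ""
) -> LogEffect:
    """Convert a printed RR with 95% CI to a log effect with standard error."""
    if min(rr, lcl, ucl) <= 0:
        raise DomainError(f"relative risks must be positive, got ({rr}, {lcl}, {ucl})")
    if lcl == ucl:
        raise DegenerateIntervalError(f"zero-width interval ({lcl}, {ucl}) carries no se")
    if not lcl <= rr <= ucl:
        raise DomainError(f"rr {rr} outside its CI ({lcl}, {ucl})")
    return LogEffect(
        y=float(np.log(rr)),
        se=float((np.log(ucl) - np.log(lcl)) / (2 * Z95)),
        report_id=report_id,
        contrast_label=contrast_label,
    )


def _category_effect(report: StudyReport, cat: ExposureCategory) -> LogEffect:
    return log_effect_from_ci(cat.rr, cat.lcl, cat.ucl, report.report_id, cat.label)


def combine_categories(
    report: StudyReport,
    selector: Callable[[ExposureCategory], bool] | None = None,
    method: CollapseMethod = "shared_ref",
) -> LogEffect:
    """Collapse selected non-reference categories into one log effect.

    A single selected category is returned unchanged. Several categories are
    combined by GLS: with ``method="independent"`` this is the plain
    inverse-variance (1/se^2-weighted) average; with the default
    ``method="shared_ref"`` the covariance between categories induced by the
    common reference group is reconstructed from the report totals, which
    widens the combined interval accordingly.
    """
    cats = [c for c in report.exposure_categories if selector is None or selector(c)]
    if not cats:
        raise NoDataError(f"{report.report_id}: no category passes the selector")
    effects = [_category_effect(report, c) for c in cats]
    label = "+".join(c.label for c in cats)
    if len(effects) == 1:
        return effects[0]

    y = np.array([e.y for e in effects])
    var = np.array([e.se for e in effects]) ** 2
    v0 = shared_variance(report, y, var) if method == "shared_ref" else 0.0
    cov = np.full((y.size, y.size), v0)
    np.fill_diagonal(cov, var)
    ci = np.linalg.inv(cov)
    ones = np.ones(y.size)
    pooled_var = 1.0 / float(ones @ ci @ ones)
    pooled_y = pooled_var * float(ones @ ci @ y)
    return LogEffect(pooled_y, float(np.sqrt(pooled_var)), report.report_id, label)


def parous_contrast(report: StudyReport, method: CollapseMethod = "shared_ref") -> LogEffect:
    """Parous-vs-nulliparous log effect for one report.

    The printed "Parous" row is used verbatim when the source provides one;
    otherwise every non-reference category is collapsed via
    :func:`combine_categories`.
    """
    if report.parous_row is not None:
        return _category_effect(report, report.parous_row)
    if not report.exposure_categories:
        raise NoDataError(f"{report.report_id}: no parous categories to combine")
    return combine_categories(report, method=method)
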