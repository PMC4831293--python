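"""Fixed- and random-effects pooling, heterogeneity, subgroups, sensitivity.

Fixed-effects pooling is the inverse-variance average of study log effects;
the random-effects model is DerSimonian-Laird, adding the moment estimate of
the between-study variance tau^2 to every study variance before re-weighting.
Heterogeneity is summarized by Cochran's Q, its chi-square p-value, and
I^2 = max(0, (Q - df)/Q) x 100. The model-selection rule follows the source
analysis: random effects are reported only when I^2 exceeds 50%, applied
per analysis (overall, each stratum, each leave-one-out fit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import StudyReport, classify_quality
from .effects import Z95, LogEffect, parous_contrast
from .exceptions import InsufficientDataError, NoDataError

__all__ = [
    "PooledResult",
    "pool_fixed",
    "pool_random_dl",
    "pool_auto",
    "subgroup_analysis",
    "leave_one_out",
    "forest_table",
    "GROUPINGS",
]

I2_RANDOM_THRESHOLD = 50.0  # percent; substantial heterogeneity


@dataclass(frozen=True)
class PooledResult:
    """Pooled estimate with its heterogeneity statistics."""

    k: int
    y_pooled: float
    se_pooled: float
    Q: float
    df: int
    p_het: float
    i2: float
    tau2: float
    model: Literal["fixed", "random"]

    @property
    def rr(self) -> float:
        return float(np.exp(self.y_pooled))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.y_pooled - Z95 * self.se_pooled)),
            float(np.exp(self.y_pooled + Z95 * self.se_pooled)),
        )

    @property
    def p_value(self) -> float:
        """Two-sided normal test of the pooled log effect against zero."""
        return float(2 * stats.norm.sf(abs(self.y_pooled / self.se_pooled)))


def _het_stats(y: np.ndarray, w: np.ndarray, y_pooled: float) -> tuple[float, int, float, float]:
    Q = float(np.sum(w * (y - y_pooled) ** 2))
    df = y.size - 1
    p_het = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, p_het, i2


def pool_fixed(effects: Sequence[LogEffect]) -> PooledResult:
    """Inverse-variance fixed-effects pool; k = 1 returns the effect itself."""
    if not effects:
        raise NoDataError("cannot pool an empty list of effects")
    y = np.array([e.y for e in effects])
    w = 1.0 / np.array([e.se for e in effects]) ** 2
    y_pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    Q, df, p_het, i2 = _het_stats(y, w, y_pooled)
    return PooledResult(y.size, y_pooled, se, Q, df, p_het, i2, 0.0, "fixed")


def pool_random_dl(effects: Sequence[LogEffect]) -> PooledResult:
    """DerSimonian-Laird random-effects pool (k >= 2).

    Q, I^2 and p_het are those of the fixed-effects step, as conventionally
    reported alongside the random-effects estimate.
    """
    if len(effects) < 2:
        raise InsufficientDataError("random-effects pooling needs at least 2 effects")
    y = np.array([e.y for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    Q, df, p_het, i2 = _het_stats(y, w, y_fe)
    tau2 = max(0.0, (Q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    w_star = 1.0 / (v + tau2)
    y_pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    return PooledResult(y.size, y_pooled, se, Q, df, p_het, i2, float(tau2), "random")


def pool_auto(effects: Sequence[LogEffect]) -> PooledResult:
    """Fixed effects, switching to DerSimonian-Laird when I^2 > 50%."""
    fixed = pool_fixed(effects)
    if fixed.i2 > I2_RANDOM_THRESHOLD and fixed.k >= 2:
        return pool_random_dl(effects)
    return fixed


def _control_type(report: StudyReport) -> str | None:
    return {"population_cc": "population_based", "hospital_cc": "hospital_based"}.get(
        report.design_detail
    )


GROUPINGS: dict[str, Callable[[StudyReport], str | None]] = {
    "design": lambda r: r.design,
    "quality": lambda r: None if r.nos_score is None else classify_quality(r),
    "region": lambda r: r.region,
    "control_type": lambda r: _control_type(r) if r.design == "case_control" else None,
    "adjustment": lambda r: "adjusted" if r.adjusted else "unadjusted",
}


def subgroup_analysis(
    reports: Sequence[StudyReport],
    grouping: str,
    contrast: Callable[[StudyReport], LogEffect] = parous_contrast,
) -> dict[str, PooledResult]:
    """Pool the per-report contrasts within each stratum of a grouping.

    Reports for which the grouping is undefined (e.g. control type outside
    case-control designs, or an unscored report under the quality grouping)
    are omitted rather than treated as errors.
    """
    if grouping not in GROUPINGS:
        raise KeyError(f"unknown grouping {grouping!r}; one of {sorted(GROUPINGS)}")
    keyfn = GROUPINGS[grouping]
    strata: dict[str, list[LogEffect]] = {}
    for report in reports:
        key = keyfn(report)
        if key is not None:
            strata.setdefault(key, []).append(contrast(report))
    return {key: pool_auto(effs) for key, effs in strata.items()}


def leave_one_out(effects: Sequence[LogEffect]) -> list[tuple[str, PooledResult]]:
    """Re-pool k times, omitting one effect at a time (k >= 2)."""
    if len(effects) < 2:
        raise InsufficientDataError("leave-one-out needs at least 2 effects")
    out = []
    for i, omitted in enumerate(effects):
        rest = [e for j, e in enumerate(effects) if j != i]
        out.append((omitted.report_id, pool_auto(rest)))
    return out


def forest_table(
    effects: Sequence[LogEffect], pooled: PooledResult | None = None
) -> pd.DataFrame:
    """Plot-ready forest data: one row per effect plus a pooled row.

    Weights are the percentage inverse-variance weights of the model used for
    the pooled row (fixed weights when pooled is fixed or absent).
    """
    if pooled is None:
        pooled = pool_auto(effects)
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / (v + (pooled.tau2 if pooled.model == "random" else 0.0))
    w_pct = 100.0 * w / w.sum()
    rows = [
        {
            "report_id": e.report_id,
            "label": e.contrast_label,
            "rr": e.rr,
            "lcl": e.ci95[0],
            "ucl": e.ci95[1],
            "weight_pct": w_pct[i],
        }
        for i, e in enumerate(effects)
    ]
    rows.append(
        {
            "report_id": "POOLED",
            "label": f"{pooled.model} effects",
            "rr": pooled.rr,
            "lcl": pooled.ci95[0],
            "ucl": pooled.ci95[1],
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
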