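"""Egger and Begg tests for funnel-plot asymmetry.

Egger's test regresses the standardized effect y_i/se_i on the precision
1/se_i by ordinary least squares; the intercept estimates asymmetry and is
tested with a t statistic on k - 2 degrees of freedom. Begg's rank
correlation computes Kendall's tau between the variance-standardized
deviations from the fixed-effects pool and the study variances, with the
continuity-corrected normal approximation (and exact enumeration for small
k, where the permutation distribution is affordable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import LogEffect
from .exceptions import InsufficientDataError, SingularDesignError

__all__ = ["BiasTestResult", "egger_test", "begg_test", "funnel_table"]


@dataclass(frozen=True)
class BiasTestResult:
    method: Literal["egger", "begg"]
    statistic: float
    p_value: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None


def egger_test(effects: Sequence[LogEffect]) -> BiasTestResult:
    """Egger's weighted-regression asymmetry test (k >= 3)."""
    if len(effects) < 3:
        raise InsufficientDataError("Egger's test needs at least 3 effects")
    se = np.array([e.se for e in effects])
    y = np.array([e.y for e in effects])
    precision = 1.0 / se
    if np.ptp(precision) < 1e-12:
        raise SingularDesignError("all precisions equal; Egger design is singular")
    fit = sm.OLS(y / se, sm.add_constant(precision)).fit()
    intercept = float(fit.params[0])
    t_stat = float(fit.tvalues[0])
    p = float(2 * stats.t.sf(abs(t_stat), len(effects) - 2))
    return BiasTestResult(
        "egger", t_stat, p, len(effects), intercept, float(fit.bse[0])
    )


def _kendall_score(a: np.ndarray, b: np.ndarray) -> int:
    """Concordant minus discordant pairs (ties contribute zero)."""
    i, j = np.triu_indices(a.size, k=1)
    return int(np.sum(np.sign(a[j] - a[i]) * np.sign(b[j] - b[i])))


def _tie_corrected_variance(values: np.ndarray) -> float:
    n = values.size
    var = n * (n - 1) * (2 * n + 5) / 18.0
    for _, count in zip(*np.unique(values, return_counts=True)):
        if count > 1:
            var -= count * (count - 1) * (2 * count + 5) / 18.0
    return var


def begg_test(effects: Sequence[LogEffect], exact_max_k: int = 8) -> BiasTestResult:
    """Begg-Mazumdar rank correlation between effect and variance (k >= 3).

    Effects are first standardized against the fixed-effects pool,
    y*_i = (y_i - y_FE) / sqrt(se_i^2 - se_FE^2), so that under the null the
    ranks of y* are exchangeable with respect to the variances. For
    k <= ``exact_max_k`` the two-sided p is computed by exhaustive
    permutation of the ranks; otherwise the normal approximation with the
    standard continuity correction (|score| reduced by 1) and tie-corrected
    variance is used.
    """
    if len(effects) < 3:
        raise InsufficientDataError("Begg's test needs at least 3 effects")
    y = np.array([e.y for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / v
    y_fe = np.sum(w * y) / np.sum(w)
    v_fe = 1.0 / np.sum(w)
    # guard: pooled variance is strictly below each study variance
    y_star = (y - y_fe) / np.sqrt(np.maximum(v - v_fe, 1e-300))
    score = _kendall_score(y_star, v)
    n = y.size

    if n <= exact_max_k:
        null_scores = [
            _kendall_score(np.array(perm, dtype=float), v)
            for perm in permutations(range(n))
        ]
        p = float(np.mean([abs(s) >= abs(score) for s in null_scores]))
        var = _tie_corrected_variance(v)
        z = (abs(score) - 1) / np.sqrt(var) if var > 0 else 0.0
        return BiasTestResult("begg", float(z), p, n)

    var = _tie_corrected_variance(v)
    z = max((abs(score) - 1), 0.0) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(z)))
    return BiasTestResult("begg", float(z), p, n)


def funnel_table(effects: Sequence[LogEffect]) -> pd.DataFrame:
    """Plot-ready funnel data: one (y, se) row per report."""
    return pd.DataFrame(
        {
            "report_id": [e.report_id for e in effects],
            "y": [e.y for e in effects],
            "se": [e.se for e in effects],
        }
    )
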