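"""Synthetic study catalogs with known truth.

The generator emulates the structure of the real evidence base: a mix of
case-control and cohort reports, each with a nulliparous reference category
and one to six parous categories, per-category counts drawn under the
study's design, a configurable true dose-response curve on the log-RR scale,
and between-study heterogeneity as a study-level normal shift. Confidence
intervals are Woolf (log-scale normal) intervals computed from the realized
counts at full precision, so converting them back to log effects is exact.

Case-control reports draw case and control category counts from
multinomials (cases tilted by the true relative risks); cohort reports draw
per-category case counts from Poisson person-time. All randomness flows
from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import ExposureCategory, StudyReport
from .effects import Z95

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_catalog", "curve_log_rr"]

log = logging.getLogger(__name__)

# category layouts seen in the real literature: (lower, upper) with None = open-ended
_TEMPLATES: tuple[tuple[tuple[int, int | None], ...], ...] = (
    ((1, 1), (2, 2), (3, None)),
    ((1, 1), (2, 2), (3, 3), (4, None)),
    ((1, 2), (3, 4), (5, None)),
    ((1, 2), (3, None)),
    ((1, 1), (2, 2), (3, 3), (4, 5), (6, 7), (8, None)),
    ((1, None),),
)

_REGIONS = ("Europe", "America", "Asia", "Oceania")
_REGION_WEIGHTS = (8 / 23, 8 / 23, 5 / 23, 2 / 23)

_MAX_PARITY = 12          # truncation of the parity distribution
_P_NULLIPAROUS = 0.12     # reference-group prevalence
_PARITY_DECAY = 0.35      # geometric-like decay of parity counts beyond 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generating conditions.

    ``true_curve`` is ``("null",)``, ``("linear", beta)`` with beta the
    log-RR per live birth, or ``("spline", b1, b2, (k1, k2, k3))``.
    ``tau2`` is the variance of a study-level additive shift of all
    non-reference log relative risks. ``design_mix`` is the probability that
    a study is case-control (the real literature is 14 of 24).
    ``cases_per_study`` bounds the expected case count, drawn log-uniformly.
    ``selection`` optionally suppresses studies without a significantly
    positive parous contrast, with the given probability.
    """

    n_studies: int = 24
    design_mix: float = 14 / 24
    true_curve: tuple = ("null",)
    tau2: float = 0.0
    category_template: tuple[tuple[int, int | None], ...] | None = None
    baseline_risk: float = 1e-4            # cases per person-year in the reference
    cases_per_study: tuple[int, int] = (30, 1500)
    selection: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be at least 1")
        for p in (self.design_mix, self.baseline_risk):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.selection is not None and not 0 <= self.selection <= 1:
            raise ValueError("selection probability outside [0, 1]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass
class SimulationTruth:
    """True quantities behind one simulated catalog."""

    config: SimulationConfig
    study_shifts: list[float] = field(default_factory=list)
    true_log_rr: dict[str, np.ndarray] = field(default_factory=dict)
    doses: dict[str, np.ndarray] = field(default_factory=dict)


def curve_log_rr(curve: tuple, dose: np.ndarray) -> np.ndarray:
    """Evaluate the configured true dose-response curve on the log-RR scale."""
    dose = np.asarray(dose, dtype=float)
    kind = curve[0]
    if kind == "null":
        return np.zeros_like(dose)
    if kind == "linear":
        return curve[1] * dose
    if kind == "spline":
        from .dose_response import rcs_basis

        _, b1, b2, knots = curve[0], curve[1], curve[2], curve[3]
        x1, x2 = rcs_basis(dose, knots)
        return b1 * x1 + b2 * x2
    raise ValueError(f"unknown curve kind {kind!r}")


def _template_doses(template) -> np.ndarray:
    doses, prev_width = [], None
    for lo, hi in template:
        if hi is None:
            width = prev_width if prev_width else 1.0
            doses.append(lo + width / 2.0)
        else:
            doses.append((lo + hi) / 2.0)
            prev_width = float(hi - lo)
    return np.array(doses)


def _category_probs(template) -> tuple[float, np.ndarray]:
    """(reference probability, per-category probabilities) from the parity law."""
    parity_p = np.exp(-_PARITY_DECAY * (np.arange(1, _MAX_PARITY + 1) - 1))
    probs = []
    for lo, hi in template:
        hi = _MAX_PARITY if hi is None else min(hi, _MAX_PARITY)
        probs.append(parity_p[lo - 1: hi].sum())
    probs = np.array(probs)
    return _P_NULLIPAROUS, probs / probs.sum() * (1 - _P_NULLIPAROUS)


def _draw_case_control(rng, p0, probs, rr, n_cases):
    p_ctrl = np.concatenate([[p0], probs])
    p_case = p_ctrl * np.concatenate([[1.0], rr])
    p_case /= p_case.sum()
    a = rng.multinomial(n_cases, p_case)
    b = rng.multinomial(n_cases, p_ctrl)
    return a, b


def _draw_cohort(rng, p0, probs, rr, target_cases, baseline_risk):
    pt_total = target_cases / baseline_risk
    pt = pt_total * np.concatenate([[p0], probs])
    lam = baseline_risk * pt * np.concatenate([[1.0], rr])
    return rng.poisson(lam), pt


def _study_report(rng, config: SimulationConfig, index: int, truth: SimulationTruth):
    rid = f"sim{index:03d}"
    is_cc = rng.random() < config.design_mix
    template = config.category_template or _TEMPLATES[rng.integers(len(_TEMPLATES))]
    doses = _template_doses(template)
    p0, probs = _category_probs(template)
    shift = rng.normal(0.0, np.sqrt(config.tau2)) if config.tau2 > 0 else 0.0
    true_logrr = curve_log_rr(config.true_curve, doses) + shift
    rr = np.exp(true_logrr)
    lo, hi = config.cases_per_study
    n_target = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    scale = 1
    for attempt in range(15):
        if is_cc:
            a, b = _draw_case_control(rng, p0, probs, rr, n_target * scale)
            denom = b
        else:
            a, pt = _draw_cohort(rng, p0, probs, rr, n_target * scale, config.baseline_risk)
            denom = pt
        if a.min() >= 1 and (not is_cc or b.min() >= 1):
            break
        if attempt == 9:
            scale *= 2
            log.warning("%s: zero cells after 10 draws; widening counts x%d", rid, scale)
    else:
        raise RuntimeError(f"{rid}: could not draw a table without zero cells")

    cats = [
        ExposureCategory("Nulliparous", 0, 0, True, 1.0, 1.0, 1.0, int(a[0]), float(denom[0]))
    ]
    for i, (lo_b, hi_b) in enumerate(template, start=1):
        if is_cc:
            y = np.log((a[i] / b[i]) / (a[0] / b[0]))
            se = np.sqrt(1 / a[i] + 1 / b[i] + 1 / a[0] + 1 / b[0])
        else:
            y = np.log((a[i] / denom[i]) / (a[0] / denom[0]))
            se = np.sqrt(1 / a[i] + 1 / a[0])
        label = f"{lo_b}" if hi_b == lo_b else (f">={lo_b}" if hi_b is None else f"{lo_b}-{hi_b}")
        cats.append(
            ExposureCategory(
                label, lo_b, hi_b, False,
                float(np.exp(y)),
                float(np.exp(y - Z95 * se)),
                float(np.exp(y + Z95 * se)),
                int(a[i]), float(denom[i]),
            )
        )

    total_cases = int(a.sum())
    total_subjects = int(b.sum()) if is_cc else int(np.sum(denom) / 10.0)  # ~10 y follow-up
    report = StudyReport(
        report_id=rid,
        author_year=f"Synthetic ({rid})",
        design="case_control" if is_cc else "prospective",
        design_detail="population_cc" if is_cc else "cohort",
        region=_REGIONS[rng.choice(len(_REGIONS), p=_REGION_WEIGHTS)],
        nos_score=int(rng.integers(5, 10)),
        adjusted=True,
        total_cases=total_cases,
        total_subjects=max(total_subjects, total_cases),
        categories=cats,
    )
    report.validate()
    truth.study_shifts.append(float(shift))
    truth.true_log_rr[rid] = true_logrr
    truth.doses[rid] = doses
    return report


def _passes_selection(rng, config: SimulationConfig, report: StudyReport) -> bool:
    if config.selection is None:
        return True
    from .effects import combine_categories

    eff = combine_categories(report, method="independent")
    significant_positive = eff.y / eff.se > Z95
    if significant_positive:
        return True
    return rng.random() >= config.selection


def simulate_catalog(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[StudyReport], SimulationTruth]:
    """Generate a catalog of synthetic study reports with its truth record.

    Deterministic given the generator state (or ``config.seed`` when no
    generator is passed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = SimulationTruth(config=config)
    reports: list[StudyReport] = []
    index = 0
    attempts = 0
    while len(reports) < config.n_studies:
        attempts += 1
        if attempts > 200 * config.n_studies:
            raise RuntimeError("publication selection rejected too many studies")
        report = _study_report(rng, config, index, truth)
        if _passes_selection(rng, config, report):
            reports.append(report)
            index += 1
        else:
            # discard the rejected study's truth entries
            truth.study_shifts.pop()
            truth.true_log_rr.pop(report.report_id)
            truth.doses.pop(report.report_id)
    return reports, truth
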