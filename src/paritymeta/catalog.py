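"""Typed data model for summarized study reports and the catalog CSV format.

A *report* is one analyzable unit of evidence: usually a study, occasionally an
age stratum that the source publication never combined (and which is therefore
treated as its own report). Each report carries an ordered list of exposure
categories — one row of printed relative risk and 95% confidence interval per
parity range — anchored by a single nulliparous reference category, plus an
optional printed "Parous" (any births vs none) contrast.

The CSV schema is one row per category with the report metadata repeated:

    report_id, author_year, design, design_detail, region, nos_score, adjusted,
    total_cases, total_subjects, category_label, lower, upper, is_reference,
    rr, lcl, ucl, n_cases, n_denominator

``upper`` left blank encodes an open-ended range ("3 or more births").
``nos_score`` may be blank for reports that were never quality-scored (pooled
re-analyses). ``n_cases``/``n_denominator`` are per-category counts, blank when
the source table does not print them. ``total_subjects`` is the size of the
comparison group: controls for case-control reports, cohort size otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "ExposureCategory",
    "StudyReport",
    "read_catalog",
    "write_catalog",
    "load_fixture",
    "classify_quality",
    "CSV_COLUMNS",
]

Design = Literal["prospective", "case_control"]
DesignDetail = Literal[
    "cohort", "nested_cc", "case_cohort", "population_cc", "hospital_cc", "pooled_cc"
]
Region = Literal["Europe", "America", "Asia", "Oceania", "International"]

CSV_COLUMNS = [
    "report_id", "author_year", "design", "design_detail", "region",
    "nos_score", "adjusted", "total_cases", "total_subjects",
    "category_label", "lower", "upper", "is_reference",
    "rr", "lcl", "ucl", "n_cases", "n_denominator",
]

_DESIGNS = {"prospective", "case_control"}
_DETAILS = {"cohort", "nested_cc", "case_cohort", "population_cc", "hospital_cc", "pooled_cc"}
_REGIONS = {"Europe", "America", "Asia", "Oceania", "International"}


@dataclass(frozen=True)
class ExposureCategory:
    """One printed RR/CI row with its parity range.

    ``upper is None`` encodes an open-ended range; counts are ``None`` when the
    source does not report them. The reference category is the nulliparous
    group and must carry the identity relative risk.
    """

    label: str
    lower: int
    upper: int | None
    is_reference: bool
    rr: float
    lcl: float
    ucl: float
    n_cases: int | None = None
    n_noncases_or_persontime: float | None = None

    def validate(self, report_id: str = "") -> None:
        if self.lower < 0:
            raise ValidationError(f"category {self.label!r}: negative lower bound", report_id)
        if self.upper is not None and self.lower > self.upper:
            raise ValidationError(
                f"category {self.label!r}: lower {self.lower} > upper {self.upper}", report_id
            )
        if self.is_reference:
            if not (self.rr == self.lcl == self.ucl == 1.0):
                raise ValidationError(
                    f"reference category {self.label!r} must have rr = lcl = ucl = 1", report_id
                )
            if self.lower != 0 or self.upper != 0:
                raise ValidationError(
                    f"reference category {self.label!r} must span parity 0 exactly", report_id
                )
        else:
            if min(self.rr, self.lcl, self.ucl) <= 0:
                raise ValidationError(
                    f"category {self.label!r}: non-positive rr or CI bound", report_id
                )
            if not (self.lcl <= self.rr <= self.ucl):
                raise ValidationError(
                    f"category {self.label!r}: rr {self.rr} outside CI "
                    f"({self.lcl}, {self.ucl})", report_id
                )


@dataclass
class StudyReport:
    """One analyzable report with its exposure categories and metadata."""

    report_id: str
    author_year: str
    design: Design
    design_detail: DesignDetail
    region: Region
    nos_score: int | None
    adjusted: bool
    total_cases: int
    total_subjects: int
    categories: list[ExposureCategory] = field(default_factory=list)
    parous_row: ExposureCategory | None = None

    @property
    def reference(self) -> ExposureCategory:
        return next(c for c in self.categories if c.is_reference)

    @property
    def exposure_categories(self) -> list[ExposureCategory]:
        """Non-reference categories, in printed (ascending parity) order."""
        return [c for c in self.categories if not c.is_reference]

    def validate(self) -> None:
        if self.design not in _DESIGNS:
            raise ValidationError(f"unknown design {self.design!r}", self.report_id)
        if self.design_detail not in _DETAILS:
            raise ValidationError(f"unknown design detail {self.design_detail!r}", self.report_id)
        if self.region not in _REGIONS:
            raise ValidationError(f"unknown region {self.region!r}", self.report_id)
        if self.nos_score is not None and not 0 <= self.nos_score <= 9:
            raise ValidationError(f"NOS score {self.nos_score} outside [0, 9]", self.report_id)
        refs = [c for c in self.categories if c.is_reference]
        if len(refs) != 1:
            raise ValidationError(
                f"expected exactly one reference category, found {len(refs)}", self.report_id
            )
        for cat in self.categories:
            cat.validate(self.report_id)
        if self.parous_row is not None:
            self.parous_row.validate(self.report_id)
        # parity ranges ascending and non-overlapping
        prev_hi: float = -1.0
        for cat in self.categories:
            if cat.lower <= prev_hi:
                raise ValidationError(
                    f"category {cat.label!r} overlaps or is out of order", self.report_id
                )
            prev_hi = math.inf if cat.upper is None else cat.upper


def classify_quality(report: StudyReport) -> str:
    """Newcastle-Ottawa quality label: ``"high"`` iff the score is 7 or more."""
    if report.nos_score is None:
        raise ValidationError("no NOS score recorded", report.report_id)
    return "high" if report.nos_score >= 7 else "low"


def _parse_int(value, row: int, column: str, required: bool = True) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise ParseError("missing required integer", row, column)
        return None
    try:
        out = int(float(value))
    except (TypeError, ValueError):
        raise ParseError(f"not an integer: {value!r}", row, column) from None
    if out != float(value):
        raise ParseError(f"not an integer: {value!r}", row, column)
    return out


def _parse_float(value, row: int, column: str, required: bool = True) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise ParseError("missing required number", row, column)
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"not a number: {value!r}", row, column) from None


def read_catalog(path: str | Path) -> list[StudyReport]:
    """Read a catalog CSV into validated :class:`StudyReport` objects.

    Raises :class:`ParseError` on schema violations (naming row and column)
    and :class:`ValidationError` on invariant violations (naming the report).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing columns {missing}; header must match the documented schema")

    reports: dict[str, StudyReport] = {}
    for idx, rec in frame.iterrows():
        row = int(idx) + 2  # 1-based with header
        rid = rec["report_id"]
        if not rid:
            raise ParseError("empty report_id", row, "report_id")
        cat = ExposureCategory(
            label=rec["category_label"],
            lower=_parse_int(rec["lower"], row, "lower"),
            upper=_parse_int(rec["upper"], row, "upper", required=False),
            is_reference=bool(_parse_int(rec["is_reference"], row, "is_reference")),
            rr=_parse_float(rec["rr"], row, "rr"),
            lcl=_parse_float(rec["lcl"], row, "lcl"),
            ucl=_parse_float(rec["ucl"], row, "ucl"),
            n_cases=_parse_int(rec["n_cases"], row, "n_cases", required=False),
            n_noncases_or_persontime=_parse_float(
                rec["n_denominator"], row, "n_denominator", required=False
            ),
        )
        if rid not in reports:
            if rec["design"] not in _DESIGNS:
                raise ParseError(f"unknown design {rec['design']!r}", row, "design")
            reports[rid] = StudyReport(
                report_id=rid,
                author_year=rec["author_year"],
                design=rec["design"],
                design_detail=rec["design_detail"],
                region=rec["region"],
                nos_score=_parse_int(rec["nos_score"], row, "nos_score", required=False),
                adjusted=bool(_parse_int(rec["adjusted"], row, "adjusted")),
                total_cases=_parse_int(rec["total_cases"], row, "total_cases"),
                total_subjects=_parse_int(rec["total_subjects"], row, "total_subjects"),
            )
        if cat.label == "Parous" and not cat.is_reference:
            reports[rid].parous_row = cat
        else:
            reports[rid].categories.append(cat)

    out = list(reports.values())
    for report in out:
        report.validate()
    return out


def _cat_row(report: StudyReport, cat: ExposureCategory) -> dict:
    return {
        "report_id": report.report_id,
        "author_year": report.author_year,
        "design": report.design,
        "design_detail": report.design_detail,
        "region": report.region,
        "nos_score": "" if report.nos_score is None else report.nos_score,
        "adjusted": int(report.adjusted),
        "total_cases": report.total_cases,
        "total_subjects": report.total_subjects,
        "category_label": cat.label,
        "lower": cat.lower,
        "upper": "" if cat.upper is None else cat.upper,
        "is_reference": int(cat.is_reference),
        "rr": cat.rr,
        "lcl": cat.lcl,
        "ucl": cat.ucl,
        "n_cases": "" if cat.n_cases is None else cat.n_cases,
        "n_denominator": (
            "" if cat.n_noncases_or_persontime is None else cat.n_noncases_or_persontime
        ),
    }


def write_catalog(reports: Iterable[StudyReport], path: str | Path) -> None:
    """Write reports back to the catalog CSV schema (one row per category)."""
    rows = []
    for report in reports:
        ordered = list(report.categories)
        # the printed Parous contrast sits after the reference row, as in the source tables
        if report.parous_row is not None:
            ordered.insert(1, report.parous_row)
        rows.extend(_cat_row(report, c) for c in ordered)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def load_fixture() -> list[StudyReport]:
    """Load the packaged parity / thyroid-cancer catalog (24 reports)."""
    with resources.as_file(
        resources.files("paritymeta") / "data" / "parity_thyroid_catalog.csv"
    ) as p:
        return read_catalog(p)
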