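"""Dose assignment, covariance reconstruction, trend and spline estimation."""

import math

import numpy as np
import pytest

import paritymeta as pm
from paritymeta.dose_response import pooled_knots, rcs_basis, spline_curve, trend_table
from paritymeta.effects import Z95
from paritymeta.exceptions import DomainError, InsufficientDataError, NoDataError
from paritymeta.pseudocounts import gl_pseudocounts, hamling_pseudocounts


def _report(cats, design="case_control", total_cases=200, total_subjects=200, rid="toy",
            ref_counts=(None, None)):
    """cats: list of (label, lower, upper, rr, lcl, ucl[, n_cases, denom])."""
    categories = [
        pm.ExposureCategory(
            "Nulliparous", 0, 0, True, 1.0, 1.0, 1.0, ref_counts[0], ref_counts[1]
        )
    ]
    for spec in cats:
        label, lo, hi, rr, lcl, ucl = spec[:6]
        n_c = spec[6] if len(spec) > 6 else None
        n_d = spec[7] if len(spec) > 7 else None
        categories.append(
            pm.ExposureCategory(label, lo, hi, False, rr, lcl, ucl, n_c, n_d)
        )
    report = pm.StudyReport(
        report_id=rid, author_year=f"{rid} (2020)", design=design,
        design_detail="population_cc" if design == "case_control" else "cohort",
        region="Europe", nos_score=7, adjusted=True,
        total_cases=total_cases, total_subjects=total_subjects,
        categories=categories,
    )
    report.validate()
    return report


class TestAssignDoses:
    def test_memon_ladder(self, by_id):
        doses = pm.assign_doses(by_id["memon_2002"])
        assert doses.doses == (0.0, 1.5, 3.5, 5.5, 7.5, 9.5, 11.5)
        assert doses.rules[-1] == "open_ended"

    def test_reference_and_midpoint_rules(self, by_id):
        doses = pm.assign_doses(by_id["xhaard_2014"])
        # single values 1, 2 then open-ended >=3 whose neighbour has width 0
        assert doses.doses == (0.0, 1.0, 2.0, 3.5)
        assert doses.rules == ("reference_zero", "single_value", "single_value", "open_ended")

    def test_open_interval_inherits_adjacent_width(self, by_id):
        doses = pm.assign_doses(by_id["truong_2005"])
        # ... 4-5, 6-7 (width 1), >=8 -> 8.5
        assert doses.doses[-1] == 8.5

    def test_idempotent_and_strictly_increasing(self, reports):
        for report in reports:
            first = pm.assign_doses(report)
            assert pm.assign_doses(report) == first
            assert np.all(np.diff(first.doses) > 0)


class TestStudyLinearTrend:
    def test_single_category_closed_form(self):
        report = _report([("1-2", 1, 2, 2.0, 1.0, 4.0)])
        slope, se = pm.study_linear_trend(report)
        eff = pm.log_effect_from_ci(2.0, 1.0, 4.0)
        assert slope == pytest.approx(eff.y / 1.5, rel=1e-12)
        assert se == pytest.approx(eff.se / 1.5, rel=1e-12)

    def test_exactly_linear_data_recovered(self):
        beta = 0.21
        cats = []
        for dose, lo, hi in [(1, 1, 1), (2, 2, 2), (3, 3, 3)]:
            rr = math.exp(beta * dose)
            cats.append((str(dose), lo, hi, rr, rr * math.exp(-0.3), rr * math.exp(0.3)))
        slope, _se = pm.study_linear_trend(_report(cats))
        assert slope == pytest.approx(beta, rel=1e-12)

    def test_full_covariance_matches_matrix_oracle(self):
        report = _report(
            [("1", 1, 1, 1.2, 0.9, 1.6), ("2", 2, 2, 1.5, 1.0, 2.25), ("3", 3, 3, 1.4, 0.8, 2.45)]
        )
        doses = pm.assign_doses(report)
        x = doses.nonreference(report)
        y = np.array([math.log(c.rr) for c in report.exposure_categories])
        var = np.array(
            [
                ((math.log(c.ucl) - math.log(c.lcl)) / (2 * Z95)) ** 2
                for c in report.exposure_categories
            ]
        )
        cov = np.full((3, 3), 0.02)
        np.fill_diagonal(cov, var)
        slope, se = pm.study_linear_trend(report, doses, cov)
        ci = np.linalg.inv(cov)
        expected = float(x @ ci @ y) / float(x @ ci @ x)
        assert slope == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(float(x @ ci @ x) ** -0.5, rel=1e-12)

    def test_doubling_doses_halves_slope(self, by_id):
        report = by_id["rossing_2000"]
        base_d = pm.assign_doses(report)
        doubled = pm.DoseAssignment(
            tuple(2 * d for d in base_d.doses), base_d.rules
        )
        s1, se1 = pm.study_linear_trend(report, base_d)
        s2, se2 = pm.study_linear_trend(report, doubled)
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)
        assert se2 == pytest.approx(se1 / 2, rel=1e-12)

    def test_diagonal_gls_equals_wls_through_origin(self, by_id):
        report = by_id["galanti_1995"]
        doses = pm.assign_doses(report)
        slope, se = pm.study_linear_trend(report, doses)
        x = doses.nonreference(report)
        w, ys = [], []
        for c in report.exposure_categories:
            eff = pm.log_effect_from_ci(c.rr, c.lcl, c.ucl)
            w.append(1 / eff.se**2)
            ys.append(eff.y)
        w, ys = np.array(w), np.array(ys)
        assert slope == pytest.approx((w * x * ys).sum() / (w * x * x).sum(), rel=1e-12)
        assert se == pytest.approx((w * x * x).sum() ** -0.5, rel=1e-12)


class TestCovarianceReconstruction:
    def test_independent_is_diagonal_of_variances(self, by_id):
        report = by_id["memon_2002"]
        cov = pm.reconstruct_covariance(report, method="independent")
        var = [
            pm.log_effect_from_ci(c.rr, c.lcl, c.ucl).se ** 2
            for c in report.exposure_categories
        ]
        assert np.allclose(np.diag(cov), var)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0)

    @staticmethod
    def _crude_cc_report():
        """Crude 2x4 case-control table with a minority reference group."""
        a = np.array([15, 60, 45, 30])   # cases: ref + 3 categories
        b = np.array([20, 55, 40, 35])   # controls
        cats = []
        for i, (lo, hi) in enumerate([(1, 1), (2, 2), (3, 3)], start=1):
            orr = (a[i] / b[i]) / (a[0] / b[0])
            se = math.sqrt(1 / a[i] + 1 / b[i] + 1 / a[0] + 1 / b[0])
            cats.append(
                (str(lo), lo, hi, orr, orr * math.exp(-Z95 * se), orr * math.exp(Z95 * se),
                 int(a[i]), float(b[i]))
            )
        report = _report(
            cats, total_cases=int(a.sum()), total_subjects=int(b.sum()), rid="crude",
            ref_counts=(int(a[0]), float(b[0])),
        )
        return report, a, b

    def test_gl_counts_recovers_crude_covariance(self):
        report, a, b = self._crude_cc_report()
        cov = pm.reconstruct_covariance(report, method="gl_counts")
        # delta-method covariance of crude log odds ratios sharing the controls
        v0 = 1 / a[0] + 1 / b[0]
        for i in range(3):
            for j in range(3):
                expected = v0 if i != j else v0 + 1 / a[i + 1] + 1 / b[i + 1]
                assert cov[i, j] == pytest.approx(expected, rel=1e-6)

    def test_gl_counts_requires_denominators(self, by_id):
        with pytest.raises(NoDataError):
            pm.reconstruct_covariance(by_id["memon_2002"], method="gl_counts")

    def test_hamling_inverts_crude_counts(self):
        report, a, b = self._crude_cc_report()
        y = np.array([math.log(c.rr) for c in report.exposure_categories])
        var = np.array(
            [
                ((math.log(c.ucl) - math.log(c.lcl)) / (2 * Z95)) ** 2
                for c in report.exposure_categories
            ]
        )
        table = hamling_pseudocounts(report, y, var)
        assert table.ref_cases == pytest.approx(a[0], rel=1e-6)
        assert table.ref_denom == pytest.approx(b[0], rel=1e-6)
        assert np.allclose(table.cases, a[1:], rtol=1e-6)
        assert np.allclose(table.denoms, b[1:], rtol=1e-6)

    def test_hamling_rate_model_inverts_crude_counts(self):
        a = np.array([12, 40, 55, 30])          # cases, ref first
        pt = np.array([9000.0, 22000.0, 30000.0, 16000.0])
        cats = []
        for i, (lo, hi) in enumerate([(1, 1), (2, 2), (3, 3)], start=1):
            rr = (a[i] / pt[i]) / (a[0] / pt[0])
            se = math.sqrt(1 / a[i] + 1 / a[0])
            cats.append(
                (str(lo), lo, hi, rr, rr * math.exp(-Z95 * se), rr * math.exp(Z95 * se))
            )
        report = _report(
            cats, design="prospective", total_cases=int(a.sum()), total_subjects=80000,
            rid="rate",
        )
        y = np.array([math.log(c.rr) for c in report.exposure_categories])
        var = np.array(
            [
                ((math.log(c.ucl) - math.log(c.lcl)) / (2 * Z95)) ** 2
                for c in report.exposure_categories
            ]
        )
        table = hamling_pseudocounts(report, y, var)
        assert table.ref_cases == pytest.approx(a[0], rel=1e-6)
        assert np.allclose(table.cases, a[1:], rtol=1e-6)


class TestRcsBasis:
    KNOTS = (1.0, 3.0, 6.0)

    def test_zero_below_first_knot(self):
        _, b2 = rcs_basis(np.array([0.0, 0.5, 1.0]), self.KNOTS)
        assert np.allclose(b2, 0.0)

    def test_value_at_last_knot_matches_plugin(self):
        k1, k2, k3 = self.KNOTS
        _, b2 = rcs_basis(k3, self.KNOTS)
        expected = ((k3 - k1) ** 3 - (k3 - k2) ** 3 * (k3 - k1) / (k3 - k2)) / (k3 - k1) ** 2
        assert float(b2) == pytest.approx(expected, rel=1e-12)

    def test_linear_beyond_last_knot(self):
        grid = np.arange(6.0, 10.0, 0.25)
        _, b2 = rcs_basis(grid, self.KNOTS)
        second_diff = np.diff(b2, n=2)
        assert np.allclose(second_diff, 0.0, atol=1e-10)

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(DomainError):
            rcs_basis(2.0, (1.0, 1.0, 4.0))


class TestPooledTrend:
    def test_equal_se_slopes_average(self):
        r1 = _report([("1", 1, 1, math.exp(0.1), math.exp(0.1 - 0.2), math.exp(0.1 + 0.2))], rid="a")
        r2 = _report([("1", 1, 1, math.exp(0.3), math.exp(0.3 - 0.2), math.exp(0.3 + 0.2))], rid="b")
        res = pm.pooled_linear_trend([r1, r2])
        assert res.pooled_slope == pytest.approx(0.2, rel=1e-9)

    def test_fixture_knots_inside_dose_range(self, reports):
        knots = pooled_knots(reports)
        doses = np.concatenate(
            [pm.assign_doses(r).nonreference(r) for r in reports if r.exposure_categories]
        )
        assert doses.min() <= knots[0] < knots[1] < knots[2] <= doses.max()

    def test_fixture_trend_heterogeneity_significant(self, reports):
        res = pm.pooled_linear_trend(reports)
        assert res.pooled.p_het < 1e-4

    def test_too_few_distinct_doses_rejected(self):
        r1 = _report([("1", 1, 1, 1.2, 1.0, 1.44)], rid="a")
        r2 = _report([("1", 1, 1, 1.1, 0.9, 1.34)], rid="b")
        with pytest.raises(InsufficientDataError):
            pm.nonlinearity_test([r1, r2], knots=(0.5, 1.0, 2.0))

    def test_fixture_no_nonlinearity(self, reports):
        res = pm.dose_response_analysis(reports)
        assert res.lr_stat >= 0
        assert res.p_nonlinear > 0.05
        assert res.p_wald_nonlinear == pytest.approx(res.p_nonlinear, abs=0.05)

    def test_trend_and_curve_tables(self, reports):
        res = pm.dose_response_analysis(reports)
        table = trend_table(res)
        assert table.iloc[-1]["report_id"] == "POOLED"
        assert len(table) == len(res.per_study) + 1
        curve = spline_curve(res)
        assert {"dose", "rr", "lcl", "ucl"} <= set(curve.columns)
        assert curve.iloc[0]["rr"] == pytest.approx(1.0)  # anchored at dose 0


class TestNonlinearityBehaviour:
    def test_null_linear_truth_gives_uniform_p(self):
        """Under an exactly linear truth the LR p-values are uniform."""
        from scipy import stats as ss

        cfg = pm.SimulationConfig(
            n_studies=24,
            true_curve=("linear", 0.03),
            category_template=((1, 1), (2, 2), (3, 3), (4, None)),
            cases_per_study=(300, 1500),
        )
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(150):
            reports, _ = pm.simulate_catalog(cfg, rng)
            res = pm.nonlinearity_test(reports, cov_method="gl_counts")
            pvals.append(res.p_nonlinear)
        assert ss.kstest(pvals, "uniform").pvalue > 0.01

    def test_pronounced_curvature_detected(self):
        cfg = pm.SimulationConfig(
            n_studies=30,
            true_curve=("spline", 0.0, 0.9, (1.0, 2.5, 4.5)),
            category_template=((1, 1), (2, 2), (3, 3), (4, None)),
            cases_per_study=(2000, 8000),
        )
        rng = np.random.default_rng(29)
        rejections = 0
        n_reps = 60
        for _ in range(n_reps):
            reports, _ = pm.simulate_catalog(cfg, rng)
            res = pm.nonlinearity_test(reports, cov_method="gl_counts")
            rejections += res.p_nonlinear < 0.05
        assert rejections / n_reps > 0.8

    def test_slope_recovery_on_synthetic_literature(self):
        """Pooled per-birth slope recovers the generating coefficient."""
        beta = 0.05
        cfg = pm.SimulationConfig(
            n_studies=50,
            true_curve=("linear", beta),
            category_template=((1, 1), (2, 2), (3, 3), (4, None)),
            cases_per_study=(500, 2000),
        )
        rng = np.random.default_rng(31)
        estimates = []
        for _ in range(60):
            reports, _ = pm.simulate_catalog(cfg, rng)
            res = pm.pooled_linear_trend(reports, cov_method="gl_counts")
            estimates.append(res.pooled_slope)
        assert abs(np.mean(estimates) - beta) < 0.005
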