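import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mechcycle.assay import (
    AssayReading,
    DoseResponsePoint,
    activity_units,
    fit_probit,
    ic50_replicate_summary,
    percent_inhibition,
    plate_to_dose_response,
)


def reading(eb1, es, conc=0.1, rep="R1"):
    return AssayReading(replicate_id=rep, concentration=conc,
                        absorbance_blank_EB1=eb1, absorbance_sample_ES=es)


class TestActivityUnits:
    def test_half_absorbance(self):
        assert activity_units(reading(0.8, 0.4)).activity_units == pytest.approx(400.0)

    @given(st.floats(min_value=0.01, max_value=3.0))
    def test_equal_absorbance_is_zero(self, x):
        assert activity_units(reading(x, x)).activity_units == pytest.approx(0.0, abs=1e-9)

    def test_zero_sample_is_full_scale(self):
        assert activity_units(reading(0.611, 0.0)).activity_units == pytest.approx(800.0)

    def test_frozen_arithmetic(self):
        # (0.611 - 0.302) / 0.611 * 800, evaluated independently
        assert activity_units(reading(0.611, 0.302)).activity_units == pytest.approx(
            404.5826513911621, rel=1e-12)

    def test_sample_above_blank_flagged_not_rejected(self):
        result = activity_units(reading(0.5, 0.6))
        assert result.activity_units < 0
        assert result.warning is not None and "exceeds blank" in result.warning

    def test_nonpositive_blank_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            reading(0.0, 0.1)

    @given(st.floats(min_value=0.0, max_value=0.8),
           st.floats(min_value=0.0, max_value=0.8))
    def test_monotone_decreasing_in_sample(self, es1, es2):
        lo, hi = sorted([es1, es2])
        a_lo = activity_units(reading(0.8, lo)).activity_units
        a_hi = activity_units(reading(0.8, hi)).activity_units
        assert a_lo >= a_hi


class TestPercentInhibition:
    def test_no_change_is_zero(self):
        assert percent_inhibition(404.6, 404.6) == pytest.approx(0.0)

    def test_full_inhibition_is_hundred(self):
        assert percent_inhibition(0.0, 404.6) == pytest.approx(100.0)

    def test_frozen_group_means(self):
        # (404.6 - 228.3) / 404.6 * 100, evaluated independently
        assert percent_inhibition(228.3, 404.6) == pytest.approx(43.57390014829461,
                                                                 rel=1e-12)

    def test_activation_passes_through_negative(self):
        assert percent_inhibition(500.0, 400.0) == pytest.approx(-25.0)

    def test_printed_sign_compatibility_flag(self):
        assert percent_inhibition(228.3, 404.6, printed_sign=True) == pytest.approx(
            -43.57390014829461, rel=1e-12)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="activity_without"):
            percent_inhibition(10.0, 0.0)

    @given(st.floats(min_value=0.2, max_value=2.0),
           st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_blank_and_scale_cancel(self, eb1, f_sample, f_control):
        """With a shared blank, inhibition% reduces to
        (ES_sample − ES_control)/(EB1 − ES_control) × 100."""
        es_sample = eb1 * f_sample
        es_control = eb1 * f_control * 0.5  # keep control activity positive
        a = activity_units(reading(eb1, es_sample)).activity_units
        b = activity_units(reading(eb1, es_control)).activity_units
        expected = (es_sample - es_control) / (eb1 - es_control) * 100.0
        assert percent_inhibition(a, b) == pytest.approx(expected, rel=1e-9, abs=1e-9)


def probit_points(conc, intercept, slope, noise=None, rng=None):
    x = np.log10(np.asarray(conc))
    pct = 100.0 * stats.norm.cdf(intercept + slope * x)
    if noise is not None:
        pct = pct + rng.normal(0.0, noise, size=pct.size)
    return [DoseResponsePoint(c, p) for c, p in zip(conc, pct)]


class TestFitProbit:
    def test_exact_recovery_of_generating_curve(self):
        conc = np.geomspace(0.01, 10.0, 7)
        fit = fit_probit(probit_points(conc, intercept=1.3, slope=1.7))
        assert fit.converged
        assert fit.intercept == pytest.approx(1.3, rel=1e-6)
        assert fit.slope == pytest.approx(1.7, rel=1e-6)
        assert fit.ic50 == pytest.approx(10 ** (-1.3 / 1.7), rel=1e-6)

    def test_two_symmetric_points_pin_the_midpoint(self):
        c_star = 0.2
        points = [
            DoseResponsePoint(c_star / 10, 100 * stats.norm.cdf(-1.0)),
            DoseResponsePoint(c_star * 10, 100 * stats.norm.cdf(1.0)),
        ]
        fit = fit_probit(points)
        assert fit.ic50 == pytest.approx(c_star, rel=1e-9)

    def test_identical_proportions_fail_gracefully(self):
        points = [DoseResponsePoint(c, 50.0) for c in (0.1, 1.0, 10.0)]
        fit = fit_probit(points)
        assert not fit.converged
        assert "identical" in fit.message
        assert math.isnan(fit.ic50)

    def test_single_concentration_rejected(self):
        points = [DoseResponsePoint(1.0, 10.0), DoseResponsePoint(1.0, 90.0)]
        with pytest.raises(ValueError, match="distinct"):
            fit_probit(points)

    def test_deterministic(self):
        conc = np.geomspace(0.016, 1.6, 5)
        rng = np.random.default_rng(3)
        points = probit_points(conc, 1.0, 1.2, noise=3.0, rng=rng)
        assert fit_probit(points) == fit_probit(points)

    def test_extreme_percentages_are_clipped_not_fatal(self):
        points = [DoseResponsePoint(0.01, 0.0), DoseResponsePoint(0.1, 30.0),
                  DoseResponsePoint(1.0, 70.0), DoseResponsePoint(10.0, 100.0)]
        fit = fit_probit(points)
        assert fit.converged and math.isfinite(fit.ic50)

    def test_matches_independent_glm_fit(self):
        """Dual route: our IRLS against statsmodels' probit GLM."""
        sm = pytest.importorskip("statsmodels.api")
        conc = np.geomspace(0.016, 1.6, 6)
        rng = np.random.default_rng(8)
        points = probit_points(conc, 1.1, 1.4, noise=2.0, rng=rng)
        fit = fit_probit(points)
        y = np.clip([p.percent_inhibition / 100 for p in points], 1e-6, 1 - 1e-6)
        X = sm.add_constant(np.log10(conc))
        glm = sm.GLM(y, X, family=sm.families.Binomial(
            link=sm.families.links.Probit())).fit()
        assert fit.intercept == pytest.approx(glm.params[0], rel=1e-6)
        assert fit.slope == pytest.approx(glm.params[1], rel=1e-6)

    @pytest.mark.parametrize("scale", [0.1, 3.0])
    def test_concentration_rescaling_scales_ic50(self, scale):
        conc = np.geomspace(0.016, 1.6, 6)
        rng = np.random.default_rng(4)
        points = probit_points(conc, 1.2, 1.5, noise=2.0, rng=rng)
        base = fit_probit(points)
        scaled_points = [DoseResponsePoint(p.concentration * scale,
                                           p.percent_inhibition) for p in points]
        scaled = fit_probit(scaled_points)
        assert scaled.ic50 == pytest.approx(base.ic50 * scale, rel=1e-6)

    def test_extrapolation_flag(self):
        conc = [1.0, 2.0, 4.0, 8.0]
        fit = fit_probit(probit_points(conc, intercept=2.5, slope=1.0))
        # ic50 = 10^-2.5 lies far below the tested range
        assert fit.extrapolated

    def test_parameter_recovery_and_coverage(self):
        """200 seeded noisy replicates: median relative IC50 error < 10% and
        ±2·SE (delta method, log scale) coverage ≥ 80% at noise SD 3 points."""
        rng = np.random.default_rng(123)
        true_ic50, slope = 0.14, 1.5
        intercept = -slope * math.log10(true_ic50)
        conc = np.geomspace(0.016, 1.6, 5)
        errors, covered, n_ok = [], 0, 0
        for _ in range(200):
            fit = fit_probit(probit_points(conc, intercept, slope, noise=3.0, rng=rng))
            if not (fit.converged and math.isfinite(fit.ic50)):
                continue
            n_ok += 1
            errors.append(abs(fit.ic50 - true_ic50) / true_ic50)
            cov = np.array(fit.covariance)
            grad = np.array([-1.0 / fit.slope, fit.intercept / fit.slope ** 2])
            se_log = math.sqrt(grad @ cov @ grad)
            if abs(math.log10(fit.ic50) - math.log10(true_ic50)) <= 2 * se_log:
                covered += 1
        assert n_ok >= 190
        assert np.median(errors) < 0.10
        assert covered / n_ok >= 0.80


class TestReplicateSummary:
    def test_reference_replicates(self, table1_values):
        from mechcycle.assay import ProbitFit
        fits = [ProbitFit(intercept=0.0, slope=1.0, ic50=v, converged=True,
                          n_points=5, standard_errors=(0.1, 0.1))
                for v in table1_values.values()]
        summary = ic50_replicate_summary(fits)
        assert summary.mean == pytest.approx(0.1433333333, rel=1e-9)
        assert round(summary.mean, 2) == 0.14
        # SD/sqrt(6) of (0.15, 0.24, 0.11, 0.08, 0.14, 0.14), frozen
        assert summary.sem == pytest.approx(0.02201009869229224, rel=1e-9)

    def test_single_fit(self):
        from mechcycle.assay import ProbitFit
        fit = ProbitFit(0.0, 1.0, 0.2, True, 5, (0.1, 0.1))
        summary = ic50_replicate_summary([fit])
        assert summary.mean == 0.2 and summary.sem == 0.0
        assert summary.single_replicate

    def test_identical_values_zero_sem(self):
        from mechcycle.assay import ProbitFit
        fits = [ProbitFit(0.0, 1.0, 0.3, True, 5, (0.1, 0.1)) for _ in range(6)]
        summary = ic50_replicate_summary(fits)
        assert summary.mean == pytest.approx(0.3) and summary.sem == pytest.approx(0.0)

    def test_nonconverged_excluded_and_counted(self):
        from mechcycle.assay import ProbitFit
        good = ProbitFit(0.0, 1.0, 0.2, True, 5, (0.1, 0.1))
        bad = ProbitFit(float("nan"), float("nan"), float("nan"), False, 5,
                        (float("nan"), float("nan")))
        summary = ic50_replicate_summary([good, bad])
        assert summary.n_converged == 1 and summary.n_excluded == 1

    def test_zero_converged_rejected(self):
        from mechcycle.assay import ProbitFit
        bad = ProbitFit(float("nan"), float("nan"), float("nan"), False, 5,
                        (float("nan"), float("nan")))
        with pytest.raises(ValueError, match="converged"):
            ic50_replicate_summary([bad])


class TestPlateToDoseResponse:
    def test_requires_controls(self):
        with pytest.raises(ValueError, match="control"):
            plate_to_dose_response([reading(0.8, 0.4, conc=0.1)])

    def test_requires_inhibitor_rows(self):
        with pytest.raises(ValueError, match="inhibitor"):
            plate_to_dose_response([reading(0.8, 0.2, conc=0.0)])

    def test_basic_reduction(self):
        rows = [reading(0.8, 0.2, conc=0.0), reading(0.8, 0.5, conc=0.1)]
        points = plate_to_dose_response(rows)["R1"]
        assert len(points) == 1
        # activities: control 600, sample 300 -> 50% inhibition
        assert points[0].percent_inhibition == pytest.approx(50.0)
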