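"""Unit and property tests for the four-parameter logistic curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import baroreset as br
from baroreset.logistic import FitOptions, UnidentifiableDataError

valid_params = st.builds(
    br.LogisticParams,
    a1=st.floats(10.0, 300.0),
    a2=st.floats(0.02, 0.5),
    a3=st.floats(60.0, 180.0),
    a4=st.floats(0.0, 50.0),
)


class TestEvaluate:
    def test_midpoint_value(self, textbook_params):
        # Y(a3) = a1/2 + a4 exactly
        assert br.evaluate(textbook_params, 120.0) == pytest.approx(60.0, abs=1e-12)

    def test_plateau_limits(self, textbook_params):
        assert br.evaluate(textbook_params, 1e6) == pytest.approx(10.0, abs=1e-9)
        assert br.evaluate(textbook_params, -1e6) == pytest.approx(110.0, abs=1e-9)

    def test_value_at_threshold_is_95_percent_point(self, textbook_params):
        y = br.evaluate(textbook_params, 90.556)
        assert y == pytest.approx(10.0 + 0.95 * 100.0, abs=1e-3)

    def test_vectorizes_over_grid(self, textbook_params):
        p = np.linspace(60, 180, 7)
        y = br.evaluate(textbook_params, p)
        assert y.shape == p.shape
        assert np.all(np.diff(y) < 0)

    def test_overflow_guard_saturates(self, textbook_params):
        # exponent magnitude far beyond float range must not warn or overflow
        with np.errstate(over="raise"):
            lo = br.evaluate(textbook_params, 1e5)
        assert lo == pytest.approx(textbook_params.lower_plateau)

    def test_nonfinite_pressure_rejected(self, textbook_params):
        with pytest.raises(ValueError):
            br.evaluate(textbook_params, float("nan"))
        with pytest.raises(ValueError):
            br.evaluate(textbook_params, np.array([100.0, np.inf]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_midpoint_identity_property(self, params):
        assert br.evaluate(params, params.a3) == pytest.approx(
            params.a1 / 2 + params.a4, rel=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_strictly_decreasing_property(self, params):
        p = np.linspace(params.a3 - 60, params.a3 + 60, 200)
        y = br.evaluate(params, p)
        assert np.all(np.diff(y) < 0)


class TestGain:
    def test_max_gain_at_midpoint(self, textbook_params):
        assert br.gain_at(textbook_params, 120.0) == pytest.approx(2.5, rel=1e-12)

    def test_plateau_slope_vanishes(self, textbook_params):
        # 80 mmHg beyond the midpoint the slope is sech^2(4)-small
        assert br.gain_at(textbook_params, 40.0) < 0.01
        assert br.gain_at(textbook_params, 200.0) < 0.01

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=valid_params, delta=st.floats(0.1, 50.0))
    def test_symmetry_about_midpoint(self, params, delta):
        left = br.gain_at(params, params.a3 - delta)
        right = br.gain_at(params, params.a3 + delta)
        assert left == pytest.approx(right, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params=valid_params)
    def test_matches_central_finite_difference(self, params):
        m = br.curve_metrics(params)
        p = np.linspace(m.threshold, m.saturation, 21)
        h = 1e-5
        fd = np.abs(br.evaluate(params, p + h) - br.evaluate(params, p - h)) / (2 * h)
        assert np.allclose(br.gain_at(params, p), fd, rtol=1e-6)


class TestCurveMetrics:
    def test_textbook_values(self, textbook_params):
        m = br.curve_metrics(textbook_params)
        assert m.threshold == pytest.approx(90.556, abs=1e-3)
        assert m.saturation == pytest.approx(149.444, abs=1e-3)
        assert m.operating_range == pytest.approx(58.889, abs=1e-3)
        assert m.max_gain == pytest.approx(2.5, rel=1e-12)
        assert m.upper_plateau == 110.0 and m.lower_plateau == 10.0

    def test_invalid_params_rejected_at_construction(self):
        with pytest.raises(ValueError):
            br.LogisticParams(a1=-1.0, a2=0.1, a3=120.0, a4=0.0)
        with pytest.raises(ValueError):
            br.LogisticParams(a1=100.0, a2=0.0, a3=120.0, a4=0.0)
        with pytest.raises(ValueError):
            br.LogisticParams(a1=100.0, a2=0.1, a3=120.0, a4=-5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_closed_forms_match_root_finding(self, params):
        """Independent oracle: solve the 5% conditions by bracketed root
        finding on the curve itself and compare with the closed forms."""
        m = br.curve_metrics(params)
        y_thr = params.a4 + 0.95 * params.a1  # 5% of range below maximum
        y_sat = params.a4 + 0.05 * params.a1  # 5% of range above minimum
        span = 2000.0 / params.a2
        thr = brentq(lambda p: br.evaluate(params, p) - y_thr,
                     params.a3 - span, params.a3, xtol=1e-12)
        sat = brentq(lambda p: br.evaluate(params, p) - y_sat,
                     params.a3, params.a3 + span, xtol=1e-12)
        assert m.threshold == pytest.approx(thr, abs=1e-9)
        assert m.saturation == pytest.approx(sat, abs=1e-9)
        assert m.threshold < m.midpoint_pressure < m.saturation
        assert m.operating_range == pytest.approx(m.saturation - m.threshold)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params=valid_params)
    def test_max_gain_located_at_midpoint(self, params):
        p = np.linspace(params.a3 - 80, params.a3 + 80, 4001)
        g = br.gain_at(params, p)
        assert p[np.argmax(g)] == pytest.approx(params.a3, abs=p[1] - p[0])
        assert g.max() <= params.a1 * params.a2 / 4 + 1e-9


class TestFitLogistic:
    def test_noiseless_recovery(self, textbook_params):
        p = np.linspace(60, 180, 50)
        series = br.PressureSnaSeries(p, br.evaluate(textbook_params, p))
        fit = br.fit_logistic(series)
        assert fit.converged
        for est, true in zip(fit.params.as_tuple(), textbook_params.as_tuple()):
            assert est == pytest.approx(true, rel=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_noisy_recovery_within_stated_tolerances(self, textbook_params):
        p = np.linspace(60, 180, 200)
        rng = np.random.default_rng(42)
        y = np.maximum(0, br.evaluate(textbook_params, p) + rng.normal(0, 2.0, p.size))
        fit = br.fit_logistic(br.PressureSnaSeries(p, y), FitOptions(seed=42))
        assert fit.converged
        a1, a2, a3, a4 = fit.params.as_tuple()
        assert a1 == pytest.approx(100.0, rel=0.05)
        assert a4 == pytest.approx(10.0, rel=0.05)
        assert a3 == pytest.approx(120.0, abs=2.0)
        assert a2 == pytest.approx(0.1, rel=0.10)

    def test_deterministic_given_series_and_options(self, textbook_params):
        p = np.linspace(60, 180, 80)
        rng = np.random.default_rng(1)
        y = np.maximum(0, br.evaluate(textbook_params, p) + rng.normal(0, 3.0, p.size))
        s = br.PressureSnaSeries(p, y)
        f1 = br.fit_logistic(s, FitOptions(seed=5))
        f2 = br.fit_logistic(s, FitOptions(seed=5))
        assert f1.params == f2.params

    def test_flat_response_unidentifiable(self):
        p = np.linspace(60, 180, 50)
        with pytest.raises(UnidentifiableDataError):
            br.fit_logistic(br.PressureSnaSeries(p, np.full(50, 40.0)))

    def test_too_few_points_or_narrow_span_rejected(self, textbook_params):
        p = np.linspace(60, 180, 5)
        with pytest.raises(UnidentifiableDataError):
            br.fit_logistic(br.PressureSnaSeries(p, br.evaluate(textbook_params, p)))
        p = np.linspace(115, 125, 30)
        with pytest.raises(UnidentifiableDataError):
            br.fit_logistic(br.PressureSnaSeries(p, br.evaluate(textbook_params, p)))


class TestSeriesContainer:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            br.PressureSnaSeries(np.arange(5.0), np.arange(4.0))

    def test_negative_sna_rejected(self):
        with pytest.raises(ValueError):
            br.PressureSnaSeries(np.array([100.0, 110.0]), np.array([5.0, -1.0]))

    def test_normalization_to_resting_level(self):
        s = br.PressureSnaSeries(np.array([100.0, 110.0]), np.array([50.0, 25.0]))
        n = s.normalized(resting_sna=50.0)
        assert np.allclose(n.sna, [100.0, 50.0])
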