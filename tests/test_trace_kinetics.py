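"""Trace readouts: exponential-rise fitting, rates, areas, disaggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plateletkin import (
    Trace,
    auc,
    disaggregation_percent,
    fit_exponential_rise,
    initial_rate,
)
from plateletkin.errors import DegenerateFitError, TraceRangeError
from plateletkin.trace import estimate_baseline, detect_onset, normalize_to_control


class TestExponentialFit:
    @pytest.mark.parametrize("k", [0.19, 0.03])
    def test_noiseless_recovery_of_measured_constants(self, eq5_trace, k):
        res = fit_exponential_rise(eq5_trace(k, t_end=max(60.0, 5 / k)),
                                   "LSI12")
        assert res.k == pytest.approx(k, rel=1e-3)
        assert res.i_m == pytest.approx(100.0, rel=1e-6)
        assert res.r2 == pytest.approx(1.0)
        assert res.ok

    @given(k=st.floats(1e-3, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_unbiased_across_rate_range(self, k):
        t = np.arange(0.0, 5.0 / k + 0.05, 0.1)
        tr = Trace(t, {"LSI12": 100.0 * (1.0 - np.exp(-k * t))})
        res = fit_exponential_rise(tr, "LSI12")
        assert abs(res.k - k) / k < 1e-3

    def test_noisy_recovery_median_under_five_percent(self, eq5_trace):
        k = 0.19
        errs = []
        for seed in range(100):
            tr = eq5_trace(k, noise_sd=2.0, seed=seed)
            errs.append(abs(fit_exponential_rise(tr, "LSI12").k - k) / k)
        assert np.median(errs) < 0.05

    def test_constant_trace_is_degenerate(self):
        t = np.arange(0, 30, 0.1)
        with pytest.raises(DegenerateFitError):
            fit_exponential_rise(Trace(t, {"LSI12": np.full_like(t, 7.0)}),
                                 "LSI12")

    def test_window_and_onset_anchor(self, eq5_trace):
        # signal starting at t = 10 s, fitted on an anchored window
        tr = eq5_trace(0.1, t_end=80.0)
        shifted = Trace(tr.t + 10.0, dict(tr.channels))
        res = fit_exponential_rise(shifted, "LSI12", window=(10.0, 90.0),
                                   t0=10.0)
        assert res.k == pytest.approx(0.1, rel=1e-6)

    def test_too_few_samples_rejected(self, eq5_trace):
        with pytest.raises(ValueError):
            fit_exponential_rise(eq5_trace(0.1), "LSI12", window=(0.0, 0.5))


class TestInitialRate:
    def test_linear_ramp(self):
        t = np.arange(0, 40, 0.1)
        tr = Trace(t, {"LSI1": 2.0 * t})
        for te in (5.0, 20.0):
            assert initial_rate(tr, "LSI1", te) == pytest.approx(2.0)

    def test_flat_trace_zero_rate(self):
        t = np.arange(0, 40, 0.1)
        assert initial_rate(Trace(t, {"LSI1": np.ones_like(t)}), "LSI1",
                            20.0) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_tangent_oracle(self, eq5_trace):
        # analytic derivative of the saturation curve at 5 s
        expected = 100 * 0.19 * np.exp(-0.19 * 5.0)
        tr = eq5_trace(0.19)
        assert initial_rate(tr, "LSI12", 5.0, half_window=0.5) == pytest.approx(
            expected, rel=2e-3
        )
        # the default +-2 s regression window carries a small curvature bias
        assert initial_rate(tr, "LSI12", 5.0) == pytest.approx(expected,
                                                               rel=0.02)

    def test_out_of_range_rejected(self, eq5_trace):
        with pytest.raises(TraceRangeError):
            initial_rate(eq5_trace(0.19, t_end=30.0), "LSI12", 40.0)


class TestAUC:
    def test_constant_and_ramp_areas(self):
        t = np.arange(0, 130, 0.1)
        assert auc(Trace(t, {"LSI1": np.ones_like(t)}), "LSI1", 120.0,
                   baseline=0.0) == pytest.approx(120.0)
        t = np.arange(0, 21, 0.1)
        assert auc(Trace(t, {"FL527": 0.5 * t}), "FL527", 20.0,
                   baseline=0.0) == pytest.approx(100.0)

    def test_closed_form_saturation_area(self, eq5_trace):
        k, im = 0.19, 100.0
        tr = eq5_trace(k, t_end=120.0)
        expected = im * 120.0 - (im / k) * (1 - np.exp(-k * 120.0))
        assert auc(tr, "LSI12", 120.0, baseline=0.0) == pytest.approx(
            expected, rel=1e-4
        )

    def test_riemann_oracle(self, eq5_trace):
        tr = eq5_trace(0.05, t_end=120.0)
        y = tr.channel("LSI12")
        oracle = float(np.sum((y[1:] + y[:-1]) / 2 * np.diff(tr.t)))
        assert auc(tr, "LSI12", 120.0, baseline=0.0) == pytest.approx(
            oracle, rel=1e-9
        )

    def test_window_overrun_rejected(self, eq5_trace):
        with pytest.raises(TraceRangeError):
            auc(eq5_trace(0.1, t_end=60.0), "LSI12", 120.0)


class TestDisaggregation:
    def _trace(self, final):
        t = np.arange(0, 100, 0.5)
        y = np.where(t < 50, 2.0 * t, 100.0 + (final - 100.0) *
                     (t - 50) / 49.5)
        return Trace(t, {"LSI1": y})

    def test_monotone_rise_gives_zero(self):
        t = np.arange(0, 50, 0.5)
        assert disaggregation_percent(Trace(t, {"LSI1": t}), "LSI1",
                                      baseline=0.0) == 0.0

    @pytest.mark.parametrize("final,expected", [(0.0, 100.0), (50.0, 50.0)])
    def test_partial_and_complete_decay(self, final, expected):
        assert disaggregation_percent(self._trace(final), "LSI1",
                                      baseline=0.0) == pytest.approx(expected)

    def test_affine_invariance(self):
        tr = self._trace(30.0)
        v1 = disaggregation_percent(tr, "LSI1", baseline=0.0)
        tr2 = Trace(tr.t, {"LSI1": 3.0 * tr.channel("LSI1") + 17.0})
        v2 = disaggregation_percent(tr2, "LSI1", baseline=17.0)
        assert v1 == pytest.approx(v2)

    def test_flat_trace_rejected(self):
        t = np.arange(0, 50, 0.5)
        with pytest.raises(DegenerateFitError):
            disaggregation_percent(Trace(t, {"LSI1": np.ones_like(t)}),
                                   "LSI1", baseline=1.0)


class TestBaselineAndOnset:
    def test_baseline_from_pre_event_window(self):
        t = np.arange(0, 30, 0.1)
        y = np.where(t < 10, 3.0, 50.0)
        tr = Trace(t, {"LSI12": y},
                   annotations={"events": [{"t": 10.0}]})
        assert estimate_baseline(tr, "LSI12") == pytest.approx(3.0)
        assert detect_onset(tr, "LSI12") == pytest.approx(10.0, abs=0.2)

    def test_normalize_to_control(self):
        assert normalize_to_control(5.0, 10.0) == pytest.approx(50.0)
        with pytest.raises(ZeroDivisionError):
            normalize_to_control(1.0, 0.0)
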