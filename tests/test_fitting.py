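"""Spike fitting, nested-model F-test and selection filters."""

import numpy as np
import pytest

from spikefit.extract import FluoTrace
from spikefit.fitting import (
    Algorithm,
    FitSettings,
    RobustMode,
    apply_selection,
    default_bounds,
    f_test_nested,
    fit_constant,
    fit_spike,
)
from spikefit.model import SpikeParams, evaluate_spike

from conftest import random_valid_params


def make_trace(values, times=None, baseline_sd=0.0):
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return FluoTrace(times=times, values=values, baseline_sd=baseline_sd)


def noise_free_trace(params: SpikeParams, n=512, dt=1.0, t_start=-50.0):
    t = t_start + dt * np.arange(n)
    return make_trace(evaluate_spike(params, t), times=t)


class TestFitConstant:
    def test_equal_values(self):
        out = fit_constant(make_trace([3.0] * 30))
        assert out == {"c": 3.0, "SSE0": 0.0}

    def test_two_values(self):
        out = fit_constant(make_trace([0.0, 1.0]))
        assert out["c"] == 0.5 and out["SSE0"] == 0.5

    def test_gaussian_variance_within_chi2_bounds(self):
        rng = np.random.RandomState(2)
        n, s = 1000, 0.15
        out = fit_constant(make_trace(rng.normal(0, s, n)))
        var = out["SSE0"] / (n - 1)
        se = s**2 * np.sqrt(2.0 / (n - 1))
        assert var == pytest.approx(s**2, abs=3 * se)


class TestFTest:
    def test_equal_sse_gives_p_one(self):
        out = f_test_nested(10.0, 10.0, 100)
        assert out["F_stat"] == 0.0 and out["p_value"] == 1.0

    def test_worked_example_against_f_distribution_oracle(self):
        out = f_test_nested(100.0, 120.0, 100)
        assert out["F_stat"] == pytest.approx(4.75)
        # oracle: numeric integration of the F(4, 95) density
        assert out["p_value"] == pytest.approx(0.0015455866, rel=1e-6)

    def test_p_monotone_in_sse1(self):
        ps = [f_test_nested(s, 120.0, 100)["p_value"] for s in (110.0, 100.0, 80.0, 40.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_worse_than_constant_is_p_one(self):
        assert f_test_nested(130.0, 120.0, 100)["p_value"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            f_test_nested(1.0, 2.0, 5)


class TestFitSpike:
    def test_noise_free_recovery_from_truth_init(self):
        truth = SpikeParams(t0=4.2, FM=2.0, alpha=0.05, tauA=2.2, tauT=4.5)
        fit = fit_spike(noise_free_trace(truth), FitSettings(init=truth))
        assert np.allclose(fit.params.as_array(), truth.as_array(), rtol=1e-6)
        assert fit.accepted and fit.SSE1 < 1e-15

    def test_noise_free_recovery_from_perturbed_init(self):
        # constrained trust region from init = truth +/- 20 %
        rng = np.random.RandomState(13)
        lb, ub = default_bounds()
        count = 0
        for truth in random_valid_params(rng, 100, tau_floor=1.1, alpha_max=0.3):
            x = truth.as_array()
            perturbed = np.clip(x * (1 + 0.2 * rng.choice([-1, 1], 5)), lb + 1e-9, ub)
            init = SpikeParams.from_array(perturbed)
            fit = fit_spike(noise_free_trace(truth), FitSettings(init=init))
            if np.allclose(fit.params.as_array(), x, rtol=1e-4, atol=1e-7):
                count += 1
        assert count >= 97  # a rare perturbed init may land in another basin

    def test_acceptance_on_noise_free_small_amplitude(self):
        truth = SpikeParams(t0=4.0, FM=0.03, alpha=0.05, tauA=2.0, tauT=4.0)
        fit = fit_spike(noise_free_trace(truth), FitSettings(init=truth))
        assert fit.accepted

    def test_pure_noise_rejected_by_f_test(self):
        from spikefit.simulate import OG5N
        rng = np.random.RandomState(21)
        t = np.arange(-50.0, 462.0)
        trace = make_trace(rng.normal(0, 0.15, t.size), times=t, baseline_sd=0.15)
        fit = fit_spike(trace, FitSettings(init=OG5N.param_means))
        assert not fit.accepted and fit.p_value > 0.05

    def test_constrained_fit_respects_bounds(self):
        truth = SpikeParams(t0=4.0, FM=1.5, alpha=0.02, tauA=0.4, tauT=0.6)  # below tau floor
        fit = fit_spike(noise_free_trace(truth), FitSettings(init=SpikeParams(4.0, 1.5, 0.02, 2.0, 4.0)))
        assert fit.params.tauA >= 1.0 and fit.params.tauT >= 1.0
        assert "tauA" in fit.at_boundary or "tauT" in fit.at_boundary

    def test_lm_and_gn_reject_constraints(self):
        init = SpikeParams(4.0, 1.0, 0.05, 2.0, 4.0)
        for alg in (Algorithm.LEVENBERG_MARQUARDT, Algorithm.GAUSS_NEWTON):
            with pytest.raises(ValueError):
                FitSettings(init=init, algorithm=alg, constrained=True)

    @pytest.mark.parametrize("alg", [Algorithm.SIMPLEX, Algorithm.LEVENBERG_MARQUARDT,
                                     Algorithm.GAUSS_NEWTON])
    def test_alternative_algorithms_recover_noise_free_spike(self, alg):
        truth = SpikeParams(t0=4.2, FM=2.0, alpha=0.05, tauA=2.2, tauT=4.5)
        settings = FitSettings(init=truth, algorithm=alg,
                               constrained=(alg is Algorithm.SIMPLEX))
        fit = fit_spike(noise_free_trace(truth), settings)
        assert np.allclose(fit.params.as_array(), truth.as_array(), rtol=1e-3)

    @pytest.mark.parametrize("robust", [RobustMode.LAR, RobustMode.BISQUARE])
    def test_robust_modes_tolerate_outliers(self, robust):
        truth = SpikeParams(t0=4.2, FM=2.0, alpha=0.05, tauA=2.2, tauT=4.5)
        trace = noise_free_trace(truth)
        values = trace.values.copy()
        values[200] += 25.0  # gross outlier
        corrupted = make_trace(values, times=trace.times)
        fit = fit_spike(corrupted, FitSettings(init=truth, robust=robust))
        plain = fit_spike(corrupted, FitSettings(init=truth))
        err_robust = np.linalg.norm(fit.params.as_array() - truth.as_array())
        err_plain = np.linalg.norm(plain.params.as_array() - truth.as_array())
        assert err_robust < err_plain

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_spike(make_trace(np.zeros(10)), FitSettings(init=SpikeParams(4, 1, 0.05, 2, 4)))


class TestSelection:
    def _fit(self, **kw):
        truth = SpikeParams(**{**dict(t0=4.2, FM=2.0, alpha=0.05, tauA=2.2, tauT=4.5), **kw})
        return fit_spike(noise_free_trace(truth), FitSettings(init=truth, constrained=False))

    def test_all_cuts_satisfied_passes(self):
        assert apply_selection(self._fit(), "A")

    def test_small_activation_time_fails(self):
        assert not apply_selection(self._fit(tauA=0.5), "A")

    def test_late_latency_fails(self):
        assert not apply_selection(self._fit(t0=85.0), "A")

    def test_undefined_fdhm_fails_selection_a(self):
        assert not apply_selection(self._fit(alpha=1.0), "A")

    def test_selection_b_thresholds_amplitude(self):
        fit = self._fit()
        assert apply_selection(fit, "B", noise_sd=0.15, snr_threshold=2.0)
        assert not apply_selection(fit, "B", noise_sd=0.15, snr_threshold=1e3)

    def test_selection_b_requires_noise_sd(self):
        with pytest.raises(ValueError):
            apply_selection(self._fit(), "B", noise_sd=None)
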