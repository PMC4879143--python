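"""Forward-model unit and property tests: peripheral stages, PSP closed
form vs an independent ODE solve, hazard integration, and the threshold
solver."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import nocidet as nd
from nocidet.model import psc, psp_values, stimulus_drive


class TestPeripheralStages:
    @pytest.mark.parametrize("a, pw, tau1, expected", [
        (0.0, 0.21, 0.2, 0.0),
        (0.22, 0.525, 0.2, 0.22 * (1 - math.exp(-2.625))),
        (1.0, 1e6, 0.2, 1.0),  # saturation for very long pulses
    ])
    def test_effective_amplitude(self, a, pw, tau1, expected):
        assert nd.effective_amplitude(a, pw, tau1) == pytest.approx(expected, abs=1e-12)

    def test_effective_amplitude_example_value(self):
        # 0.22 mA at PW = 0.525 ms attenuates to 0.204064 mA
        assert nd.effective_amplitude(0.22, 0.525, 0.2) == pytest.approx(0.204064, abs=2e-6)

    @pytest.mark.parametrize("pw, tau1", [(0.0, 0.2), (-1.0, 0.2), (0.2, 0.0)])
    def test_effective_amplitude_domain_errors(self, pw, tau1):
        with pytest.raises(ValueError):
            nd.effective_amplitude(0.1, pw, tau1)

    @pytest.mark.parametrize("fa, alpha1, expected", [
        (0.125, 0.125, 0.0),
        (0.1, 0.125, 0.0),
        (0.204064, 0.125, math.pi * 0.079064),
    ])
    def test_peripheral_drive(self, fa, alpha1, expected):
        assert nd.peripheral_drive(fa, alpha1) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 5.0), st.floats(0.01, 2.0), st.floats(0.01, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_effective_amplitude_bounded_by_amplitude(self, a, pw, tau1):
        fa = nd.effective_amplitude(a, pw, tau1)
        assert 0.0 <= fa <= a


class TestPostsynapticCurrent:
    def test_onset_value(self, ref_params):
        stim = nd.StimulusTrain(nop=1, pw=0.525, amplitude=0.22)
        d = stimulus_drive(stim, ref_params)
        assert d == pytest.approx(math.pi * 0.079064, abs=5e-6)
        assert psc(0.0, stim, d, 1.5) == pytest.approx(d / 1.5)
        assert psc(0.0, stim, d, 1.5) == pytest.approx(0.165591, abs=1e-5)

    def test_heaviside_gate_before_first_pulse(self):
        stim = nd.StimulusTrain(nop=1, pw=0.525, amplitude=0.22)
        assert psc(-0.5, stim, 0.248386, 1.5) == 0.0

    def test_superposition_at_second_pulse(self):
        stim = nd.StimulusTrain(nop=2, ipi=20.0, pw=0.525, amplitude=0.22)
        d = 0.248386
        got = psc(20.0, stim, d, 1.5)
        expected = d / 1.5 * (1.0 + math.exp(-20.0 / 1.5))
        assert got == pytest.approx(expected, rel=1e-12)


class TestPSP:
    def test_zero_amplitude_trace_is_zero(self, ref_params, config, double20):
        trace = nd.psp(double20.with_amplitude(0.0), ref_params, config)
        assert np.all(trace.values == 0.0)

    def test_peak_in_instantaneous_synapse_limit(self, ref_params):
        # As tau_s -> 0 the per-pulse peak tends to B = D/tau2 = 0.0055197
        params = dataclasses.replace(ref_params, tau_s=1e-6)
        stim = nd.StimulusTrain(nop=1, pw=0.525, amplitude=0.22)
        t = np.linspace(0.0, 0.001, 2001)
        peak = psp_values(t, stim, params).max()
        assert peak == pytest.approx(0.0055197, rel=1e-3)

    def test_nonnegative_and_decaying(self, ref_params, config, double50):
        trace = nd.psp(double50.with_amplitude(0.3), ref_params, config)
        assert np.all(trace.values >= 0.0)
        # T = last pulse + 15*tau2, so the PSP has decayed by ~e^-15
        assert trace.values[-1] < 1e-5 * trace.values.max()

    @pytest.mark.parametrize("nop, ipi", [(1, None), (2, 20.0), (3, 12.5)])
    def test_closed_form_matches_ode_integration(self, ref_params, nop, ipi):
        """The superposition closed form must agree with a stiff ODE solve
        of the leaky integrator to 1e-8 relative, across random parameter
        draws at 0.5-2x reference."""
        rng = np.random.default_rng(42)
        for _ in range(4):
            f = rng.uniform(0.5, 2.0, size=4)
            params = dataclasses.replace(
                ref_params, tau1=ref_params.tau1 * f[0],
                tau2=ref_params.tau2 * f[1], tau_s=ref_params.tau_s * f[2],
                alpha1=ref_params.alpha1 * f[3])
            stim = nd.StimulusTrain(nop=nop, ipi=ipi, pw=0.525,
                                    amplitude=rng.uniform(0.3, 1.0))
            d = stimulus_drive(stim, params)
            t_end = float(stim.pulse_times[-1]) + 5 * params.tau2
            t_eval = np.linspace(0.0, t_end, 400)

            # piecewise solve so pulse-onset jumps in the forcing are exact
            edges = list(stim.pulse_times) + [t_end]
            x0, ts, xs = 0.0, [], []
            for a, b in zip(edges[:-1], edges[1:]):
                t_sub = t_eval[(t_eval >= a) & (t_eval < b)]
                sol = solve_ivp(
                    lambda t, x: (-x + psc(t, stim, d, params.tau_s)) / params.tau2,
                    (a, b), [x0], method="LSODA", rtol=1e-11, atol=1e-14,
                    t_eval=np.append(t_sub, b), max_step=1.0)
                x0 = sol.y[0, -1]
                ts.append(sol.t[:-1]), xs.append(sol.y[0][:-1])
            t_all, x_ode = np.concatenate(ts), np.concatenate(xs)
            x_closed = psp_values(t_all, stim, params)
            scale = np.max(np.abs(x_ode))
            assert np.max(np.abs(x_closed - x_ode)) < 1e-8 * scale

    def test_degenerate_equal_time_constants(self, ref_params):
        params = dataclasses.replace(ref_params, tau_s=ref_params.tau2)
        stim = nd.StimulusTrain(nop=1, pw=0.525, amplitude=0.22)
        t = np.linspace(0.0, 200.0, 500)
        x = psp_values(t, stim, params)
        assert np.all(np.isfinite(x)) and x.max() > 0


class TestFiringRate:
    def test_sigmoid_midpoint(self, ref_params):
        assert nd.firing_rate(ref_params.alpha_l, ref_params) == pytest.approx(0.005)

    def test_rest_is_negligible(self, ref_params):
        assert nd.firing_rate(0.0, ref_params) < 1e-20

    def test_saturation(self, ref_params):
        assert nd.firing_rate(1.0, ref_params) == pytest.approx(ref_params.lambda_l)

    def test_overflow_guard_returns_exact_zero(self, ref_params):
        params = dataclasses.replace(ref_params, sigma_l=1e-9)
        assert nd.firing_rate(0.0, params) == 0.0

    @given(st.floats(0.0, 0.1), st.floats(0.0, 0.1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, x1, x2):
        params = nd.LumpedParams.reference()
        lo, hi = sorted((x1, x2))
        r1, r2 = nd.firing_rate(lo, params), nd.firing_rate(hi, params)
        assert 0.0 <= r1 <= r2 <= params.lambda_l


class TestExpectedCountAndPsychometric:
    def test_zero_amplitude_count_negligible(self, ref_params, config, single_p21):
        assert nd.expected_count(single_p21.with_amplitude(0.0), ref_params,
                                 config) < 1e-18

    def test_window_extension_invariance(self, ref_params, config, double20):
        stim = double20.with_amplitude(0.3)
        base = nd.expected_count(stim, ref_params, config)
        longer = dataclasses.replace(config, tail_factor=30.0)
        assert nd.expected_count(stim, ref_params, longer) == pytest.approx(
            base, abs=10 * config.quad_tol)

    def test_psychometric_nondecreasing_in_amplitude(self, ref_params, config,
                                                     double20):
        amps = np.linspace(0.0, 1.0, 41)
        psis = [nd.psychometric(double20.with_amplitude(a), ref_params, config)
                for a in amps]
        assert psis[0] < 1e-10
        assert all(b >= a - 1e-12 for a, b in zip(psis, psis[1:]))
        assert all(0.0 <= p < 1.0 for p in psis)


class TestDetectionThreshold:
    def test_reference_thresholds_near_closed_form(self, ref_params, config,
                                                   single_p21, double20):
        # closed-form sigmaL->0, tauS->0 oracle values; numeric tracks
        # them within the 2% the full model allows
        assert nd.detection_threshold(single_p21, ref_params, config).a50 == \
            pytest.approx(0.62102, rel=0.02)
        assert nd.detection_threshold(double20, ref_params, config).a50 == \
            pytest.approx(0.252140, rel=0.02)

    def test_psi_closure_all_reference_combos(self, ref_params, config):
        for stim in nd.REFERENCE_COMBOS:
            res = nd.detection_threshold(stim, ref_params, config)
            assert abs(res.psi_at_a50 - 0.5) <= 10 * config.quad_tol

    def test_threshold_rises_with_afferent_threshold(self, ref_params, config,
                                                     double20):
        harder = dataclasses.replace(ref_params, alpha1=2 * ref_params.alpha1)
        a_ref = nd.detection_threshold(double20, ref_params, config).a50
        a_hard = nd.detection_threshold(double20, harder, config).a50
        assert a_hard > a_ref

    def test_converges_to_analytic_in_sharp_limit(self, ref_params):
        """With sigma_l and tau_s scaled down 100x, the numeric threshold
        approaches the closed-form limit to < 0.1% relative."""
        limit = dataclasses.replace(ref_params, sigma_l=8.33e-7, tau_s=0.015)
        for stim in (nd.StimulusTrain(nop=1, pw=0.21),
                     nd.StimulusTrain(nop=2, ipi=50.0, pw=0.525)):
            num = nd.detection_threshold(stim, limit).a50
            ana = nd.analytic_threshold(stim, ref_params).a50
            assert abs(num - ana) / ana < 1e-3

    def test_ill_posed_when_baseline_hazard_high(self, config, single_p21):
        params = nd.LumpedParams(alpha_l=1e-6, sigma_l=1.0)
        with pytest.raises(ValueError, match="ill-posed"):
            nd.detection_threshold(single_p21, params, config)

    def test_unreachable_when_bracket_capped(self, ref_params, single_p21):
        tight = nd.ModelConfig(amplitude_bracket_max=0.2)
        with pytest.raises(ValueError, match="unreachable"):
            nd.detection_threshold(single_p21, ref_params, tight)

    def test_threshold_table_columns(self, ref_params, config):
        df = nd.threshold_table(nd.REFERENCE_COMBOS, ref_params, config)
        assert len(df) == 4
        assert list(df.columns) == ["NoP", "IPI_ms", "PW_ms", "A50_mA",
                                    "psi_at_A50", "solver_iterations"]


class TestStimulusValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(nop=0, pw=0.21),
        dict(nop=1, pw=0.0),
        dict(nop=2, pw=0.525),            # missing IPI
        dict(nop=2, pw=0.525, ipi=-5.0),
        dict(nop=1, pw=0.21, amplitude=-0.1),
    ])
    def test_invalid_stimuli_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nd.StimulusTrain(**kwargs)
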