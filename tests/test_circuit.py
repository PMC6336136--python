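"""Circuit dynamics: stimuli, PPTg response, steady states and full trials."""

import dataclasses
import math

import numpy as np
import pytest

from vtacircuit.circuit import (
    CircuitParams,
    LearnableWeights,
    TrialProtocol,
    input_currents,
    pfc_step,
    pptg_rate,
    simulate_trial,
    stimulus_signals,
    vta_step,
)
from vtacircuit.transfer import hill_response


class TestStimulusSignals:
    def test_cs_window_and_us_amplitude(self, protocol):
        t, cs, us = stimulus_signals(protocol)
        assert np.all(cs[(t >= 0.5) & (t < 1.0)] == 1.0)
        assert np.all(cs[(t < 0.5) | (t >= 1.0)] == 0.0)
        assert np.all(us[(t >= 2.0) & (t < 2.5)] == 4.0)
        assert np.all(us[(t < 2.0) | (t >= 2.5)] == 0.0)

    def test_omission_zeroes_the_us(self, protocol):
        proto = dataclasses.replace(protocol, reward_omitted=True)
        _, _, us = stimulus_signals(proto)
        assert np.all(us == 0.0)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            TrialProtocol(cs_onset=1.8, cs_duration=0.5)  # CS overlaps US
        with pytest.raises(ValueError):
            TrialProtocol(us_onset=2.8)  # US spills past trial end


class TestPptgRate:
    def test_zero_reward_gives_zero_rate(self, params, protocol):
        _, _, us = stimulus_signals(
            dataclasses.replace(protocol, reward_omitted=True), params.dt
        )
        assert np.all(pptg_rate(us, params) == 0.0)

    def test_phasic_peak_time_and_amplitude(self, params, protocol):
        """Burst peaks tau_pptg after reward onset at f(reward)/e."""
        t, _, us = stimulus_signals(protocol, params.dt)
        nu = pptg_rate(us, params)
        t_peak = t[int(np.argmax(nu))]
        assert t_peak == pytest.approx(
            protocol.us_onset + params.tau_pptg / 1000.0, abs=2 * params.dt / 1000.0
        )
        expected = hill_response(4.0, params.pptg_hill) / math.e
        assert np.max(nu) == pytest.approx(expected, rel=0.02)


class TestInputCurrents:
    def test_all_zero_inputs_give_zero_currents(self, params, naive_weights):
        assert input_currents(0, 0, 0, 0, naive_weights, params) == (0, 0, 0, 0)

    def test_current_arithmetic(self, params):
        w = LearnableWeights(j_pfc=0.2, w_pfc_d=0.5, w_pfc_g=0.5)
        i_g_d, i_glu_d, i_glu_g, i_a4b2 = input_currents(10.0, 8.0, 14.0, 0.2, w, params)
        assert i_g_d == pytest.approx(params.w_g_d * 14.0)  # ~15.36
        assert i_glu_d == pytest.approx(0.5 * 10.0 + params.w_ppt_d * 8.0)
        assert i_glu_g == pytest.approx(0.5 * 10.0 + params.w_ppt_g * 8.0)
        assert i_a4b2 == pytest.approx(15.0 * 0.2)  # = 3


class TestPfcStep:
    def test_rest_is_a_fixed_point_up_to_sigmoid_floor(self, params, naive_weights):
        nu, a = 0.0, 0.0
        for _ in range(5000):
            nu, a = pfc_step(nu, a, 0.0, naive_weights, params, params.dt)
        assert nu < 1.0  # the quiescent state (sigmoid floor keeps it slightly >0)

    def test_cs_drives_the_high_branch(self, params, naive_weights):
        nu, a = 0.0, 0.0
        for _ in range(500):  # 0.5 s of CS
            nu, a = pfc_step(nu, a, 1.0, naive_weights, params, params.dt)
        assert nu > 25.0  # Up state reached within the CS

    def test_bistability_after_learning(self, params):
        """With strong recurrence the Up state survives CS offset until
        adaptation destabilizes it."""
        w = LearnableWeights(j_pfc=1.2, w_pfc_d=0.0, w_pfc_g=0.0)
        nu, a = 0.0, 0.0
        for _ in range(500):
            nu, a = pfc_step(nu, a, 1.0, w, params, params.dt)
        for _ in range(300):  # 0.3 s past CS offset
            nu, a = pfc_step(nu, a, 0.0, w, params, params.dt)
        assert nu > 20.0  # still up
        for _ in range(2500):
            nu, a = pfc_step(nu, a, 0.0, w, params, params.dt)
        assert nu < 8.0  # eventually collapses


class TestVtaStep:
    def test_rest_state_calibration(self, params, naive_weights):
        nu_d, nu_g = 0.0, 0.0
        for _ in range(5000):
            cur = input_currents(0.0, 0.0, nu_g, 0.0, naive_weights, params)
            nu_d, nu_g = vta_step(nu_d, nu_g, cur, params, params.dt)
        assert nu_g == pytest.approx(14.0, abs=1e-6)
        assert nu_d == pytest.approx(5.0, abs=0.5)

    def test_da_rate_never_exceeds_omega(self, params):
        nu_d, nu_g = 5.0, 14.0
        for _ in range(1000):
            nu_d, nu_g = vta_step(nu_d, nu_g, (0.0, 1e3, 0.0, 0.0), params, params.dt)
            assert nu_d <= 30.0

    def test_gaba_excitation_lowers_da(self, params, naive_weights):
        def steady(i_glu_g):
            nu_d, nu_g = 5.0, 14.0
            for _ in range(3000):
                nu_d, nu_g = vta_step(
                    nu_d, nu_g, (params.w_g_d * nu_g, 0.0, i_glu_g, 0.0),
                    params, params.dt,
                )
            return nu_d

        assert steady(5.0) < steady(0.0)


class TestSimulateTrial:
    def test_naive_trial_has_us_burst_and_no_cs_response(
        self, params, receptor_params, protocol, naive_weights
    ):
        tr = simulate_trial(params, receptor_params, naive_weights, protocol)
        cs_win = tr.window(protocol.cs_onset, 0.2)
        us_win = tr.window(protocol.us_onset, 0.2)
        assert np.max(tr.nu_d[us_win]) > 10.0  # reward burst
        assert np.max(tr.nu_d[cs_win]) == pytest.approx(5.0, abs=0.5)  # no cue response

    def test_learned_omission_dips_below_baseline(
        self, params, receptor_params, protocol
    ):
        w = LearnableWeights(j_pfc=1.2, w_pfc_d=1.0, w_pfc_g=1.0)
        proto = dataclasses.replace(protocol, reward_omitted=True)
        tr = simulate_trial(params, receptor_params, w, proto)
        us_win = tr.window(protocol.us_onset, protocol.us_duration)
        assert np.min(tr.nu_d[us_win]) < 4.0  # pause below the 5 Hz baseline

    def test_traces_finite_and_nonnegative(
        self, params, receptor_params, protocol, naive_weights
    ):
        tr = simulate_trial(params, receptor_params, naive_weights, protocol)
        for series in (tr.nu_pfc, tr.nu_pptg, tr.nu_g, tr.nu_d):
            assert np.all(np.isfinite(series))
            assert np.all(series >= 0.0)

    def test_rest_state_independent_of_initial_rates(
        self, params, receptor_params, protocol, naive_weights
    ):
        proto = dataclasses.replace(protocol, reward_omitted=True)
        lo = simulate_trial(params, receptor_params, naive_weights, proto,
                            initial_rates=(0.0, 0.0))
        hi = simulate_trial(params, receptor_params, naive_weights, proto,
                            initial_rates=(29.0, 60.0))
        assert abs(lo.nu_d[0] - hi.nu_d[0]) < 1e-3
        assert abs(lo.nu_g[0] - hi.nu_g[0]) < 1e-3

    def test_no_afferents_means_flat_baseline(self, receptor_params, protocol):
        # silencing the PPTg route includes its cholinergic outflow
        p = CircuitParams(w_ppt_d=0.0, w_ppt_g=0.0, w_cs=0.0, w_ach=0.0)
        tr = simulate_trial(p, receptor_params, LearnableWeights(), protocol)
        assert np.ptp(tr.nu_g) < 1e-6
        assert np.ptp(tr.nu_d) < 1e-3

    def test_dt_halving_changes_traces_below_one_percent(
        self, receptor_params, protocol, naive_weights
    ):
        coarse = simulate_trial(
            CircuitParams(dt=1.0), receptor_params, naive_weights, protocol
        )
        fine = simulate_trial(
            CircuitParams(dt=0.5), receptor_params, naive_weights, protocol
        )
        for a, b in ((coarse.nu_d, fine.nu_d), (coarse.nu_g, fine.nu_g)):
            scale = np.max(b)
            assert np.max(np.abs(a - b[1::2])) / scale < 0.01

    @pytest.mark.parametrize("tau_pptg", [50.0, 100.0, 150.0])
    @pytest.mark.parametrize("tau_g", [15.0, 30.0, 45.0])
    def test_sign_structure_robust_to_time_constants(
        self, receptor_params, protocol, tau_pptg, tau_g
    ):
        """Varying tau_PPTg and tau_G by +-50% preserves the learned response
        pattern: a clear CS burst and a strongly reduced US response."""
        p = CircuitParams(tau_pptg=tau_pptg, tau_g=tau_g)
        naive = simulate_trial(p, receptor_params, LearnableWeights(), protocol)
        w = LearnableWeights(j_pfc=1.2, w_pfc_d=1.3, w_pfc_g=1.3)
        learned = simulate_trial(p, receptor_params, w, protocol)
        cs_win = learned.window(protocol.cs_onset, 0.2)
        us_win = learned.window(protocol.us_onset, 0.2)
        baseline = 5.0
        cs_burst = np.max(learned.nu_d[cs_win]) - baseline
        us_naive = np.max(naive.nu_d[us_win]) - baseline
        us_learned = np.max(learned.nu_d[us_win]) - baseline
        assert cs_burst > 2.0
        assert us_learned < 0.5 * us_naive
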