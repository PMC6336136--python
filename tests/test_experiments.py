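"""Optogenetics, condition batteries, dose-response and PFC fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtacircuit.circuit import CircuitParams, LearnableWeights, simulate_trial
from vtacircuit.experiments import (
    OptoProtocol,
    apply_opto,
    cs_dose_response,
    pfc_fixed_points,
    run_condition_battery,
)
from vtacircuit.plasticity import run_conditioning
from vtacircuit.receptors import PharmacologySchedule


@pytest.fixture(scope="module")
def learned_weights():
    # representative post-conditioning state (session-derived magnitudes)
    return LearnableWeights(j_pfc=1.2, w_pfc_d=1.3, w_pfc_g=1.3)


class TestOpto:
    def test_zero_intensity_reproduces_control_exactly(
        self, params, receptor_params, protocol, learned_weights
    ):
        control = simulate_trial(params, receptor_params, learned_weights, protocol)
        off = simulate_trial(
            params, receptor_params, learned_weights, protocol,
            opto=OptoProtocol(intensity=0.0),
        )
        np.testing.assert_array_equal(control.nu_d, off.nu_d)
        np.testing.assert_array_equal(control.nu_g, off.nu_g)

    def test_laser_disinhibits_da_during_window(
        self, params, receptor_params, protocol, learned_weights
    ):
        control = simulate_trial(params, receptor_params, learned_weights, protocol)
        lasered = simulate_trial(
            params, receptor_params, learned_weights, protocol, opto=OptoProtocol()
        )
        win = (control.time >= 1.5) & (control.time < 2.5)
        assert np.mean(lasered.nu_d[win]) > np.mean(control.nu_d[win])

    def test_effect_monotone_in_affected_fraction(
        self, params, receptor_params, protocol, learned_weights
    ):
        def mean_da(fraction):
            tr = simulate_trial(
                params, receptor_params, learned_weights, protocol,
                opto=OptoProtocol(fraction=fraction),
            )
            win = (tr.time >= 1.5) & (tr.time < 2.5)
            return np.mean(tr.nu_d[win])

        assert mean_da(1.0) > mean_da(0.2) > mean_da(0.0)

    def test_effect_localized_to_laser_window(
        self, params, receptor_params, protocol, learned_weights
    ):
        control = simulate_trial(params, receptor_params, learned_weights, protocol)
        lasered = simulate_trial(
            params, receptor_params, learned_weights, protocol, opto=OptoProtocol()
        )
        outside = (control.time < 1.5)  # before the laser; decay tail excluded
        scale = np.max(control.nu_d)
        assert np.max(np.abs(lasered.nu_d[outside] - control.nu_d[outside])) < 0.05 * scale

    def test_apply_opto_matches_in_loop_subtraction(self, params):
        """The standalone helper reproduces the effective GABA rate the trial
        loop feeds into the DA current."""
        nu_g = np.full(3000, 20.0)
        opto = OptoProtocol()
        eff = apply_opto(nu_g, opto, params.dt)
        time = (np.arange(3000) + 0.5) / 1000.0
        inside = (time >= 1.6) & (time < 2.5)
        assert np.all(eff[inside] < 20.0)
        assert np.all(eff[time < 1.5] == 20.0)
        # affected subpopulation is rectified at zero, never negative
        deep = apply_opto(np.full(3000, 0.5), OptoProtocol(intensity=50.0), params.dt)
        assert np.all(deep >= (1 - opto.fraction) * 0.5 - 1e-12)


class TestConditionBattery:
    def test_control_battery_is_plain_conditioning(
        self, params, receptor_params, protocol, rates
    ):
        session, probe = run_condition_battery(
            "control", params, receptor_params, protocol, rates=rates, n_trials=3
        )
        reference = run_conditioning(
            params, receptor_params, protocol, rates=rates, n_trials=3
        )
        assert session.final_weights == reference.final_weights
        np.testing.assert_array_equal(
            session.series("delta"), reference.series("delta")
        )

    def test_unknown_condition_rejected(self, params, receptor_params, protocol):
        with pytest.raises(ValueError):
            run_condition_battery("placebo", params, receptor_params, protocol)

    def test_withdrawal_probe_suppresses_reward_response_below_baseline(
        self, params, receptor_params, protocol, rates
    ):
        """After learning under nicotine, a drug-free probe restores the full
        cholinergic drive onto GABA neurons: the DA response to the reward is
        pushed far below the 5 Hz tonic baseline throughout the US window."""
        _, probe = run_condition_battery(
            "withdrawal", params, receptor_params, protocol, rates=rates, n_trials=50
        )
        us_win = probe.window(protocol.us_onset, 0.2)
        assert np.max(probe.nu_d[us_win]) < 3.0

    def test_nicotine_boosts_naive_reward_response(
        self, params, receptor_params, protocol, naive_weights
    ):
        control = simulate_trial(params, receptor_params, naive_weights, protocol)
        nicotine = simulate_trial(
            params, receptor_params, naive_weights, protocol,
            PharmacologySchedule.nicotine(),
        )
        us_win = control.window(protocol.us_onset, 0.2)
        assert np.max(nicotine.nu_d[us_win]) > np.max(control.nu_d[us_win]) + 1.0


class TestDoseResponse:
    def test_zero_reward_leaves_cue_response_at_baseline(
        self, params, receptor_params, protocol, rates
    ):
        curve = cs_dose_response(
            [0.0], "control", params, receptor_params, protocol,
            rates=rates, n_trials=3,
        )
        assert curve.cs_peak[0] == pytest.approx(5.0, abs=0.5)

    def test_monotone_in_reward(self, params, receptor_params, protocol, rates):
        curve = cs_dose_response(
            [2.0, 8.0], "control", params, receptor_params, protocol,
            rates=rates, n_trials=25,
        )
        assert curve.cs_peak[1] > curve.cs_peak[0]


class TestPfcFixedPoints:
    def test_monostable_rest_before_learning(self, params):
        pts = pfc_fixed_points(0.2, 0.0, 0.0, params)
        assert len(pts) == 1
        nu, stable = pts[0]
        assert nu < 1.0 and stable

    def test_bistable_after_learning(self, params):
        pts = pfc_fixed_points(1.2, 0.0, 0.0, params)
        assert len(pts) == 3
        (lo, s_lo), (mid, s_mid), (hi, s_hi) = pts
        assert s_lo and not s_mid and s_hi
        assert lo < 1.0 < mid < hi
        assert hi > 25.0

    def test_cs_input_pushes_to_single_high_state(self, params):
        pts = pfc_fixed_points(0.2, 1.0, 0.0, params)
        assert len(pts) == 1
        nu, stable = pts[0]
        assert nu > 25.0 and stable

    def test_adaptation_destroys_the_up_state(self, params):
        high_adapt = pfc_fixed_points(1.2, 0.0, 25.0, params)
        assert len(high_adapt) == 1
        assert high_adapt[0][0] < 1.0

    def test_fixed_points_satisfy_the_equation(self, params):
        from vtacircuit.transfer import sigmoid

        for j, cs, a in [(0.2, 0.0, 0.0), (1.2, 0.0, 0.0), (0.9, 1.0, 6.0)]:
            for nu, _ in pfc_fixed_points(j, cs, a, params):
                rhs = sigmoid(params.w_cs * cs + j * nu - a, params.pfc_sigmoid)
                assert rhs == pytest.approx(nu, abs=1e-4)

    @given(st.floats(0.0, 2.0), st.floats(0.0, 1.0), st.floats(0.0, 30.0))
    @settings(deadline=None, max_examples=60)
    def test_count_bounded_by_bistability(self, j, cs, a):
        pts = pfc_fixed_points(j, cs, a, CircuitParams())
        assert 1 <= len(pts) <= 3
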