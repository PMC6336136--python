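#!/usr/bin/env python
"""Calibration report for the constants that are not pinned by measurement.

The circuit's printed constants (time constants, baselines, sigmoid shapes,
the nAChR balance r, w_alpha4b2, w_ACh, the Hill dose-response, alpha_T) are
fixed. The remaining constants are calibrated against the model's target
behaviors; this script recomputes the derivable ones and reports the
behavioral checks that pinned the rest, so the defaults in
vtacircuit.config can be audited in one run.

Calibration targets:
 1. w_G-D: the drug-free rest state must sit at nu_D = 5 Hz given
    nu_G = B_G = 14 Hz -> w_G-D = (B_D - F^-1(5)) / B_G (closed form).
 2. w_CS: the naive PFC must reach its Up state within the 0.5 s tone and
    collapse at tone offset despite the adaptation accumulated meanwhile.
 3. c (adaptation gain): the collapse time must be movable by J_PFC across
    the whole CS-US interval with a feedback gain small enough for Eq-style
    timing learning to converge (alpha_T fixed at 0.2).
 4. w_PPT-D / w_PPT-G: a naive 4 uL reward burst of roughly 10-15 Hz whose
    learned cancellation leaves cue responses graded over 1-20 uL without
    saturating the 30 Hz ceiling.
 5. alpha_V: value learning converging within ~50 trials with the CS/US
    crossover in the middle trials.
 6. Receptor constants: 5 min of 1 uM nicotine desensitizes most of the
    pool; sub-second ACh transients of a few uM activate it appreciably;
    the drug-free baseline is left unchanged.
"""

import numpy as np

from vtacircuit.circuit import CircuitParams, LearnableWeights, TrialProtocol, simulate_trial
from vtacircuit.plasticity import LearningRates, measure_trial, run_conditioning
from vtacircuit.receptors import PharmacologySchedule, ReceptorParams, pre_expose
from vtacircuit.transfer import sigmoid_inverse


def main() -> None:
    p = CircuitParams()
    rp = ReceptorParams()
    proto = TrialProtocol()
    rates = LearningRates()

    w_g_d = (p.b_d - sigmoid_inverse(5.0, p.da_sigmoid)) / p.b_g
    print(f"[1] w_G-D from F(B_D - w*14) = 5 Hz: {w_g_d:.4f} "
          f"(default {p.w_g_d})")

    naive = simulate_trial(p, rp, LearnableWeights(), proto)
    cs_win = naive.window(proto.cs_onset, proto.cs_duration)
    print(f"[2] naive PFC max during CS: {np.max(naive.nu_pfc[cs_win]):.1f} Hz "
          f"(target: Up state, > 25 Hz)")

    m1 = measure_trial(naive, proto)
    print(f"[4] naive 4 uL reward burst: {m1.us_peak:.1f} Hz "
          f"(target 10-15 Hz); peak time {m1.t2:.3f} s")

    session = run_conditioning(p, rp, proto, rates=rates, n_trials=50)
    dt_da = session.series("dt_da")
    w = np.array([x.w_pfc_d for x in session.weights])
    trial_timing = int(np.argmax(np.abs(dt_da) < 0.05)) + 1
    trial_value = int(np.argmax(w >= 0.5 * w[-1])) + 1
    cs = session.series("cs_peak")
    us = session.series("us_peak")
    cross = int(np.argmax(cs > us)) + 1
    print(f"[3] timing criterion met at trial {trial_timing}; "
          f"collapse time at trial 50: {session.series('t1')[49]:.3f} s")
    print(f"[5] value at 50% of final at trial {trial_value}; "
          f"CS/US crossover at trial {cross}; "
          f"delta: {session.series('delta')[0]:.2f} -> "
          f"{session.series('delta')[49]:.2f} Hz.s")

    state = pre_expose(rp, PharmacologySchedule.nicotine())
    print(f"[6] after 5 min of 1 uM nicotine: sensitized fraction s = "
          f"{state.s:.2f} (target: well below 1)")
    nic = simulate_trial(
        p, rp, LearnableWeights(), proto, PharmacologySchedule.nicotine()
    )
    m_nic = measure_trial(nic, proto)
    print(f"    naive reward burst under nicotine: {m_nic.us_peak:.1f} Hz "
          f"(control {m1.us_peak:.1f}; disinhibition boost)")
    pre = naive.window(0.0, proto.cs_onset)
    print(f"    baseline: control {np.mean(naive.nu_d[pre]):.3f} Hz, "
          f"nicotine {np.mean(nic.nu_d[pre]):.3f} Hz (target: unchanged)")


if __name__ == "__main__":
    main()
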