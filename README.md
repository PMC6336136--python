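# vtacircuit

A mean-field model of the ventral tegmental area (VTA) circuit that computes
reward prediction errors (RPE) during Pavlovian trace conditioning, with
nicotinic-receptor pharmacology and a downstream decision task.

The package is for computational neuroscientists studying how dopamine (DA)
neurons learn the timing and magnitude of rewards, and how nicotine — by
desensitizing α4β2 nicotinic acetylcholine receptors (nAChRs) on VTA GABA
neurons — distorts those computations and downstream choices.

## The model

Four interacting populations are integrated with forward Euler (dt = 1 ms):

```
τ_D ν̇_D = −ν_D + F(B_D − I_G-D + I_Glu-D + r·I_α4β2)
τ_G ν̇_G = −ν_G + Φ(B_G + I_Glu-G + (1−r)·I_α4β2)
```

where `F(x) = ω / (1 + exp(−β(x−γ)))` is a sigmoid (ω = 30 Hz, γ = 8,
β = 0.3 for DA) and `Φ` a linear rectifier. GABA neurons (baseline drive
B_G = 14) inhibit DA neurons (B_D = 18), which rest at ~5 Hz. The
**PPTg** responds to the water reward (US) with a Hill-saturating,
phasically filtered burst (peak ~100 ms after delivery) and releases
acetylcholine in proportion to its rate; the **PFC** holds a working-memory
representation of the tone (CS) in a bistable attractor with
spike-frequency adaptation, feeding both VTA populations through equal
corticostriatal weights `w_PFC-D = w_PFC-G`.

Two plasticity processes act between trials:

* **timing** (fast): `J_PFC ← J_PFC + α_T·Δt_DA`, where Δt_DA is the lag
  between the PFC Up-state collapse and the DA peak at reward — the PFC
  learns to hold the cue memory exactly until reward delivery;
* **value** (slow): `w_PFC-D ← w_PFC-D + α_V·δ`, where δ is the signed area
  of the DA rate above its reward-onset value over 200 ms — a
  Rescorla–Wagner rule that grows the expectation signal until the reward
  burst is cancelled.

α4β2 nAChRs are a two-gate (activation × sensitization) pool: acetylcholine
opens them in milliseconds; sub-micromolar nicotine silently desensitizes
them over minutes. Five minutes of 1 μM nicotine therefore removes most of
the cholinergic drive onto GABA neurons, disinhibiting DA reward responses
and inflating learned cue values — which a softmax decision rule
(`P = 1/(1+exp(b·ΔV))`, b = 0.4) converts into a measurable choice bias.

## Worked example

```python
from vtacircuit import CircuitParams, ReceptorParams, TrialProtocol
from vtacircuit.plasticity import run_conditioning

session = run_conditioning(CircuitParams(), ReceptorParams(), TrialProtocol(),
                           n_trials=50)
m1, m50 = session.measures[0], session.measures[-1]
print(f"trial  1: US burst {m1.us_peak:.1f} Hz, CS burst {m1.cs_peak:.1f} Hz, "
      f"RPE {m1.delta:.2f} Hz.s")
print(f"trial 50: US burst {m50.us_peak:.1f} Hz, CS burst {m50.cs_peak:.1f} Hz, "
      f"RPE {m50.delta:.2f} Hz.s")
print(f"PFC collapse at {m50.t1:.2f} s (reward at 2.0 s)")
```

prints

```
trial  1: US burst 12.5 Hz, CS burst 5.0 Hz, RPE 0.76 Hz.s
trial 50: US burst 2.2 Hz, CS burst 14.3 Hz, RPE 0.15 Hz.s
PFC collapse at 2.10 s (reward at 2.0 s)
```

— the unexpected-reward burst (12.5 Hz over the 5 Hz baseline) migrates to
the cue as the RPE decays, and the PFC working memory learns to span the
1.5 s trace interval. The same machinery is exposed on the command line:

```
vtacircuit condition --trials 50 --out-dir out/      # control conditioning
vtacircuit nicotine  --trials 50 --out-dir out_nic/  # under 1 uM nicotine
vtacircuit dose-response --out-dir out_dr/           # CS curves, both conditions
vtacircuit decide --seed 1 --out-dir out_dec/        # three-location choice task
vtacircuit fixed-points --j 1.2                      # PFC attractor structure
```

`scripts/calibrate.py` prints the calibration report for the constants that
are not fixed by measurement (see `docs/methods.md`).

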