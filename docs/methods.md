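# Methods

## Model

The circuit is a four-population firing-rate model of the VTA and its
afferents. The VTA DA and GABA populations follow first-order rate dynamics
(τ_D = τ_G = 30 ms) around baseline drives B_D = 18 and B_G = 14; the DA
transfer function is a sigmoid (ω = 30 Hz, γ = 8, β = 0.3) so that rates
above ~8 Hz represent bursting and the population saturates at 30 Hz, while
the GABA population uses a linear rectifier. GABA neurons inhibit DA neurons
with weight w_G-D; both receive glutamate from the corticostriatal pathway
(weights w_PFC-D = w_PFC-G, constrained equal) and from the PPTg, plus a
nAChR-mediated current w_α4β2·a·s split between DA (fraction r = 0.2) and
GABA (1 − r).

**PPTg.** The 0.5 s reward pulse of size R (μL) is converted to a rate by a
square-root Hill function f(R) = 70·√R/(√R + √20) and differentiated by a
two-stage low-pass cascade with τ_PPTg = 100 ms, producing a burst that
peaks 100 ms after reward onset with amplitude f(R)/e. Cholinergic outflow
tracks the PPTg rate, ACh = w_ACh·ν_PPTg with w_ACh = 1 μM per Hz (the
model gives only the product w_α4β2·a·s dimensional meaning, so this unit
convention is a labeling choice, not a physiological claim).

**PFC.** A recurrent population with the sigmoid transfer (ω = 30, γ = 8,
β = 0.5), time constant 100 ms, recurrent weight J_PFC, tone input
w_CS·ν_CS and subtractive adaptation a with τ_a = 1 s and asymptote
a_∞ = c·ν_PFC. For sufficient J_PFC the population is bistable after tone
offset; adaptation eventually collapses the Up state, and the collapse time
is a monotone function of J_PFC — the substrate of timing learning.

**nAChRs.** A two-gate pool: activation a (τ_a = 5 ms, Hill steady state in
ACh + α·Nic with α = 3) and sensitization s (driven by nicotine only,
η = 0; concentration-dependent time constant from τ_0 = 0.5 s at saturating
ligand to τ_0 + τ_max ≈ 3 min for drug-free recovery). Gates are advanced
with the exact exponential step for the ligand held constant over dt, so
trajectories are independent of step size.

## Trial and learning protocol

Each 3 s trial presents a 0.5 s tone at 0.5 s and a 0.5 s reward at 2.0 s.
Rates start from the condition-appropriate rest state, found by relaxing
the circuit for 2 s of model time before t = 0. After each trial:

* Δt_DA = t2 − t1, where t1 is the PFC rate's first downward crossing of
  γ = 8 Hz after tone onset (linearly interpolated; clipped to the trial
  end when the Up state outlives the trial) and t2 is the DA argmax in the
  200 ms after reward onset — the same 200 ms window used for every phasic
  DA measurement (cue peaks, reward peaks and the RPE δ). Then
  J_PFC += 0.2·Δt_DA, clipped to [0, 2]. Unrewarded trials and trials where
  the PFC never engaged carry no timing information and are skipped.
* δ = ∫(ν_D(t) − ν_D(2.0 s)) dt over the 200 ms after reward onset (signed,
  so omission pauses yield negative RPE); then w_PFC-D = w_PFC-G += α_V·δ,
  clipped below at 0. Timing is updated before value, both from the same
  trace.

## Calibrated constants

Printed constants keep their published values. The remainder are calibrated
once against the model's target behaviors (see `scripts/calibrate.py` for a
recomputable report):

| constant | default | how it was fixed |
|---|---|---|
| w_G-D | 1.0975 | closed form: F(B_D − w·14) = 5 Hz rest DA rate |
| w_PPT-D | 1.4 | naive 4 μL reward burst ≈ 12 Hz, graded over 1–20 μL |
| w_PPT-G | 0.6 | with the ACh current, near-balances the PPTg drive so the learned expectation can cancel the reward burst without saturating cue responses |
| w_CS | 20 | PFC reaches the Up state within the 0.5 s tone despite adaptation |
| c (adaptation gain) | 1.0 | collapse time tunable by J_PFC over the whole trace interval with a stable timing-feedback gain at α_T = 0.2 |
| α_V | 0.06 | value learning converges within ~50 trials, CS/US crossover near trial 12 |
| EC50, n_a | 8 μM, 1.5 | ACh transients of 5–13 μM (rewards 1–20 μL) activate the pool over its rising range, so nicotine's effect grows with reward up to ~8 μL |
| IC50, n_s | 0.15 μM, 0.8 | 5 min at 1 μM nicotine leaves s ≈ 0.18 (deep desensitization) |
| τ_a, τ_0, τ_max, K_τ | 5 ms, 0.5 s, 180 s, 0.3 μM | ms-scale activation vs minutes-scale desensitization/recovery, so the desensitized state persists across a trial |

J_PFC is clipped at 2 to prevent runaway recurrence (the collapse-time map
diverges near the bistability limit); the clip is never active at the
calibrated defaults.

## Pharmacology conditions

The nicotine condition pre-exposes the receptor pool to 1 μM for 5 min
before every trial (closed-form relaxation; no time stepping). Nicotine is
treated as washed out on the trial timescale: activation recovers within
milliseconds, so the drug's lasting trace is the desensitized pool, whose
recovery takes minutes. This choice keeps the drug-free baseline rate
exactly unchanged — any tonic receptor activation at rest would, with
r = 0.2, excite GABA more than DA and *lower* baseline DA, contradicting
the observation that baseline changes only slightly under nicotine. A
config flag (`nicotine_during_trial`) restores the alternative reading
(1 μM held throughout the trial). The withdrawal probe resets the pool to
the fully sensitized drug-free state — an assumption, since only the
removal of nicotine is specified.

## Numerical choices

Forward Euler at dt = 1 ms for the populations (time constants ≥ 30 ms;
halving dt changes rate traces by < 1% max-norm, enforced by a test); exact
exponential steps for the receptor gates; the linear filters (phasic
cascade, activation gate, opto subtraction) are evaluated with vectorized
IIR recursions verified against the per-step updates to 1e−12. Time
samples sit at step centers; all measurement windows are half-open
[start, start + width). PFC fixed points are located by sign-change
bracketing on a 3001-point grid plus Brent's method (tolerance 1e−6 Hz),
with stability from the slope J·F′ at the fixed point. The softmax uses the
two-option logistic form (the equal-value and zero-temperature cases give
exactly 1/2), and the decision walk's occupancy is validated against the
stationary distribution of its 3×3 transition matrix.

## Known limitations

* **Timing offset.** The timing rule's fixed point equates the PFC collapse
  with the DA maximum after reward, which cannot occur earlier than ~60 ms
  after reward onset (the PPTg burst is filtered with τ_PPTg = 100 ms and
  DA integrates with τ_D = 30 ms). The learned collapse therefore settles
  ~70–100 ms after reward delivery rather than exactly on it.
* **Residual RPE.** δ is measured relative to the DA rate at reward onset.
  Once the reward burst is cancelled, the post-collapse recovery of DA
  toward baseline inside the 200 ms window contributes a small positive
  area, so δ decays to a floor of roughly 15–25% of its naive value instead
  of zero; the corticostriatal weight correspondingly drifts slowly rather
  than freezing. Parameter regimes that push δ below 5% of its naive value
  (very deep expectation signals) suppress the interval DA rate to the
  sigmoid floor, which destroys the omission pause, saturates the cue
  dose-response, and reverses the nicotine choice bias — so the defaults
  deliberately do not go there.
* **Withdrawal RPE sign.** On the drug-free probe after learning under
  nicotine the reward response is suppressed far below the tonic baseline
  (its maximum in the US window is < 3 Hz against a 5 Hz baseline), but the
  area-above-onset statistic δ remains marginally positive, because the
  onset reference itself sits at the bottom of the collapse dip. δ < 0 on
  this probe is unreachable for any weight configuration of this circuit
  (verified on a dense (J, w) grid); the suppression itself is asserted by
  a regression test.
* The model omits an explicit NAc population, other VTA afferents,
  spiking noise, conduction delays, receptor up-regulation under chronic
  nicotine, and early-reward probes. Simulations are deterministic except
  for the decision walk; "learning" here means trial-to-trial weight
  updates, not within-trial dynamics. Passing tests demonstrate internal
  consistency of the mean-field model, not quantitative agreement with
  physiological recordings.
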