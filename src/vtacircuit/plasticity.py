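"""Two-speed learning across conditioning trials.

Two quantities are learned from each trial's trace, on different timescales:

* **Reward timing** (fast, converges in a handful of trials). The timing
  error ``dt_DA = t2 - t1`` compares the moment the PFC Up state collapses
  (``t1``, when the PFC rate falls back through the sigmoid inflection
  gamma = 8 Hz) with the moment of maximal DA activity at the reward
  (``t2``). The PFC recurrent weight is nudged by ``alpha_T * dt_DA``
  (alpha_T = 0.2 per second of error), which stretches or shrinks the Up
  state until it collapses exactly at reward delivery.

* **Reward value** (slow, tens of trials). The reward prediction error
  ``delta(n)`` is the signed area of the DA rate above its value at US
  onset over the 200 ms following reward delivery. The corticostriatal
  weights onto DA and GABA neurons grow by ``alpha_V * delta`` (a
  Rescorla-Wagner delta rule); as they grow, the feed-forward expectation
  signal cancels the reward burst and delta decays toward zero.

The session runner applies both updates after every trial — timing first,
then value, both computed from the same trace — and records the weight and
measurement history. Everything here is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circuit import (
    CircuitParams,
    LearnableWeights,
    TrialProtocol,
    TrialTrace,
    simulate_trial,
)
from .receptors import PharmacologySchedule, ReceptorParams

__all__ = [
    "LearningRates",
    "TrialMeasures",
    "SessionResult",
    "measure_delta",
    "measure_timing",
    "update_timing",
    "update_value",
    "run_conditioning",
]

#: width (s) of the measurement window after CS and US onsets
MEASURE_WINDOW = 0.2

#: PFC rate threshold (Hz) defining the Up-state collapse time t1
COLLAPSE_THRESHOLD = 8.0

#: upper clip for the PFC recurrent weight, preventing runaway growth
J_MAX = 2.0


@dataclass(frozen=True)
class LearningRates:
    """Learning rates of the two plasticity processes.

    alpha_t : timing rate, weight change per second of timing error (0.2)
    alpha_v : corticostriatal value rate, weight change per Hz.s of RPE
              [calibrated so value learning converges within ~50 trials]
    """

    alpha_t: float = 0.2
    alpha_v: float = 0.06

    def __post_init__(self) -> None:
        if self.alpha_t <= 0 or self.alpha_v <= 0:
            raise ValueError("learning rates must be positive")


@dataclass(frozen=True)
class TrialMeasures:
    """Per-trial scalar measurements extracted from a trace.

    delta   : RPE, signed area (Hz.s) of nu_D above its US-onset value
    t1      : PFC collapse time (s); NaN when the PFC never engaged
    t2      : time of maximal DA activity in the US window (s)
    dt_da   : timing error t2 - t1 (s); NaN when t1 is undefined
    cs_peak : max nu_D within 200 ms of CS onset (Hz)
    us_peak : max nu_D within 200 ms of US onset (Hz)
    engaged : whether the PFC crossed the collapse threshold at all
    """

    delta: float
    t1: float
    t2: float
    dt_da: float
    cs_peak: float
    us_peak: float
    engaged: bool


@dataclass
class SessionResult:
    """History of a conditioning session.

    ``weights[n]`` are the weights *used* on trial n (0-based), so
    ``weights[0]`` is the naive state; ``final_weights`` are the weights
    after the last update. ``traces`` holds full traces for the recorded
    trial indices only.
    """

    weights: list[LearnableWeights]
    measures: list[TrialMeasures]
    final_weights: LearnableWeights
    traces: dict[int, TrialTrace]

    @property
    def n_trials(self) -> int:
        return len(self.measures)

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.measures])


def measure_delta(trace: TrialTrace, proto: TrialProtocol) -> float:
    """Signed RPE: integral of nu_D above its US-onset value over 200 ms.

    Negative on omission dips (the DA pause below the pre-reward level).
    """
    end = proto.us_onset + MEASURE_WINDOW
    if trace.time[-1] + trace.dt / 2 < end:
        raise ValueError("trace does not cover the 200 ms RPE window")
    baseline = trace.value_at(trace.nu_d, proto.us_onset)
    mask = trace.window(proto.us_onset, MEASURE_WINDOW)
    return float(np.sum(trace.nu_d[mask] - baseline) * trace.dt)


def _first_downward_crossing(
    time: np.ndarray, series: np.ndarray, threshold: float, after: float
) -> float:
    """First time after ``after`` the series crosses threshold from above,
    having exceeded it; linear interpolation between samples; NaN if the
    series never exceeds the threshold."""
    valid = time >= after
    t = time[valid]
    y = series[valid]
    above = y > threshold
    if not above.any():
        return math.nan
    start = int(np.argmax(above))
    for k in range(start, len(y) - 1):
        if y[k] > threshold >= y[k + 1]:
            # interpolate inside [t_k, t_{k+1}]
            w = (y[k] - threshold) / (y[k] - y[k + 1])
            return float(t[k] + w * (t[k + 1] - t[k]))
    return math.nan


def measure_timing(
    trace: TrialTrace,
    proto: TrialProtocol,
    threshold: float = COLLAPSE_THRESHOLD,
) -> tuple[float, float, float]:
    """PFC collapse time t1, DA peak time t2 and timing error t2 - t1.

    t1 is the first downward crossing of the threshold by the PFC rate after
    CS onset (the Up-state collapse); t2 is the argmax of the DA rate within
    the 200 ms window following US onset — the same window used for every
    other phasic DA measurement. When the PFC never exceeds the threshold
    (no engagement) t1 and dt_da are NaN and no timing update should occur.
    When the Up state is still alive at the end of the trial the collapse is
    pending beyond the observation window; t1 is clipped to the trial end so
    the timing error stays defined (and negative, shrinking the recurrence).
    """
    t1 = _first_downward_crossing(trace.time, trace.nu_pfc, threshold, proto.cs_onset)
    if math.isnan(t1) and np.any(trace.nu_pfc[trace.time >= proto.cs_onset] > threshold):
        t1 = float(trace.time[-1])
    mask = trace.window(proto.us_onset, MEASURE_WINDOW)
    idx = int(np.argmax(trace.nu_d[mask]))
    t2 = float(trace.time[mask][idx])
    return t1, t2, t2 - t1


def update_timing(
    weights: LearnableWeights, dt_da: float, rates: LearningRates
) -> LearnableWeights:
    """Timing rule: j_pfc += alpha_t * dt_da, clipped into [0, J_MAX]."""
    if not math.isfinite(dt_da):
        raise ValueError("timing error must be finite (no-engagement trials skip it)")
    j = min(max(weights.j_pfc + rates.alpha_t * dt_da, 0.0), J_MAX)
    return replace(weights, j_pfc=j)


def update_value(
    weights: LearnableWeights, delta: float, rates: LearningRates
) -> LearnableWeights:
    """Value rule: both corticostriatal weights += alpha_v * delta, >= 0."""
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    w = max(weights.w_pfc_d + rates.alpha_v * delta, 0.0)
    return replace(weights, w_pfc_d=w, w_pfc_g=w)


def measure_trial(trace: TrialTrace, proto: TrialProtocol) -> TrialMeasures:
    """All per-trial measurements from one trace."""
    delta = measure_delta(trace, proto)
    t1, t2, dt_da = measure_timing(trace, proto)
    cs_peak = float(np.max(trace.nu_d[trace.window(proto.cs_onset, MEASURE_WINDOW)]))
    us_peak = float(np.max(trace.nu_d[trace.window(proto.us_onset, MEASURE_WINDOW)]))
    return TrialMeasures(
        delta=delta,
        t1=t1,
        t2=t2,
        dt_da=dt_da,
        cs_peak=cs_peak,
        us_peak=us_peak,
        engaged=math.isfinite(t1),
    )


def run_conditioning(
    p: CircuitParams,
    rp: ReceptorParams,
    proto: TrialProtocol,
    pharm: PharmacologySchedule | None = None,
    rates: LearningRates | None = None,
    n_trials: int = 50,
    initial: LearnableWeights | None = None,
    record: tuple[int, ...] = (),
) -> SessionResult:
    """Run a conditioning session: simulate, measure, update, repeat.

    Per trial the timing update is applied first, then the value update,
    both computed from that trial's trace. Timing is skipped on
    no-engagement trials and on unrewarded trials (with no US-evoked DA
    response the "time of maximal DA activity at the US" carries no timing
    information). ``record`` lists 0-based trial indices whose full traces
    are kept.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rates = rates or LearningRates()
    weights = initial or LearnableWeights()
    history: list[LearnableWeights] = []
    measures: list[TrialMeasures] = []
    traces: dict[int, TrialTrace] = {}
    for n in range(n_trials):
        trace = simulate_trial(p, rp, weights, proto, pharm)
        m = measure_trial(trace, proto)
        history.append(weights)
        measures.append(m)
        if n in record:
            traces[n] = trace
        rewarded = not proto.reward_omitted and proto.reward_size > 0
        if m.engaged and rewarded:
            weights = update_timing(weights, m.dt_da, rates)
        weights = update_value(weights, m.delta, rates)
    return SessionResult(
        weights=history, measures=measures, final_weights=weights, traces=traces
    )
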