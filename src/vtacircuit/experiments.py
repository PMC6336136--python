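"""Simulated experiments on the conditioned circuit.

* GABA photo-inhibition: a low-pass-filtered copy of a laser square pulse
  is subtracted from an affected fraction of the GABA population, which
  disinhibits DA neurons during the laser window.
* Nicotine and withdrawal condition batteries: conditioning with receptors
  pre-desensitized by 5 min of 1 uM nicotine before every trial, and a
  drug-free probe after learning under nicotine.
* CS dose-response: the learned DA burst at the cue as a function of reward
  size, in control and nicotine conditions.
* PFC fixed-point analysis: the graphical bistability analysis of the
  working-memory population, used to understand timing learning.
* Three-location decision task: a mouse alternates between locations worth
  2, 4 and 8 uL; each transition is a two-option softmax choice over the
  learned cue values, and occupancy is compared between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .circuit import CircuitParams, TrialProtocol, TrialTrace, simulate_trial
from .plasticity import (
    LearningRates,
    SessionResult,
    measure_trial,
    run_conditioning,
)
from .receptors import PharmacologySchedule, ReceptorParams
from .transfer import sigmoid

__all__ = [
    "OptoProtocol",
    "DecisionTaskSpec",
    "DoseResponseCurve",
    "apply_opto",
    "run_condition_battery",
    "cs_dose_response",
    "pfc_fixed_points",
    "softmax_choice",
    "stationary_distribution",
    "run_decision_task",
]

CONDITIONS = ("control", "nicotine", "withdrawal")


@dataclass(frozen=True)
class OptoProtocol:
    """Photo-inhibition of a fraction of the GABA population.

    The laser is on between ``laser_on`` and ``laser_off`` (seconds, default
    a 1 s window centered on reward delivery) at dimensionless intensity
    ``intensity``; the subtracted signal integrates the light with time
    constant ``tau_s`` (ms). Only ``fraction`` of the GABA population is
    affected (partial opsin expression).
    """

    laser_on: float = 1.5
    laser_off: float = 2.5
    intensity: float = 4.0
    tau_s: float = 300.0
    fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.laser_on < self.laser_off:
            raise ValueError("laser_on must precede laser_off")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("affected fraction must lie in [0, 1]")
        if self.intensity < 0 or self.tau_s <= 0:
            raise ValueError("intensity >= 0 and tau_s > 0 required")


@dataclass(frozen=True)
class DecisionTaskSpec:
    """Three-location alternation task with softmax choices.

    reward_sizes : uL at each location (2, 4, 8)
    b            : inverse temperature of the softmax choice rule
    n_choices    : number of sequential choices simulated (10,000)
    seed         : RNG seed for the walk
    """

    reward_sizes: tuple[float, float, float] = (2.0, 4.0, 8.0)
    b: float = 0.4
    n_choices: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.reward_sizes):
            raise ValueError("rewards must be positive")
        if self.b < 0 or self.n_choices < 1:
            raise ValueError("need b >= 0 and n_choices >= 1")


@dataclass
class DoseResponseCurve:
    """Learned CS-burst amplitude per reward size for one condition."""

    rewards: np.ndarray
    cs_peak: np.ndarray
    condition: str


def apply_opto(nu_g: np.ndarray, opto: OptoProtocol, dt: float) -> np.ndarray:
    """Effective GABA rate feeding the DA population under photo-inhibition.

    Integrates tau_s s' = -s + nu_light with forward Euler over the trace
    grid (dt in ms), subtracts s from the affected subpopulation (rates
    clipped at zero) and recombines:
    (1 - fraction) nu_G + fraction Phi(nu_G - s).
    Identical to what :func:`vtacircuit.circuit.simulate_trial` applies
    inside its loop; exposed here for analysis of recorded traces.
    """
    nu_g = np.asarray(nu_g, dtype=float)
    n = nu_g.size
    time = (np.arange(n) + 0.5) * dt / 1000.0
    light = np.where(
        (time >= opto.laser_on) & (time < opto.laser_off), opto.intensity, 0.0
    )
    s = np.empty(n)
    prev = 0.0
    c = dt / opto.tau_s
    for k in range(n):
        prev = prev + c * (light[k] - prev)
        s[k] = prev
    return (1.0 - opto.fraction) * nu_g + opto.fraction * np.maximum(nu_g - s, 0.0)


def run_condition_battery(
    condition: str,
    p: CircuitParams,
    rp: ReceptorParams,
    proto: TrialProtocol,
    rates: LearningRates | None = None,
    n_trials: int = 50,
    record: tuple[int, ...] = (),
) -> tuple[SessionResult, TrialTrace]:
    """Conditioning under one pharmacological condition plus a probe trace.

    control    : drug-free conditioning; probe = final-trial rerun.
    nicotine   : receptors pre-exposed to 5 min / 1 uM nicotine before every
                 trial; probe = final-trial rerun under nicotine.
    withdrawal : weights learned under nicotine, probe trial with drug-free,
                 fully resensitized receptors (washout assumption).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    pharm = (
        PharmacologySchedule.control()
        if condition == "control"
        else PharmacologySchedule.nicotine()
    )
    session = run_conditioning(
        p, rp, proto, pharm, rates=rates, n_trials=n_trials, record=record
    )
    probe_pharm = (
        PharmacologySchedule.withdrawal() if condition == "withdrawal" else pharm
    )
    probe = simulate_trial(p, rp, session.final_weights, proto, probe_pharm)
    return session, probe


def cs_dose_response(
    rewards,
    condition: str,
    p: CircuitParams,
    rp: ReceptorParams,
    proto: TrialProtocol | None = None,
    rates: LearningRates | None = None,
    n_trials: int = 50,
) -> DoseResponseCurve:
    """Learned CS burst amplitude for each reward size in one condition.

    For every reward size, a full conditioning session is run and the
    maximal DA rate within 200 ms of CS onset on the final trial is taken —
    the model's analogue of the cue-evoked dose-response curve.
    """
    proto = proto or TrialProtocol()
    peaks = []
    for reward in rewards:
        pr = TrialProtocol(
            trial_length=proto.trial_length,
            cs_onset=proto.cs_onset,
            cs_duration=proto.cs_duration,
            us_onset=proto.us_onset,
            us_duration=proto.us_duration,
            reward_size=float(reward),
        )
        session, probe = run_condition_battery(
            condition, p, rp, pr, rates=rates, n_trials=n_trials
        )
        peaks.append(measure_trial(probe, pr).cs_peak)
    return DoseResponseCurve(
        rewards=np.asarray(list(rewards), dtype=float),
        cs_peak=np.asarray(peaks),
        condition=condition,
    )


def pfc_fixed_points(
    j: float,
    cs_value: float,
    adaptation_level: float,
    p: CircuitParams,
    tol: float = 1e-6,
) -> list[tuple[float, bool]]:
    """Fixed points of the PFC rate equation and their stability.

    Solves nu = F(w_cs cs + J nu - a) on [0, omega] by sign-change
    bracketing on a fine grid followed by bisection. A fixed point is stable
    when the slope of the right-hand side, J F'(x), is below 1. The
    right-hand side is bounded and monotone in nu, so there are one, two
    (saddle-node) or three solutions: the low/rest state, an unstable
    separatrix and the Up state when the recurrence is strong enough.
    """

    def rhs(nu: float) -> float:
        return sigmoid(p.w_cs * cs_value + j * nu - adaptation_level, p.pfc_sigmoid)

    def g(nu: float) -> float:
        return rhs(nu) - nu

    omega = p.pfc_sigmoid.omega
    grid = np.linspace(0.0, omega, 3001)
    vals = np.array([g(x) for x in grid])
    roots: list[float] = []
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            roots.append(float(grid[k]))
        elif vals[k] * vals[k + 1] < 0:
            roots.append(float(brentq(g, grid[k], grid[k + 1], xtol=tol)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # merge near-duplicates from grid-point hits
    merged: list[float] = []
    for rt in sorted(roots):
        if not merged or rt - merged[-1] > 10 * tol:
            merged.append(rt)

    out = []
    for nu in merged:
        x = p.w_cs * cs_value + j * nu - adaptation_level
        f = sigmoid(x, p.pfc_sigmoid)
        fprime = p.pfc_sigmoid.beta * f * (1.0 - f / omega)
        out.append((nu, j * fprime < 1.0))
    return out


def softmax_choice(v_i: float, v_j: float, b: float) -> float:
    """Probability of choosing option i over j: 1 / (1 + exp(b (v_j - v_i)))."""
    if b < 0:
        raise ValueError("inverse temperature must be non-negative")
    if not (math.isfinite(v_i) and math.isfinite(v_j)):
        raise ValueError("values must be finite")
    arg = b * (v_j - v_i)
    arg = max(-500.0, min(500.0, arg))
    return 1.0 / (1.0 + math.exp(arg))


def _transition_matrix(values, b: float) -> np.ndarray:
    """3x3 alternation chain: zero diagonal, softmax off-diagonals."""
    v = list(values)
    if len(v) != 3:
        raise ValueError("the task has exactly three locations")
    m = np.zeros((3, 3))
    for i in range(3):
        j, k = [x for x in range(3) if x != i]
        m[i, j] = softmax_choice(v[j], v[k], b)
        m[i, k] = 1.0 - m[i, j]
    return m


def stationary_distribution(values, b: float) -> np.ndarray:
    """Exact long-run occupancy of the three-location alternation chain.

    Left fixed vector of the transition matrix, from a linear solve. This is
    the analytic oracle for :func:`run_decision_task`: the walk's visit
    proportions converge to it.
    """
    m = _transition_matrix(values, b)
    # solve pi (M - I) = 0 with sum(pi) = 1
    a = np.vstack([(m - np.eye(3)).T, np.ones(3)])
    rhs = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return pi


def run_decision_task(
    spec: DecisionTaskSpec, values, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate the alternation walk and return choice proportions.

    The mouse starts at a uniformly drawn location; at each of ``n_choices``
    steps it chooses between the two other locations by the softmax rule and
    moves there. Returned proportions count the chosen locations and sum
    to 1.
    """
    v = list(values)
    if len(v) != 3:
        raise ValueError("the task has exactly three locations")
    rng = rng or np.random.default_rng(spec.seed)
    m = _transition_matrix(v, b=spec.b)
    counts = np.zeros(3, dtype=np.int64)
    state = int(rng.integers(3))
    # sample all uniforms up front; each step picks between the two options
    u = rng.random(spec.n_choices)
    others = {i: tuple(x for x in range(3) if x != i) for i in range(3)}
    for n in range(spec.n_choices):
        j, k = others[state]
        state = j if u[n] < m[state, j] else k
        counts[state] += 1
    return counts / counts.sum()
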