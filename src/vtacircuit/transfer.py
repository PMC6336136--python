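"""Stateless transfer functions and linear filters shared by all populations.

Three primitives drive every population in the circuit:

* a linear rectifier ``Phi`` (used by the GABA population and the phasic
  filter output),
* a sigmoid transfer function ``F`` mapping total input current to a firing
  rate bounded by the maximal rate ``omega`` (used by the DA and PFC
  populations),
* a double-exponential "phasic" filter ``G_tau`` that converts a square
  input into a transient bump peaking at ``t = tau`` (used by the PPTg),
* a square-root Hill function describing the saturating response of the
  PPTg to reward size.

All functions are pure; parameters arrive via the config module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SigmoidParams",
    "HillParams",
    "PhasicFilterState",
    "rectifier",
    "sigmoid",
    "hill_response",
    "phasic_filter_step",
    "phasic_filter",
]

# exp() arguments are clamped here so the sigmoid saturates exactly instead
# of overflowing at double precision
_EXP_CLAMP = 500.0


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid rate transfer function.

    omega : maximal firing rate (Hz)
    gamma : inflection point (input units); sigmoid(gamma) = omega / 2
    beta  : slope at the inflection (1 / input units)
    """

    omega: float
    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.omega > 0 and self.beta > 0):
            raise ValueError("sigmoid requires omega > 0 and beta > 0")


@dataclass(frozen=True)
class HillParams:
    """Saturating reward-size response: f_max * sqrt(x) / (sqrt(x) + sqrt(h)).

    f_max : saturating rate (Hz)
    h     : reward size (uL) eliciting the half-maximum rate
    exponent is fixed at 0.5.
    """

    f_max: float
    h: float
    exponent: float = 0.5

    def __post_init__(self) -> None:
        if not (self.f_max > 0 and self.h > 0):
            raise ValueError("Hill function requires f_max > 0 and h > 0")
        if self.exponent != 0.5:
            raise ValueError("the PPTg dose-response uses a fixed exponent of 0.5")


@dataclass
class PhasicFilterState:
    """State of the two-stage low-pass cascade behind the phasic filter.

    For a non-negative input held from a zero initial state, x1 >= x2 >= 0
    at every step, so the rectified difference is the bump amplitude.
    """

    x1: float = 0.0
    x2: float = 0.0
    tau: float = 100.0  # ms

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("filter time constant must be positive")


def rectifier(x: float) -> float:
    """Linear rectifier Phi: keep the positive part, zero otherwise."""
    if not math.isfinite(x):
        raise ValueError(f"rectifier requires finite input, got {x!r}")
    return x if x > 0.0 else 0.0


def sigmoid(x: float, p: SigmoidParams) -> float:
    """Sigmoid transfer F(x) = omega / (1 + exp(-beta (x - gamma))).

    Strictly increasing, bounded in (0, omega); F(gamma) = omega / 2.
    """
    if not math.isfinite(x):
        raise ValueError(f"sigmoid requires finite input, got {x!r}")
    arg = -p.beta * (x - p.gamma)
    arg = max(-_EXP_CLAMP, min(_EXP_CLAMP, arg))
    return p.omega / (1.0 + math.exp(arg))


def sigmoid_inverse(rate: float, p: SigmoidParams) -> float:
    """Input that produces ``rate``: x = gamma - ln(omega/rate - 1) / beta."""
    if not 0.0 < rate < p.omega:
        raise ValueError("rate must lie strictly inside (0, omega)")
    return p.gamma - math.log(p.omega / rate - 1.0) / p.beta


def hill_response(x: float, p: HillParams) -> float:
    """Saturating dose-response of the PPTg to reward size ``x`` (uL).

    Monotone increasing from 0, equal to f_max/2 at x = h, saturating at
    f_max. Negative reward sizes are rejected.
    """
    if x < 0:
        raise ValueError("reward size must be non-negative")
    if x == 0:
        return 0.0
    sx = math.sqrt(x)
    return p.f_max * sx / (sx + math.sqrt(p.h))


def phasic_filter_step(
    state: PhasicFilterState, x: float, dt: float
) -> tuple[PhasicFilterState, float]:
    """Advance the phasic filter by one forward-Euler step.

    Integrates tau x1' = -x1 + x and tau x2' = -x2 + x1, then returns the
    rectified difference Phi(x1 - x2). For a unit step input from rest the
    output follows (t/tau) exp(-t/tau): a bump peaking at t = tau with
    amplitude 1/e.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= state.tau:
        raise ValueError(
            f"dt={dt} >= tau={state.tau}: forward Euler is unstable here"
        )
    c = dt / state.tau
    x1 = state.x1 + c * (x - state.x1)
    x2 = state.x2 + c * (state.x1 - state.x2)
    new = PhasicFilterState(x1=x1, x2=x2, tau=state.tau)
    return new, rectifier(x1 - x2)


def phasic_filter(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Vectorized phasic filter over a whole input series.

    Exactly replicates repeated :func:`phasic_filter_step` calls from a zero
    initial state (same forward-Euler recursion, evaluated with lfilter).
    """
    if dt <= 0 or dt >= tau:
        raise ValueError("need 0 < dt < tau")
    x = np.asarray(x, dtype=float)
    c = dt / tau
    # y[k] = (1 - c) y[k-1] + c u[k] matches the Euler step driven by u[k]
    b, a = [c], [1.0, -(1.0 - c)]
    x1 = lfilter(b, a, x)
    x2 = lfilter(b, a, np.concatenate(([0.0], x1[:-1])))
    return np.maximum(x1 - x2, 0.0)
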