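"""Four-state alpha4beta2 nAChR kinetics and pharmacology schedules.

The receptor pool is summarized by two independent gating variables: an
activation gate ``a`` (fraction of receptors with the channel open) and a
sensitization gate ``s`` (fraction not driven into the desensitized state).
The receptor can therefore occupy four states (activated or not, sensitized
or not) and the effective nAChR drive onto the circuit is the product
``nu_a4b2 = a * s``.

Both gates relax first-order toward concentration-dependent steady states:

    a_inf = (ACh + alpha Nic)^n_a / (EC50^n_a + (ACh + alpha Nic)^n_a)
    s_inf = IC50^n_s / (IC50^n_s + (Nic + eta ACh)^n_s)

``alpha > 1`` is the higher potency of nicotine relative to ACh; ``eta`` is
the fraction of the ACh concentration allowed to desensitize the receptor
(zero by default: only nicotine desensitizes). Activation is fast (its time
constant tau_a is concentration independent, order ms); desensitization and
recovery are slow, with a concentration-dependent time constant

    tau_d = tau_0 + tau_max K_tau^n_tau / (K_tau^n_tau + (Nic + eta ACh)^n_tau)

ranging from tau_0 (fast desensitization at saturating ligand) to
tau_0 + tau_max (slow recovery in the drug-free state). This ms-vs-minutes
timescale separation is what lets a few minutes of sub-uM nicotine silence
the cholinergic drive onto GABA neurons while leaving fast ACh transients
able to open whatever receptors remain sensitized.

The numeric constants of the gates are not constrained sharply by any single
experiment; the defaults in :mod:`vtacircuit.config` are calibrated against
three requirements (see docs/methods.md): 5 min of 1 uM nicotine
desensitizes most of the pool, uM-order sub-second ACh transients produce
sizeable activation, and the drug-free rest state of the circuit is left
essentially unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ReceptorParams",
    "ReceptorState",
    "PharmacologySchedule",
    "activation_steady",
    "sensitization_steady",
    "desensitization_tau",
    "step_receptor",
    "receptor_traces",
    "pre_expose",
]


@dataclass(frozen=True)
class ReceptorParams:
    """Constants of the two-gate nAChR model.

    Concentrations in uM, time constants in ms.
    """

    ec50: float = 8.0  # half-activation concentration [calibrated]
    ic50: float = 0.15  # half-sensitization concentration [calibrated]
    n_a: float = 1.5  # activation Hill coefficient [calibrated]
    n_s: float = 0.8  # sensitization Hill coefficient [calibrated]
    alpha: float = 3.0  # nicotine potency factor relative to ACh
    eta: float = 0.0  # fraction of ACh driving desensitization
    tau_a: float = 5.0  # activation time constant (concentration independent)
    tau_0: float = 500.0  # fastest desensitization time constant
    tau_max: float = 180_000.0  # drug-free recovery time constant
    k_tau: float = 0.3  # half-point of the desensitization time constant
    n_tau: float = 1.0  # Hill coefficient of the time constant

    def __post_init__(self) -> None:
        for name in ("ec50", "ic50", "tau_a", "tau_0", "tau_max", "k_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"receptor parameter {name} must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.alpha < 1.0:
            raise ValueError("alpha must be >= 1 (nicotine at least as potent as ACh)")


@dataclass(frozen=True)
class ReceptorState:
    """Gating variables: activated fraction ``a`` and sensitized fraction ``s``."""

    a: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.s <= 1.0):
            raise ValueError("receptor gates must lie in [0, 1]")

    @property
    def activation(self) -> float:
        """Effective nAChR drive nu_a4b2 = a * s, in [0, 1]."""
        return self.a * self.s


@dataclass(frozen=True)
class PharmacologySchedule:
    """Nicotine exposure protocol for one condition.

    pre_exposure_duration / pre_exposure_concentration describe the bath the
    receptors sit in before every trial (default 5 min at 1 uM for the
    nicotine condition). ``nicotine_during_trial`` controls whether that
    concentration persists during the trial itself; by default the drug is
    treated as washed out on the trial timescale, so the lasting trace of
    exposure is the desensitized receptor pool (recovery takes minutes, far
    longer than a trial). ``withdrawal_flag`` instead resets the receptors
    to the fully sensitized drug-free state with no nicotine anywhere — the
    washout probe after learning under nicotine.
    """

    pre_exposure_duration: float = 0.0  # s
    pre_exposure_concentration: float = 0.0  # uM
    nicotine_during_trial: bool = False
    withdrawal_flag: bool = False

    def __post_init__(self) -> None:
        if self.pre_exposure_duration < 0 or self.pre_exposure_concentration < 0:
            raise ValueError("pre-exposure duration and concentration must be >= 0")

    @property
    def trial_nicotine(self) -> float:
        """Nicotine concentration (uM) held constant during the trial."""
        if self.withdrawal_flag or not self.nicotine_during_trial:
            return 0.0
        return self.pre_exposure_concentration

    @staticmethod
    def control() -> "PharmacologySchedule":
        return PharmacologySchedule()

    @staticmethod
    def nicotine(
        concentration: float = 1.0, duration: float = 300.0
    ) -> "PharmacologySchedule":
        """5 min of 1 uM nicotine before every trial (defaults)."""
        return PharmacologySchedule(
            pre_exposure_duration=duration,
            pre_exposure_concentration=concentration,
        )

    @staticmethod
    def withdrawal(
        concentration: float = 1.0, duration: float = 300.0
    ) -> "PharmacologySchedule":
        return PharmacologySchedule(
            pre_exposure_duration=duration,
            pre_exposure_concentration=concentration,
            withdrawal_flag=True,
        )


def _check_conc(*concs: float) -> None:
    for c in concs:
        if c < 0:
            raise ValueError("concentrations must be non-negative")


def activation_steady(ach: float, nic: float, p: ReceptorParams) -> float:
    """Steady-state activated fraction a_inf(Nic, ACh) in [0, 1)."""
    _check_conc(ach, nic)
    lig = ach + p.alpha * nic
    if lig == 0.0:
        return 0.0
    x = lig**p.n_a
    return x / (p.ec50**p.n_a + x)


def sensitization_steady(nic: float, ach: float, p: ReceptorParams) -> float:
    """Steady-state sensitized fraction s_inf(Nic, ACh) in (0, 1]."""
    _check_conc(ach, nic)
    lig = nic + p.eta * ach
    if lig == 0.0:
        return 1.0
    k = p.ic50**p.n_s
    return k / (k + lig**p.n_s)


def desensitization_tau(nic: float, ach: float, p: ReceptorParams) -> float:
    """Concentration-dependent time constant (ms) of the sensitization gate.

    tau_0 + tau_max in the drug-free state (slow recovery), tau_0 at
    saturating ligand (fast desensitization), half way at Nic = K_tau.
    """
    _check_conc(ach, nic)
    lig = nic + p.eta * ach
    if lig == 0.0:
        return p.tau_0 + p.tau_max
    k = p.k_tau**p.n_tau
    return p.tau_0 + p.tau_max * k / (k + lig**p.n_tau)


def step_receptor(
    state: ReceptorState, ach: float, nic: float, dt: float, p: ReceptorParams
) -> ReceptorState:
    """Advance both gates by ``dt`` ms under piecewise-constant ligand.

    Each gate relaxes exponentially toward its steady state; the update
    y <- y_inf + (y - y_inf) exp(-dt / tau_y) is exact for ligand held
    constant over the step, so halving dt does not change trajectories.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_inf = activation_steady(ach, nic, p)
    s_inf = sensitization_steady(nic, ach, p)
    tau_d = desensitization_tau(nic, ach, p)
    a = a_inf + (state.a - a_inf) * math.exp(-dt / p.tau_a)
    s = s_inf + (state.s - s_inf) * math.exp(-dt / tau_d)
    return ReceptorState(a=a, s=s)


def receptor_traces(
    ach: np.ndarray,
    nic: float,
    dt: float,
    p: ReceptorParams,
    init: ReceptorState,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate trajectories over a whole trial, nicotine constant.

    Replicates repeated :func:`step_receptor` calls (same exact exponential
    per-step update), vectorized with lfilter for the activation gate. The
    element at index k is the state *after* step k, i.e. the gate values a
    circuit step taken at sample k+1 would read; callers prepend the initial
    state as needed. With ``eta > 0`` the sensitization gate sees the ACh
    series and is integrated step by step instead.
    """
    ach = np.asarray(ach, dtype=float)
    n = ach.size
    lam = math.exp(-dt / p.tau_a)
    a_inf = np.array([activation_steady(c, nic, p) for c in ach])
    # a[k] = lam a[k-1] + (1 - lam) a_inf[k]
    a = lfilter([1.0 - lam], [1.0, -lam], a_inf, zi=[lam * init.a])[0]
    if p.eta == 0.0:
        s_inf = sensitization_steady(nic, 0.0, p)
        mu = math.exp(-dt / desensitization_tau(nic, 0.0, p))
        k = np.arange(1, n + 1)
        s = s_inf + (init.s - s_inf) * mu**k
    else:
        s = np.empty(n)
        prev = init.s
        for i in range(n):
            s_inf = sensitization_steady(nic, ach[i], p)
            mu = math.exp(-dt / desensitization_tau(nic, ach[i], p))
            prev = s_inf + (prev - s_inf) * mu
            s[i] = prev
    return a, s


def pre_expose(p: ReceptorParams, sched: PharmacologySchedule) -> ReceptorState:
    """Receptor state at trial start under the given pharmacology.

    Computed with the closed-form exponential relaxation under the constant
    pre-exposure bath (ACh = 0) — no time stepping needed. The withdrawal
    probe resets the pool to the fully sensitized drug-free state.
    """
    if sched.withdrawal_flag:
        return ReceptorState(a=0.0, s=1.0)
    dur_ms = sched.pre_exposure_duration * 1000.0
    nic = sched.pre_exposure_concentration
    if dur_ms == 0.0 or nic == 0.0:
        return ReceptorState(a=0.0, s=1.0)
    a_inf = activation_steady(0.0, nic, p)
    s_inf = sensitization_steady(nic, 0.0, p)
    tau_d = desensitization_tau(nic, 0.0, p)
    a = a_inf * (1.0 - math.exp(-dur_ms / p.tau_a))
    s = s_inf + (1.0 - s_inf) * math.exp(-dur_ms / tau_d)
    return ReceptorState(a=a, s=s)
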