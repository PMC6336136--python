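"""Coupled population dynamics of the VTA and its afferents over one trial.

Four populations are integrated with forward Euler at a common step ``dt``
(default 1 ms):

* **PFC** — a recurrent working-memory population with spike-frequency
  adaptation. The conditioned stimulus (CS, a 0.5 s tone) drives it onto a
  high-rate branch; the recurrent weight ``J_PFC`` (learned across trials)
  controls how long the Up state survives after CS offset before adaptation
  collapses it.
* **PPTg** — responds phasically to the unconditioned stimulus (US, the
  water reward): a square pulse of amplitude equal to the reward size is
  passed through a saturating Hill function and a double-exponential filter,
  giving a burst peaking ~100 ms after reward onset. The PPTg also releases
  acetylcholine in proportion to its rate.
* **VTA GABA** — a linear-rectifier population excited by PFC (via the
  corticostriatal weight ``w_PFC-G``), by PPTg glutamate, and by the nAChR
  current; it feeds forward inhibition onto the DA population.
* **VTA DA** — a sigmoidal population combining a baseline drive, GABA
  inhibition, PFC/PPTg glutamatergic excitation and a share ``r`` of the
  nAChR current. Its rest rate is ~5 Hz and its bursts saturate at 30 Hz.

Because GABA inhibition reaches the DA population one membrane time
constant (~30 ms) later than the shared excitation, fast transients of the
PFC rate are differentiated: the rise at CS onset produces a DA burst and
the collapse at the (learned) reward time produces a dip that cancels the
PPTg-driven reward burst. That temporal asymmetry is the circuit's reward
prediction error computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .receptors import (
    PharmacologySchedule,
    ReceptorParams,
    ReceptorState,
    pre_expose,
    receptor_traces,
)
from .transfer import HillParams, SigmoidParams, hill_response, phasic_filter, sigmoid

__all__ = [
    "CircuitParams",
    "LearnableWeights",
    "TrialProtocol",
    "TrialTrace",
    "stimulus_signals",
    "pptg_rate",
    "input_currents",
    "pfc_step",
    "vta_step",
    "simulate_trial",
]


@dataclass(frozen=True)
class CircuitParams:
    """Fixed constants of the circuit. Time constants in ms, rates in Hz.

    Printed model constants keep their published values (baselines, time
    constants, sigmoid shapes, r, w_alpha4b2, w_ach); the remaining weights
    are calibrated as documented in docs/methods.md. ``w_g_d`` is fixed by
    requiring the drug-free rest state to sit at nu_D = 5 Hz given
    nu_G = B_G = 14 Hz: w_g_d = (B_D - F^{-1}(5)) / B_G ~= 1.0975.
    """

    tau_d: float = 30.0  # DA membrane time constant
    tau_g: float = 30.0  # GABA membrane time constant
    tau_pfc: float = 100.0  # PFC time constant
    tau_pptg: float = 100.0  # PPTg phasic filter time constant
    b_d: float = 18.0  # DA baseline drive
    b_g: float = 14.0  # GABA baseline drive
    r: float = 0.2  # fraction of nAChR current onto DA (rest onto GABA)
    w_g_d: float = 1.0975  # GABA -> DA inhibition
    w_ppt_d: float = 1.4  # PPTg -> DA glutamate [calibrated]
    w_ppt_g: float = 0.6  # PPTg -> GABA glutamate [calibrated]
    w_alpha4b2: float = 15.0  # nAChR current weight
    w_ach: float = 1.0  # cholinergic gain, uM of ACh per Hz of PPTg rate
    w_cs: float = 20.0  # CS input strength onto PFC [calibrated]
    c_adapt: float = 1.0  # adaptation gain (a_inf = c * nu_PFC) [calibrated]
    tau_adapt: float = 1000.0  # adaptation time constant
    da_sigmoid: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(30.0, 8.0, 0.3)
    )
    pfc_sigmoid: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(30.0, 8.0, 0.5)
    )
    pptg_hill: HillParams = field(default_factory=lambda: HillParams(70.0, 20.0))
    dt: float = 1.0  # integration step (ms)
    relax_duration: float = 2.0  # pre-trial relaxation (s of model time)

    def __post_init__(self) -> None:
        for name in ("tau_d", "tau_g", "tau_pfc", "tau_pptg", "tau_adapt", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        for name in ("w_g_d", "w_ppt_d", "w_ppt_g", "w_alpha4b2", "w_ach", "w_cs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt >= min(self.tau_d, self.tau_g, self.tau_pfc, self.tau_pptg):
            raise ValueError("dt must be well below every time constant")


@dataclass(frozen=True)
class LearnableWeights:
    """Weights updated across trials.

    ``w_pfc_d`` and ``w_pfc_g`` (the corticostriatal route onto DA and GABA
    neurons) are constrained equal at all trials; ``j_pfc`` is the PFC
    recurrent excitation. A naive animal starts with j_pfc = 0.2 and zero
    corticostriatal weight (no reward expectation).
    """

    j_pfc: float = 0.2
    w_pfc_d: float = 0.0
    w_pfc_g: float = 0.0

    def __post_init__(self) -> None:
        if self.w_pfc_d != self.w_pfc_g:
            raise ValueError("w_pfc_d and w_pfc_g must stay equal")
        if min(self.j_pfc, self.w_pfc_d) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of one trace-conditioning trial (seconds).

    A 0.5 s tone (CS) and a 0.5 s reward delivery (US) with onsets 1.5 s
    apart inside a 3 s trial; the reward size is in uL of water.
    """

    trial_length: float = 3.0
    cs_onset: float = 0.5
    cs_duration: float = 0.5
    us_onset: float = 2.0
    us_duration: float = 0.5
    reward_size: float = 4.0
    reward_omitted: bool = False

    def __post_init__(self) -> None:
        if self.cs_onset + self.cs_duration > self.us_onset:
            raise ValueError("CS must end before US onset")
        if self.us_onset + self.us_duration > self.trial_length:
            raise ValueError("US must end before the trial does")
        if self.reward_size < 0:
            raise ValueError("reward size must be non-negative")


@dataclass
class TrialTrace:
    """Time-indexed record of one simulated trial.

    ``time`` holds step centers in seconds; every other array has the same
    length. Rates in Hz, concentrations in uM.
    """

    time: np.ndarray
    nu_pfc: np.ndarray
    nu_pptg: np.ndarray
    nu_g: np.ndarray
    nu_d: np.ndarray
    adaptation: np.ndarray
    i_g_d: np.ndarray
    i_glu_d: np.ndarray
    i_glu_g: np.ndarray
    i_a4b2: np.ndarray
    ach: np.ndarray
    nic: np.ndarray
    receptor_a: np.ndarray
    receptor_s: np.ndarray
    dt: float  # seconds

    def window(self, start: float, width: float) -> np.ndarray:
        """Boolean mask for the half-open window [start, start + width)."""
        return (self.time >= start) & (self.time < start + width)

    def value_at(self, series: np.ndarray, t: float) -> float:
        """Series value at the first sample with time >= t."""
        idx = int(np.searchsorted(self.time, t))
        idx = min(idx, len(self.time) - 1)
        return float(series[idx])


def _time_grid(length_s: float, dt_ms: float) -> np.ndarray:
    n = int(round(length_s * 1000.0 / dt_ms))
    return (np.arange(n) + 0.5) * (dt_ms / 1000.0)


def stimulus_signals(
    proto: TrialProtocol, dt_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Square CS and US pulses on the trial time grid.

    Returns (time, cs, us): cs = 1 on [cs_onset, cs_onset + cs_duration),
    us = reward_size on [us_onset, us_onset + us_duration) (identically zero
    on omission probes).
    """
    t = _time_grid(proto.trial_length, dt_ms)
    cs = ((t >= proto.cs_onset) & (t < proto.cs_onset + proto.cs_duration)).astype(
        float
    )
    us = np.zeros_like(t)
    if not proto.reward_omitted and proto.reward_size > 0:
        mask = (t >= proto.us_onset) & (t < proto.us_onset + proto.us_duration)
        us[mask] = proto.reward_size
    return t, cs, us


def pptg_rate(us: np.ndarray, p: CircuitParams) -> np.ndarray:
    """PPTg population rate: Hill dose-response then the phasic filter.

    The square reward pulse is converted to a firing rate by the saturating
    Hill function and differentiated into a transient burst peaking
    tau_pptg after reward onset (amplitude f(reward)/e).
    """
    us = np.asarray(us, dtype=float)
    if np.any(us < 0):
        raise ValueError("US series must be non-negative")
    drive = np.array([hill_response(x, p.pptg_hill) for x in np.unique(us)])
    lut = dict(zip(np.unique(us), drive))
    f_us = np.array([lut[x] for x in us])
    return phasic_filter(f_us, p.tau_pptg, p.dt)


def input_currents(
    nu_pfc: float,
    nu_pptg: float,
    nu_g: float,
    receptor_activation: float,
    weights: LearnableWeights,
    p: CircuitParams,
) -> tuple[float, float, float, float]:
    """Synaptic currents (I_G-D, I_Glu-D, I_Glu-G, I_a4b2) from the rates."""
    i_g_d = p.w_g_d * nu_g
    i_glu_d = weights.w_pfc_d * nu_pfc + p.w_ppt_d * nu_pptg
    i_glu_g = weights.w_pfc_g * nu_pfc + p.w_ppt_g * nu_pptg
    i_a4b2 = p.w_alpha4b2 * receptor_activation
    return i_g_d, i_glu_d, i_glu_g, i_a4b2


def pfc_step(
    nu_pfc: float,
    adaptation: float,
    cs_value: float,
    weights: LearnableWeights,
    p: CircuitParams,
    dt: float,
) -> tuple[float, float]:
    """One Euler step of the PFC working-memory population with adaptation.

    tau_pfc nu' = -nu + F(w_cs cs + J_pfc nu - a),  tau_a a' = c nu - a.
    """
    arg = p.w_cs * cs_value + weights.j_pfc * nu_pfc - adaptation
    nu_new = nu_pfc + (dt / p.tau_pfc) * (-nu_pfc + sigmoid(arg, p.pfc_sigmoid))
    a_new = adaptation + (dt / p.tau_adapt) * (p.c_adapt * nu_pfc - adaptation)
    return nu_new, a_new


def vta_step(
    nu_d: float,
    nu_g: float,
    currents: tuple[float, float, float, float],
    p: CircuitParams,
    dt: float,
) -> tuple[float, float]:
    """One Euler step of the coupled DA and GABA populations.

    tau_D nu_D' = -nu_D + F(B_D - I_G-D + I_Glu-D + r I_a4b2)
    tau_G nu_G' = -nu_G + Phi(B_G + I_Glu-G + (1-r) I_a4b2)
    """
    i_g_d, i_glu_d, i_glu_g, i_a4b2 = currents
    arg_d = p.b_d - i_g_d + i_glu_d + p.r * i_a4b2
    arg_g = p.b_g + i_glu_g + (1.0 - p.r) * i_a4b2
    nu_d_new = nu_d + (dt / p.tau_d) * (-nu_d + sigmoid(arg_d, p.da_sigmoid))
    nu_g_new = nu_g + (dt / p.tau_g) * (-nu_g + max(arg_g, 0.0))
    return nu_d_new, nu_g_new


def _opto_subtraction(n: int, time: np.ndarray, opto, dt_ms: float) -> np.ndarray:
    """Euler integration of tau_s s' = -s + nu_light over the trial grid."""
    light = np.where(
        (time >= opto.laser_on) & (time < opto.laser_off), opto.intensity, 0.0
    )
    c = dt_ms / opto.tau_s
    return lfilter([c], [1.0, -(1.0 - c)], light)


def simulate_trial(
    p: CircuitParams,
    rp: ReceptorParams,
    weights: LearnableWeights,
    proto: TrialProtocol,
    pharm: PharmacologySchedule | None = None,
    opto=None,
    initial_rates: tuple[float, float] | None = None,
) -> TrialTrace:
    """Integrate the full circuit over one trial and return the trace.

    The receptor pool starts from the pharmacology-determined state (e.g.
    desensitized after 5 min of nicotine). Rates start from the condition's
    rest state, found by relaxing the circuit for ``relax_duration`` seconds
    of model time with no stimuli before t = 0. If an optogenetic protocol
    is given, a low-pass-filtered copy of the laser signal is subtracted
    from the affected fraction of the GABA population before it inhibits DA
    (open loop: GABA has no self-connection, so only the DA-bound current
    changes).
    """
    pharm = pharm or PharmacologySchedule.control()
    dt = p.dt
    time, cs, us = stimulus_signals(proto, dt)
    n = time.size
    nu_pptg = pptg_rate(us, p)
    ach = p.w_ach * nu_pptg
    nic = pharm.trial_nicotine

    rec0 = pre_expose(rp, pharm)

    # pre-trial relaxation: no stimuli, condition-appropriate ligands
    n_relax = int(round(p.relax_duration * 1000.0 / dt))
    relax_ach = np.zeros(n_relax)
    ra, rs = receptor_traces(relax_ach, nic, dt, rp, rec0)
    nu_pfc, adaptation = 0.0, 0.0
    nu_d, nu_g = initial_rates if initial_rates is not None else (5.0, p.b_g)
    for k in range(n_relax):
        act = ra[k] * rs[k]
        cur = input_currents(nu_pfc, 0.0, nu_g, act, weights, p)
        nu_d, nu_g = vta_step(nu_d, nu_g, cur, p, dt)
        nu_pfc, adaptation = pfc_step(nu_pfc, adaptation, 0.0, weights, p, dt)
    rec_relaxed = ReceptorState(a=float(ra[-1]) if n_relax else rec0.a,
                                s=float(rs[-1]) if n_relax else rec0.s)

    # receptor gates across the trial (driven by the phasic ACh outflow)
    rec_a, rec_s = receptor_traces(ach, nic, dt, rp, rec_relaxed)
    activation = rec_a * rec_s

    # a dark laser is exactly the control condition
    if opto is not None and opto.intensity == 0.0:
        opto = None
    s_opto = _opto_subtraction(n, time, opto, dt) if opto is not None else None
    frac = getattr(opto, "fraction", 0.0) if opto is not None else 0.0

    out_pfc = np.empty(n)
    out_g = np.empty(n)
    out_d = np.empty(n)
    out_adapt = np.empty(n)
    out_igd = np.empty(n)
    out_iglud = np.empty(n)
    out_iglug = np.empty(n)
    out_ia4b2 = np.empty(n)

    for k in range(n):
        nu_g_eff = nu_g
        if s_opto is not None:
            nu_g_eff = (1.0 - frac) * nu_g + frac * max(nu_g - s_opto[k], 0.0)
        cur = input_currents(nu_pfc, nu_pptg[k], nu_g_eff, activation[k], weights, p)
        nu_d, nu_g = vta_step(nu_d, nu_g, cur, p, dt)
        nu_pfc, adaptation = pfc_step(nu_pfc, adaptation, cs[k], weights, p, dt)
        out_pfc[k] = nu_pfc
        out_g[k] = nu_g
        out_d[k] = nu_d
        out_adapt[k] = adaptation
        out_igd[k], out_iglud[k], out_iglug[k], out_ia4b2[k] = cur

    if not np.all(np.isfinite(out_d)) or not np.all(np.isfinite(out_g)):
        raise FloatingPointError("circuit integration diverged (non-finite rates)")

    return TrialTrace(
        time=time,
        nu_pfc=out_pfc,
        nu_pptg=nu_pptg,
        nu_g=out_g,
        nu_d=out_d,
        adaptation=out_adapt,
        i_g_d=out_igd,
        i_glu_d=out_iglud,
        i_glu_g=out_iglug,
        i_a4b2=out_ia4b2,
        ach=ach,
        nic=np.full(n, nic),
        receptor_a=rec_a,
        receptor_s=rec_s,
        dt=dt / 1000.0,
    )
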