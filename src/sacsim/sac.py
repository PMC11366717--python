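"""Stretch-activated-channel current and conductance time course.

The SAC current is linear, ``ISAC = gSAC (Vm - ESAC)``, with a
time-varying conductance relaxing exponentially toward a target,

    d gSAC / dt = -(gSAC - gSAC_target) / tau.

At the activation onset the target jumps from 0 to ``g_target_max``; once
gSAC approaches the target to within ``eps_switch`` the target is reset to
0, giving a rising phase of analytic length ``tau * ln(g_target_max /
eps_switch)`` followed by exponential decay.  With the defaults
(tau = 1.8 ms, target 0.1 mS/uF, eps 1e-13) the rising phase is ~50 ms.
The same drive is broadcast to every cell of the SAC region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_OFF = "off"
PHASE_RISING = "rising"
PHASE_DECAYING = "decaying"
PHASE_DONE = "done"

#: g_sac below which a decaying drive counts as finished (mS/uF)
_DONE_TOL = 1e-15


@dataclass
class SACParams:
    """SAC drive configuration.

    e_sac : reversal potential (mV), -70 ... -10 in study configurations.
    g_target_max : peak conductance target (mS/uF).
    tau : relaxation time constant (ms).
    eps_switch : proximity tolerance triggering target switch-off (mS/uF).
    onset : activation time relative to the last sinus pacing (ms).
    """

    e_sac: float = -10.0
    g_target_max: float = 0.1
    tau: float = 1.8
    eps_switch: float = 1e-13
    onset: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.eps_switch <= self.g_target_max:
            raise ValueError("need 0 < eps_switch <= g_target_max")


def pulse_on_duration(params: SACParams) -> float:
    """Analytic rising-phase length tau*ln(g_target_max/eps_switch) in ms."""
    if not params.g_target_max >= params.eps_switch > 0:
        raise ValueError("need g_target_max >= eps_switch > 0")
    return params.tau * np.log(params.g_target_max / params.eps_switch)


def tau_for_pulse_length(length_ms: float, g_target_max: float = 0.1,
                         eps_switch: float = 1e-13) -> float:
    """Time constant giving a rising phase of ``length_ms`` ms."""
    return length_ms / np.log(g_target_max / eps_switch)


@dataclass
class SACDrive:
    """Instantaneous state of the broadcast SAC conductance."""

    g_sac: float = 0.0
    g_target: float = 0.0
    phase: str = PHASE_OFF


def advance_gsac(drive: SACDrive, params: SACParams, t: float,
                 dt: float) -> SACDrive:
    """Advance the drive from time ``t`` to ``t + dt`` (exact update).

    The relaxation uses the exact exponential solution
    ``g <- target + (g - target) exp(-dt/tau)``, so the trajectory is
    step-size independent; the switch-off check runs once per call.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g, target, phase = drive.g_sac, drive.g_target, drive.phase
    if phase == PHASE_OFF:
        if t + dt > params.onset + 1e-12:
            # sub-step alignment: relax only over the post-onset fraction
            eff = min(dt, t + dt - params.onset)
            target = params.g_target_max
            phase = PHASE_RISING
            g = target + (g - target) * np.exp(-eff / params.tau)
        else:
            return SACDrive(g, target, phase)
    else:
        g = target + (g - target) * np.exp(-dt / params.tau)
    if phase == PHASE_RISING and abs(g - params.g_target_max) < params.eps_switch:
        target = 0.0
        phase = PHASE_DECAYING
    if phase == PHASE_DECAYING and g < _DONE_TOL:
        phase = PHASE_DONE
    return SACDrive(g, target, phase)


def gsac_closed_form(t, params: SACParams, t_switch: float | None = None):
    """Piecewise closed-form gSAC(t).

    Rising phase from ``onset``; exponential decay from ``t_switch``
    (default: the analytic switch time ``onset + pulse_on_duration``).
    With a per-step switch check the realized switch lands on the first
    step boundary at/after the analytic time; passing that boundary as
    ``t_switch`` makes the closed form exact for the discrete trajectory.
    """
    t = np.asarray(t, dtype=float)
    t_on = params.onset
    if t_switch is None:
        t_switch = t_on + pulse_on_duration(params)
    gmax, tau = params.g_target_max, params.tau
    g_sw = gmax * (1.0 - np.exp(-(t_switch - t_on) / tau))
    rise = gmax * (1.0 - np.exp(-(t - t_on) / tau))
    decay = g_sw * np.exp(-(t - t_switch) / tau)
    return np.where(t < t_on, 0.0, np.where(t < t_switch, rise, decay))
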