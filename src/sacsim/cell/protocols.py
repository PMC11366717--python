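"""Single-cell pacing protocols and action-potential measurements.

The protocols here mirror the cell-level experiments of the tissue study:
steady-state prepacing (50 beats at the tissue basic cycle length), APD90
measurement, and the phase-response scan in which a 50 ms SAC conductance
pulse is applied at chosen times during/after a paced action potential for
a range of SAC reversal potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from . import tt06
from .tt06 import NSTATE, VARIANTS, _EMPTY_TAB
from ..sac import SACParams

STATE_NAMES = (
    "m", "h", "j", "d", "f", "f2", "r", "s", "xr1", "xr2", "xs",
    "fcass", "rbar", "cai", "cass", "casr", "nai", "ki",
)

#: upstroke / secondary-AP detection threshold (mV), used package-wide
AP_THRESHOLD = -20.0

#: default single-cell solver step (ms)
DT_CELL = 0.02

#: default single-cell stimulus: depolarizing, uA/uF for 1 ms
STIM_AMP = 52.0
STIM_DUR = 1.0


class IntegrationError(RuntimeError):
    """Cell-model integration produced a non-finite state."""


class TruncatedTraceError(ValueError):
    """The trace ends before the action potential has repolarized."""


@dataclass
class CellParams:
    """Cell-type and conductance-scaling parameters.

    ``iks_scale`` is the heterogeneity factor on the slow delayed
    rectifier (1 basal-endocardial ... 4 apical-epicardial);
    ``gkr_adjust`` is the fixed baseline calibration factor on IKr that
    places APD90 of the scale-1 cell at its 290 ms reference value at
    BCL 500 ms (see :mod:`sacsim.cell.calibration`).
    """

    variant: str = "epi"
    iks_scale: float = 1.0
    cm: float = 1.0  # uF/cm^2
    gkr_adjust: float | None = None
    gks_adjust: float | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown cell variant {self.variant!r}")
        if not 1.0 <= self.iks_scale <= 4.0:
            raise ValueError("iks_scale must lie in [1, 4]")
        from .calibration import GKR_ADJUST, GKS_ADJUST

        if self.gkr_adjust is None:
            self.gkr_adjust = GKR_ADJUST
        if self.gks_adjust is None:
            self.gks_adjust = GKS_ADJUST

    @property
    def variant_id(self) -> int:
        return VARIANTS[self.variant]

    @property
    def gks_eff(self) -> float:
        base = {
            "epi": tt06.G_KS_EPI, "endo": tt06.G_KS_ENDO, "mid": tt06.G_KS_MID
        }[self.variant]
        return base * self.gks_adjust * self.iks_scale

    @property
    def gto(self) -> float:
        return {
            "epi": tt06.G_TO_EPI, "endo": tt06.G_TO_ENDO, "mid": tt06.G_TO_MID
        }[self.variant]

    @property
    def gkr(self) -> float:
        return tt06.G_KR * self.gkr_adjust


@dataclass
class CellState:
    """Full ionic state of one cell plus its SAC conductance."""

    vm: float
    state: np.ndarray  # length NSTATE, see sacsim.cell.tt06
    g_sac: float = 0.0

    @property
    def gates(self) -> np.ndarray:
        return self.state[:13]

    @property
    def concentrations(self) -> np.ndarray:
        return self.state[13:]

    def copy(self) -> "CellState":
        return CellState(self.vm, self.state.copy(), self.g_sac)

    def validate(self):
        if not np.isfinite(self.vm) or not np.all(np.isfinite(self.state)):
            raise IntegrationError(first_bad_variable(self.vm, self.state))
        if np.any(self.gates < -1e-9) or np.any(self.gates > 1.0 + 1e-9):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(self.concentrations <= 0):
            raise ValueError("non-positive ionic concentration")
        if self.g_sac < 0:
            raise ValueError("negative SAC conductance")


def first_bad_variable(vm, state) -> str:
    if not np.isfinite(vm):
        return "integration failure: non-finite vm"
    for name, val in zip(STATE_NAMES, state):
        if not np.isfinite(val):
            return f"integration failure: non-finite {name}"
    return "integration failure"


@njit(cache=True)
def _run_cell(v, s, dt, n_steps, stim_steps, stim_amp, stim_dur_steps,
              sac_step, tau, gmax, eps, esac, gks_eff, gto, gkr, variant,
              v_out, g_out):
    """Fixed-step single-cell run with periodic stimuli and one SAC pulse.

    ``stim_steps`` holds the step index of each stimulus onset;
    ``sac_step`` < 0 disables the SAC drive.  Records Vm and gSAC per step.
    """
    g = 0.0
    target = 0.0
    rising_done = False
    ptr = 0
    stim_until = -1
    for k in range(n_steps):
        if ptr < stim_steps.shape[0] and k >= stim_steps[ptr]:
            stim_until = stim_steps[ptr] + stim_dur_steps
            ptr += 1
        istim = stim_amp if k < stim_until else 0.0
        if sac_step >= 0 and k >= sac_step and not rising_done:
            target = gmax
        v = tt06._step_one(v, s, dt, istim, g, esac, gks_eff, gto, gkr,
                           variant, False, 0.0, 0.0, _EMPTY_TAB, _EMPTY_TAB)
        g = target + (g - target) * np.exp(-dt / tau)
        if not rising_done and np.abs(g - gmax) < eps:
            rising_done = True
            target = 0.0
        v_out[k] = v
        g_out[k] = g
    return v


def run_cell(state: CellState, params: CellParams, duration: float,
             stim_times=(), sac: SACParams | None = None, dt: float = DT_CELL,
             stim_amp: float = STIM_AMP, stim_dur: float = STIM_DUR):
    """Run one cell for ``duration`` ms; returns (t, vm, gsac, end_state).

    The input state is not modified.  ``sac`` activates the SAC
    conductance pulse at ``sac.onset`` ms (relative to the run start).
    """
    n_steps = int(round(duration / dt))
    stim_steps = np.array(sorted(int(round(t / dt)) for t in stim_times),
                          dtype=np.int64)
    v_out = np.empty(n_steps)
    g_out = np.empty(n_steps)
    if sac is None:
        sac_step, tau, gmax, eps, esac = -1, 1.0, 0.0, 1e-13, 0.0
    else:
        sac_step = int(round(sac.onset / dt))
        tau, gmax, eps, esac = sac.tau, sac.g_target_max, sac.eps_switch, sac.e_sac
    s = state.state.copy()
    v_end = _run_cell(state.vm, s, dt, n_steps, stim_steps, stim_amp,
                      int(round(stim_dur / dt)), sac_step, tau, gmax, eps,
                      esac, params.gks_eff, params.gto, params.gkr,
                      params.variant_id, v_out, g_out)
    if not np.isfinite(v_end) or not np.all(np.isfinite(s)):
        raise IntegrationError(first_bad_variable(v_end, s))
    t = dt * (1 + np.arange(n_steps))
    return t, v_out, g_out, CellState(v_end, s, float(g_out[-1]))


def step_cell(state: CellState, params: CellParams, dt: float,
              i_stim: float = 0.0, sac: SACParams | None = None,
              sac_active: bool = False) -> CellState:
    """Advance one cell by a single reaction step (exact gate updates)."""
    if dt > 0.1:
        raise ValueError("dt above the 0.1 ms single-step stability bound")
    s = state.state.copy()
    gsac = state.g_sac if (sac_active and sac is not None) else 0.0
    esac = sac.e_sac if sac is not None else 0.0
    v = tt06._step_one(state.vm, s, dt, i_stim, gsac, esac, params.gks_eff,
                       params.gto, params.gkr, params.variant_id,
                       False, 0.0, 0.0, _EMPTY_TAB, _EMPTY_TAB)
    if not np.isfinite(v) or not np.all(np.isfinite(s)):
        raise IntegrationError(first_bad_variable(v, s))
    return CellState(v, s, state.g_sac)


def init_and_prepace(params: CellParams, bcl: float, n_beats: int = 50,
                     dt: float = DT_CELL) -> CellState:
    """Pace a cell from the published resting state to its limit cycle.

    Returns the state immediately before the (n_beats+1)-th stimulus,
    the standard initial condition for tissue runs.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    V, S = tt06.initial_state(1)
    state = CellState(float(V[0]), S[0])
    stim_times = [i * bcl for i in range(n_beats)]
    _, _, _, end = run_cell(state, params, n_beats * bcl, stim_times)
    end.validate()
    return end


def measure_apd90(t: np.ndarray, vm: np.ndarray, t_stim: float,
                  threshold: float = AP_THRESHOLD) -> float:
    """APD at 90 % repolarization of the AP following the stimulus at ``t_stim``.

    Amplitude is peak Vm minus the pre-stimulus resting Vm of that beat;
    the AP starts at the upward crossing of ``threshold``.  Returns NaN if
    no upstroke crosses the detection threshold; raises
    :class:`TruncatedTraceError` if the trace ends unrepolarized.
    """
    t = np.asarray(t)
    vm = np.asarray(vm)
    pre = vm[t < t_stim]
    v_rest = pre[-1] if pre.size else vm[0]
    after = t >= t_stim
    ta, va = t[after], vm[after]
    up = np.flatnonzero((va[1:] >= threshold) & (va[:-1] < threshold))
    if up.size == 0:
        return float("nan")
    i_up = up[0] + 1
    t_up = ta[i_up]
    v_peak = va[i_up:].max()
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.flatnonzero(va[i_up:] <= v90)
    if below.size == 0:
        raise TruncatedTraceError("trace ends before 90% repolarization")
    return float(ta[i_up + below[0]] - t_up)


def run_phase_response(esac_list, onset_times, pulse: SACParams,
                       params: CellParams, bcl: float = 500.0,
                       n_prepace: int = 50, duration: float = 1000.0,
                       dt: float = DT_CELL) -> pd.DataFrame:
    """Scan SAC pulses over reversal potentials and onset times.

    Each run starts from the prepaced limit cycle, applies one stimulus at
    t=0 and the SAC pulse at the given onset.  Returns one row per
    (e_sac, onset) with the secondary-AP flag (a second upward crossing of
    the detection threshold after pulse onset), the APD90 change relative
    to the SAC-free reference beat, and the maximum depolarizing
    deflection of Vm relative to the reference during/after the pulse.
    """
    base = init_and_prepace(params, bcl, n_prepace, dt=dt)
    t_ref, v_ref, _, _ = run_cell(base, params, duration, [0.0], None, dt=dt)
    apd_ref = measure_apd90(t_ref, v_ref, 0.0)
    rows = []
    for onset in onset_times:
        if onset >= duration:
            raise ValueError(f"SAC onset {onset} ms beyond trace length")
        for esac in esac_list:
            sac = replace(pulse, e_sac=float(esac), onset=float(onset))
            t, v, g, _ = run_cell(base, params, duration, [0.0], sac, dt=dt)
            after = t >= onset
            va = v[after]
            sec = bool(np.any((va[1:] >= AP_THRESHOLD)
                              & (va[:-1] < AP_THRESHOLD)))
            # APD of the (possibly SAC-modified) paced AP
            apd = measure_apd90(t, v, 0.0)
            defl = float(np.max(v[after] - v_ref[after]))
            rows.append({
                "e_sac": float(esac), "onset": float(onset),
                "secondary_ap": sec, "apd90": apd,
                "delta_apd": apd - apd_ref, "max_deflection": defl,
            })
    df = pd.DataFrame(rows)
    df.attrs["apd90_reference"] = apd_ref
    return df


def export_trace(path, t, vm, gsac=None):
    """Write a delimited text trace: time (ms), Vm (mV)[, gSAC (mS/uF)]."""
    cols = {"t_ms": t, "vm_mv": vm}
    if gsac is not None:
        cols["gsac_ms_per_uf"] = gsac
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
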