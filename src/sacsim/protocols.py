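"""Tissue-scale experiment protocols and outcome analysis.

The experimental logic of the study: prepace the tissue over three sinus
beats from a prepaced single-cell state, apply the SAC pulse at a chosen
delay after the last sinus pacing, classify the outcome (nothing, ectopy
only, unsustained or sustained reentry), and sweep the SAC onset at 1 ms
resolution (or coarser) to map vulnerability windows.  A bracketing mode
expands from a known window in 1 ms steps and verifies 5 ms beyond each
edge, mirroring the search used when scanning many model variants.

Outcome classification operationalizes the visually-determined "global
reactivation" of the source protocol as a quantitative decision tree on
upstroke events (thresholds exposed in :class:`ClassifierConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell.protocols import CellParams, CellState, init_and_prepace
from .fibrosis import CleftSet, generate_clefts
from .geometry import PacingProtocol, TissueGeometry
from .heterogeneity import ConductivitySpec, HeterogeneityField
from .sac import SACParams, pulse_on_duration
from .solver import SimulationResult, SolverConfig, run_simulation

LABEL_NONE = "none"
LABEL_ECTOPY = "ectopy_only"
LABEL_REENTRY = "reentry_unsustained"
LABEL_SUSTAINED = "reentry_sustained"


class ProtocolError(RuntimeError):
    pass


class MeasurementError(RuntimeError):
    pass


def measure_cv(result: SimulationResult, geom: TissueGeometry,
               exclusion: float = 0.25) -> float:
    """Planar-wave CV (m/s) from rod activation times.

    Least-squares slope of activation time vs axial distance over the
    central ``1 - 2*exclusion`` span of the rod, inverted.  (mm/ms and
    m/s coincide numerically.)
    """
    x = geom.centroids[result.active, 0]
    t = result.activation_latest
    L = geom.dims_mm[0]
    sel = (x >= exclusion * L) & (x <= (1 - exclusion) * L) & np.isfinite(t)
    if sel.sum() < 3:
        raise MeasurementError("too few activated elements in the fit span")
    xs, ts = x[sel], t[sel]
    order = np.argsort(xs)
    if np.any(np.diff(ts[order]) < -1e-9):
        raise MeasurementError("non-monotone activation along the rod")
    slope = np.polyfit(xs, ts, 1)[0]  # ms/mm
    if slope <= 0:
        raise MeasurementError("non-positive activation slope")
    return float(1.0 / slope)


@dataclass
class TissueCheckpoint:
    """Solver state ready for the test beat, plus sinus references."""

    state: tuple  # (V, S, drive)
    activation_map: np.ndarray  # last prepace beat, ms from its stimulus
    sinus_span: float  # time to full activation of the last beat (ms)
    n_beats: int


def prepace_tissue(geom: TissueGeometry, spec: ConductivitySpec,
                   het: HeterogeneityField, clefts: CleftSet | None,
                   protocol: PacingProtocol, config: SolverConfig,
                   initial_cell: CellState,
                   n_beats: int | None = None) -> TissueCheckpoint:
    """Prepace the tissue for ``n_beats`` sinus beats (default 3).

    Returns the checkpoint immediately before the next (test) beat.
    Raises :class:`ProtocolError` if any root point fails to capture.
    """
    if n_beats is None:
        n_beats = protocol.n_prepace_beats
    if n_beats == 0:
        n = int(geom.inside.sum())
        V = np.full(n, initial_cell.vm)
        S = np.tile(initial_cell.state, (n, 1))
        from .sac import SACDrive
        return TissueCheckpoint((V, S, SACDrive()), np.full(n, np.nan),
                                0.0, 0)
    stim_times = protocol.bcl * np.arange(n_beats)
    cfg = replace(config, record_frames=False)
    res = run_simulation(geom, spec, het, clefts, protocol, None,
                         protocol.bcl * n_beats, cfg, initial_cell,
                         stim_times=stim_times)
    t_last = stim_times[-1]
    act = res.activation_latest - t_last
    pos = -np.ones(geom.n_elements, dtype=np.int64)
    pos[res.active] = np.arange(len(res.active))
    for rp in protocol.root_points:
        p = pos[rp.elements]
        p = p[p >= 0]
        if p.size and not np.any((act[p] >= 0) & (act[p] < 20.0)):
            raise ProtocolError(
                f"root point at {rp.center} failed to capture on the "
                f"last prepace beat")
    frac = np.mean(np.isfinite(act) & (act >= 0))
    if frac < 0.9:
        raise ProtocolError("sinus beat did not propagate through the tissue")
    span = float(np.nanmax(np.where(act >= 0, act, np.nan)))
    return TissueCheckpoint(res.final_state, act, span, n_beats)


@dataclass
class OutcomeLabel:
    label: str
    evidence: dict = field(default_factory=dict)

    @property
    def is_reentry(self) -> bool:
        return self.label in (LABEL_REENTRY, LABEL_SUSTAINED)


@dataclass
class ClassifierConfig:
    """Thresholds of the outcome decision tree.

    ``reactivation_fraction``: fraction of active elements that must be
    re-excited for a "global reactivation".  ``direct_margin``: events
    earlier than SAC switch-off + margin count as the direct
    SAC-triggered (ectopic) beat rather than reentry.  ``span_margin``:
    grace period after full sinus activation before events count as
    re-excitations.
    """

    reactivation_fraction: float = 0.75
    direct_margin: float = 25.0  # ms
    direct_vm_below: float = -55.0  # mV
    span_margin: float = 30.0  # ms
    sustained_after: float = 1000.0  # ms after last sinus activation


def classify_outcome(result: SimulationResult, geom: TissueGeometry,
                     protocol: PacingProtocol, sac: SACParams | None,
                     checkpoint: TissueCheckpoint,
                     cls: ClassifierConfig | None = None,
                     require_sustained_window: bool = True) -> OutcomeLabel:
    """Label one test-beat run (sinus stimulus at t=0, SAC at its onset).

    Decision tree: upstrokes after the sinus beat has completed are
    re-excitations.  A run with no re-excitation is ``none``.  If the SAC
    region was repolarized at pulse onset (mean Vm below
    ``direct_vm_below``) and re-excitations start inside the region
    within the pulse (plus a margin), they are the direct SAC-triggered
    ectopic beat; reentry then requires a *second* re-excitation of a
    global fraction of elements.  Without a direct trigger
    (early-repolarization mechanism: the pulse lands on depolarized
    tissue, which SAC cannot excite) a single global re-excitation wave
    is reentry.  Activity confined to the SAC region never counts.
    Reentry is sustained if any activity persists 1000 ms after the last
    sinus activation.
    """
    cls = cls or ClassifierConfig()
    if sac is None:
        return OutcomeLabel(LABEL_NONE, {"reason": "sac_disabled"})
    t_end = result.times[-1] if len(result.times) else 0.0
    sustain_t = checkpoint.sinus_span + cls.sustained_after
    if require_sustained_window and t_end < sustain_t:
        raise ValueError(
            f"result ends at {t_end:.0f} ms, before the sustained-reentry "
            f"horizon {sustain_t:.0f} ms")

    t_cut = max(checkpoint.sinus_span + cls.span_margin, sac.onset)
    sel = result.event_times > t_cut
    et = result.event_times[sel]
    ee = result.event_elems[sel]
    n_active = len(result.active)
    region_of = geom.sac_layer > 0
    if et.size == 0:
        return OutcomeLabel(LABEL_NONE, {"n_extra_events": 0})

    vm_on = np.nan
    for entry in result.event_log:
        if entry[0] == "sac_on":
            vm_on = entry[2]
    t_off = sac.onset + pulse_on_duration(sac)
    direct = et <= t_off + cls.direct_margin
    has_direct = bool(np.any(direct & region_of[ee])) and (
        np.isnan(vm_on) or vm_on < cls.direct_vm_below)
    escape = bool(np.any(~region_of[ee]))
    evidence = {
        "region_vm_at_onset": float(vm_on),
        "n_extra_events": int(et.size),
        "first_extra_t": float(et.min()),
        "escape": escape,
        "direct_trigger": has_direct,
        "last_activity_t": float(et.max()),
    }
    if not escape:
        evidence["reason"] = "confined_to_sac_region"
        return OutcomeLabel(LABEL_NONE, evidence)

    counts = np.zeros(n_active, dtype=np.int64)
    pos = -np.ones(geom.n_elements, dtype=np.int64)
    pos[result.active] = np.arange(n_active)
    np.add.at(counts, pos[ee], 1)
    need = 2 if has_direct else 1
    frac = float(np.mean(counts >= need))
    evidence["reactivated_fraction"] = frac
    if frac < cls.reactivation_fraction:
        label = LABEL_ECTOPY if has_direct else LABEL_NONE
        return OutcomeLabel(label, evidence)
    sustained = bool(np.any(et >= sustain_t))
    evidence["sustained"] = sustained
    return OutcomeLabel(LABEL_SUSTAINED if sustained else LABEL_REENTRY,
                        evidence)


@dataclass
class SweepResult:
    onsets: np.ndarray
    labels: list  # OutcomeLabel per onset
    windows: list  # [(onset_start, onset_end)] maximal reentry runs
    ectopy_onsets: np.ndarray
    errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_ms": self.onsets,
            "label": [l.label for l in self.labels],
        })


def windows_from_labels(onsets, labels) -> list:
    """Maximal runs of consecutive sampled onsets labelled reentry."""
    wins = []
    start = None
    for o, l in zip(onsets, labels):
        if l.is_reentry:
            if start is None:
                start = o
            last = o
        else:
            if start is not None:
                wins.append((start, last))
                start = None
    if start is not None:
        wins.append((start, last))
    return wins


def sweep_sac_onset(run_fn, onsets) -> SweepResult:
    """Exhaustive sweep: classify the outcome at every onset.

    ``run_fn(onset) -> OutcomeLabel`` encapsulates simulation +
    classification (typically from a shared prepaced checkpoint).
    Per-onset failures are recorded and the sweep continues.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    labels = []
    errors = {}
    for o in onsets:
        try:
            labels.append(run_fn(float(o)))
        except Exception as exc:  # noqa: BLE001 - record and continue
            errors[float(o)] = repr(exc)
            labels.append(OutcomeLabel(LABEL_NONE, {"error": repr(exc)}))
    wins = windows_from_labels(onsets, labels)
    ect = onsets[[l.label == LABEL_ECTOPY for l in labels]]
    return SweepResult(onsets, labels, wins, ect, errors)


def bracket_window(run_fn, seed_onset: float, lo: float = 1.0,
                   hi: float = 350.0, step: float = 1.0,
                   verify: float = 5.0):
    """Bracketing search: expand from ``seed_onset`` until both window
    edges are found, then verify ``verify`` ms beyond each edge.

    Returns ``(window, checked)`` where ``window`` is ``(start, end)`` or
    ``None`` and ``checked`` maps onset -> OutcomeLabel for every run
    performed.
    """
    checked = {}

    def probe(o):
        if o not in checked:
            checked[o] = run_fn(o)
        return checked[o].is_reentry

    if not probe(seed_onset):
        return None, checked
    start = seed_onset
    while start - step >= lo and probe(start - step):
        start -= step
    end = seed_onset
    while end + step <= hi and probe(end + step):
        end += step
    # +-verify ms check beyond each edge
    o = start - step
    while o >= max(lo, start - verify):
        if probe(o):
            start = o  # widen if the check finds more reentry
        o -= step
    o = end + step
    while o <= min(hi, end + verify):
        if probe(o):
            end = o
        o += step
    return (start, end), checked


def make_run_fn(geom, spec, het, clefts, protocol, sac_template,
                checkpoint, config, cls=None, post_window=1050.0,
                require_sustained_window=True):
    """Build the onset -> OutcomeLabel closure used by the sweeps."""

    def run_fn(onset: float) -> OutcomeLabel:
        sac = replace(sac_template, onset=float(onset))
        duration = checkpoint.sinus_span + post_window
        duration = max(duration,
                       onset + pulse_on_duration(sac) + 400.0)
        res = run_simulation(geom, spec, het, clefts, protocol, sac,
                             duration, config, checkpoint.state)
        return classify_outcome(
            res, geom, protocol, sac, checkpoint, cls,
            require_sustained_window=require_sustained_window)

    return run_fn


def tag_mechanism(region_vm_at_onset: float,
                  depol_below: float = -60.0,
                  early_repol_above: float = -20.0) -> str:
    """Mechanism dichotomy from the SAC-region state at pulse onset.

    A pulse landing on a repolarized region (mean Vm below ~-60 mV) acts
    by SAC-induced depolarization; one landing on the plateau (above
    ~-20 mV) acts by SAC-induced early repolarization.  The thresholds
    are conventions for the reduced geometry.
    """
    if region_vm_at_onset < depol_below:
        return "depolarization"
    if region_vm_at_onset > early_repol_above:
        return "early_repolarization"
    return "intermediate"


def run_study(config) -> pd.DataFrame:
    """Run the configured model grid; one row per (model, onset).

    ``config`` is a :class:`sacsim.config.StudyConfig`.  Returns a tidy
    table with outcome labels, windows and mechanism tags; per-model
    failures are collected in ``df.attrs['errors']``.
    """
    from .config import build_model

    rows = []
    errors = {}
    window_rows = []
    for model_cfg in config.models:
        try:
            bundle = build_model(model_cfg)
            ckpt = prepace_tissue(bundle.geom, bundle.spec, bundle.het,
                                  bundle.clefts, bundle.protocol,
                                  bundle.solver, bundle.initial_cell)
            run_fn = make_run_fn(
                bundle.geom, bundle.spec, bundle.het, bundle.clefts,
                bundle.protocol, bundle.sac, ckpt, bundle.solver,
                post_window=config.post_window_ms,
                require_sustained_window=config.assess_sustained)
            onsets = np.arange(config.onset_start, config.onset_stop + 1e-9,
                               config.onset_step)
            sweep = sweep_sac_onset(run_fn, onsets)
            errors.update({(model_cfg.name, o): e
                           for o, e in sweep.errors.items()})
            for o, l in zip(sweep.onsets, sweep.labels):
                # mechanism from the SAC-region state at pulse onset
                mech = None
                vm_on = l.evidence.get("region_vm_at_onset")
                if l.is_reentry and vm_on is not None:
                    mech = tag_mechanism(vm_on)
                rows.append({"model": model_cfg.name, "onset_ms": o,
                             "label": l.label, "mechanism": mech,
                             **{f"ev_{k}": v for k, v in l.evidence.items()}})
            for (a, b) in sweep.windows:
                window_rows.append({"model": model_cfg.name,
                                    "window_start": a, "window_end": b})
        except Exception as exc:  # noqa: BLE001
            errors[(model_cfg.name, None)] = repr(exc)
    df = pd.DataFrame(rows)
    df.attrs["errors"] = errors
    df.attrs["windows"] = pd.DataFrame(window_rows)
    return df
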