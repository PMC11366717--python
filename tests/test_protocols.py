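"""Outcome classification, sweeps, CV measurement, tissue prepacing."""

import numpy as np
import pytest

from sacsim.geometry import (PacingProtocol, RootPoint, make_geometry,
                             place_root_points, tag_sac_region)
from sacsim.heterogeneity import ConductivitySpec, HeterogeneityField
from sacsim.protocols import (LABEL_ECTOPY, LABEL_NONE, LABEL_REENTRY,
                              LABEL_SUSTAINED, ClassifierConfig,
                              MeasurementError, OutcomeLabel, ProtocolError,
                              TissueCheckpoint, bracket_window,
                              classify_outcome, measure_cv, prepace_tissue,
                              sweep_sac_onset, windows_from_labels)
from sacsim.sac import SACParams
from sacsim.solver import SimulationResult, SolverConfig, run_simulation

SPEC = ConductivitySpec(sigma_l=0.2, sigma_t=0.06)


@pytest.fixture()
def tagged_sheet():
    geom = make_geometry("sheet", [10.0, 10.0], 1000.0)
    tag_sac_region(geom, [5.0, 5.0, 0.0], 3.0, 1.0)
    return geom


def fake_result(geom, events, vm_at_onset=-80.0, t_end=1300.0):
    """SimulationResult stub from an (element, time) event list."""
    active = np.flatnonzero(geom.inside)
    ev = sorted(events, key=lambda p: p[1])
    elems = np.array([e for e, _ in ev], dtype=np.int64)
    times = np.array([t for _, t in ev])
    n = len(active)
    return SimulationResult(
        times=np.arange(1.0, t_end + 1.0), phi_e=np.zeros(int(t_end)),
        event_times=times, event_elems=elems,
        activation_latest=np.full(n, np.nan),
        frame_times=np.zeros(0), vm_frames=np.zeros((0, n)),
        active=active, event_log=[("sac_on", 0.0, vm_at_onset)],
        final_state=None, region_mean_vm=np.zeros(0))


def checkpoint(span=50.0):
    return TissueCheckpoint(None, np.zeros(0), span, 3)


class TestClassifyOutcome:
    protocol = PacingProtocol(root_points=[])

    def all_elements(self, geom):
        return np.flatnonzero(geom.inside)

    def test_sac_disabled_is_negative_control(self, tagged_sheet):
        res = fake_result(tagged_sheet, [])
        lab = classify_outcome(res, tagged_sheet, self.protocol, None,
                               checkpoint())
        assert lab.label == LABEL_NONE

    def test_no_extra_activity(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        res = fake_result(tagged_sheet, [])
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_NONE

    def test_confined_reactivation_is_not_reentry(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        region = np.flatnonzero(tagged_sheet.sac_layer > 0)
        res = fake_result(tagged_sheet, [(e, 310.0) for e in region])
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_NONE
        assert lab.evidence["reason"] == "confined_to_sac_region"

    def test_single_escaping_beat_is_ectopy(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        elems = self.all_elements(tagged_sheet)
        events = [(e, 310.0 + 0.05 * i) for i, e in enumerate(elems)]
        res = fake_result(tagged_sheet, events, vm_at_onset=-82.0)
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_ECTOPY

    def test_reactivation_after_ectopic_beat_is_reentry(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        elems = self.all_elements(tagged_sheet)
        events = [(e, 310.0) for e in elems] + [(e, 520.0) for e in elems]
        res = fake_result(tagged_sheet, events, vm_at_onset=-82.0)
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_REENTRY

    def test_activity_at_sinus_plus_1000_is_sustained(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        elems = self.all_elements(tagged_sheet)
        events = ([(e, 310.0) for e in elems]
                  + [(e, 520.0) for e in elems]
                  + [(int(elems[0]), 50.0 + 1000.0)])
        res = fake_result(tagged_sheet, events, vm_at_onset=-82.0)
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_SUSTAINED

    def test_plateau_onset_single_wave_is_reentry(self, tagged_sheet):
        """Early-repolarization mechanism: no direct trigger, one global
        re-excitation wave after the pulse."""
        sac = SACParams(e_sac=-70.0, onset=60.0)
        elems = self.all_elements(tagged_sheet)
        events = [(e, 230.0 + 0.1 * i) for i, e in enumerate(elems)]
        res = fake_result(tagged_sheet, events, vm_at_onset=10.0)
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint())
        assert lab.label == LABEL_REENTRY

    def test_truncated_result_rejected(self, tagged_sheet):
        sac = SACParams(e_sac=-10.0, onset=300.0)
        res = fake_result(tagged_sheet, [], t_end=500.0)
        with pytest.raises(ValueError, match="horizon"):
            classify_outcome(res, tagged_sheet, self.protocol, sac,
                             checkpoint())
        lab = classify_outcome(res, tagged_sheet, self.protocol, sac,
                               checkpoint(), require_sustained_window=False)
        assert lab.label == LABEL_NONE


class TestSweep:
    @staticmethod
    def fn_from(labels):
        def run_fn(onset):
            return OutcomeLabel(labels[int(onset)])
        return run_fn

    def test_windows_from_run_lengths(self):
        labels = {1: LABEL_NONE, 2: LABEL_NONE, 3: LABEL_REENTRY,
                  4: LABEL_REENTRY, 5: LABEL_REENTRY, 6: LABEL_NONE}
        res = sweep_sac_onset(self.fn_from(labels), range(1, 7))
        assert res.windows == [(3.0, 5.0)]
        assert res.ectopy_onsets.size == 0

    def test_bracketing_equivalent_to_exhaustive(self):
        labels = {o: LABEL_NONE for o in range(1, 21)}
        for o in (3, 4, 5):
            labels[o] = LABEL_REENTRY
        win, checked = bracket_window(self.fn_from(labels), 4, lo=1, hi=20)
        assert win == (3, 5)
        # the +-5 ms verification probed beyond both edges
        assert {2, 1} <= set(checked) and {6, 7, 8, 9, 10} <= set(checked)
        exhaustive = sweep_sac_onset(self.fn_from(labels), range(1, 21))
        assert exhaustive.windows == [(3.0, 5.0)]

    def test_all_none_sweep_is_empty(self):
        res = sweep_sac_onset(lambda o: OutcomeLabel(LABEL_NONE),
                              range(1, 11))
        assert res.windows == [] and res.ectopy_onsets.size == 0

    def test_failures_recorded_and_sweep_continues(self):
        def run_fn(onset):
            if onset == 3.0:
                raise RuntimeError("diverged")
            return OutcomeLabel(LABEL_NONE)
        res = sweep_sac_onset(run_fn, range(1, 6))
        assert 3.0 in res.errors
        assert len(res.labels) == 5

    def test_window_edge_cases(self):
        labels = [OutcomeLabel(LABEL_REENTRY), OutcomeLabel(LABEL_NONE),
                  OutcomeLabel(LABEL_SUSTAINED)]
        assert windows_from_labels([1, 2, 3], labels) == [(1, 1), (3, 3)]


class TestMeasureCV:
    def test_synthetic_activation_exact(self):
        geom = make_geometry("rod", [100.0], 530.0)
        active = np.flatnonzero(geom.inside)
        res = SimulationResult(
            times=np.zeros(0), phi_e=np.zeros(0), event_times=np.zeros(0),
            event_elems=np.zeros(0, dtype=np.int64),
            activation_latest=geom.centroids[active, 0] / 0.56,
            frame_times=np.zeros(0), vm_frames=np.zeros((0, len(active))),
            active=active, event_log=[], final_state=None,
            region_mean_vm=np.zeros(0))
        assert measure_cv(res, geom) == pytest.approx(0.56, rel=1e-12)

    def test_non_monotone_rejected(self):
        geom = make_geometry("rod", [100.0], 530.0)
        active = np.flatnonzero(geom.inside)
        act = geom.centroids[active, 0] / 0.56
        act[100] = act[90] - 5.0
        res = SimulationResult(
            times=np.zeros(0), phi_e=np.zeros(0), event_times=np.zeros(0),
            event_elems=np.zeros(0, dtype=np.int64),
            activation_latest=act, frame_times=np.zeros(0),
            vm_frames=np.zeros((0, len(active))), active=active,
            event_log=[], final_state=None, region_mean_vm=np.zeros(0))
        with pytest.raises(MeasurementError):
            measure_cv(res, geom)


class TestPrepaceTissue:
    def test_zero_beats_is_broadcast_identity(self, baseline_cell_state):
        geom = make_geometry("sheet", [6.0, 6.0], 1000.0)
        protocol = PacingProtocol(root_points=[])
        ckpt = prepace_tissue(geom, SPEC, HeterogeneityField.uniform(geom),
                              None, protocol, SolverConfig(),
                              baseline_cell_state, n_beats=0)
        V, S, drive = ckpt.state
        np.testing.assert_array_equal(V, baseline_cell_state.vm)
        np.testing.assert_array_equal(S,
                                      np.tile(baseline_cell_state.state,
                                              (geom.n_elements, 1)))
        assert drive.g_sac == 0.0

    def test_failed_capture_raises(self, baseline_cell_state):
        geom = make_geometry("sheet", [8.0, 6.0], 1000.0)
        protocol = place_root_points(geom, site_radius=2.0,
                                     stim_amplitude=0.0)
        with pytest.raises(ProtocolError):
            prepace_tissue(geom, SPEC, HeterogeneityField.uniform(geom),
                           None, protocol, SolverConfig(record_frames=False),
                           baseline_cell_state, n_beats=1)


def test_checkpoint_reuse_equals_full_history(baseline_cell_state):
    """Running the test beat + SAC from a prepaced checkpoint is
    bit-identical to simulating the whole history in one go."""
    geom = make_geometry("sheet", [12.0, 8.0], 1000.0)
    tag_sac_region(geom, [6.0, 4.0, 0.0], 3.0, 1.0)
    protocol = place_root_points(geom, site_radius=2.0, bcl=400.0,
                                 n_prepace_beats=2)
    het = HeterogeneityField.uniform(geom)
    cfg = SolverConfig(record_frames=False)
    sac = SACParams(e_sac=-10.0, onset=100.0)

    ckpt = prepace_tissue(geom, SPEC, het, None, protocol, cfg,
                          baseline_cell_state)
    from dataclasses import replace

    r_ck = run_simulation(geom, SPEC, het, None, protocol,
                          sac, 300.0, cfg, ckpt.state)

    full_sac = replace(sac, onset=800.0 + 100.0)
    r_full = run_simulation(geom, SPEC, het, None, protocol, full_sac,
                            800.0 + 300.0, cfg, baseline_cell_state,
                            stim_times=np.array([0.0, 400.0, 800.0]))
    np.testing.assert_array_equal(r_ck.final_state[0],
                                  r_full.final_state[0])
    np.testing.assert_array_equal(r_ck.final_state[1],
                                  r_full.final_state[1])
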