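"""Monodomain solver: conservation, propagation, phi_e recovery."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from sacsim.fibrosis import CleftSet, region_faces
from sacsim.geometry import (PacingProtocol, RootPoint, make_geometry,
                             place_root_points, tag_sac_region)
from sacsim.heterogeneity import ConductivitySpec, HeterogeneityField
from sacsim.solver import (ConfigurationError, SolverConfig,
                           assemble_diffusion, default_electrode,
                           lead_field, recover_phi_e, run_simulation)

SPEC = ConductivitySpec(sigma_l=0.2, sigma_t=0.06)


def small_sheet(nx=10, ny=10, spacing=1000.0):
    return make_geometry("sheet", [float(nx), float(ny)], spacing)


def edge_protocol(geom, amp=100.0):
    stim = np.flatnonzero(geom.centroids[:, 0] <= 1.0)
    return PacingProtocol(root_points=[RootPoint(np.zeros(3), 1.0, 0.0,
                                                 stim)],
                          stim_amplitude=amp)


def test_solver_config_requires_commensurate_steps():
    with pytest.raises(ConfigurationError):
        SolverConfig(dt_reaction=0.03, dt_diffusion=0.1)


def test_explicit_cfl_guard(baseline_cell_state):
    geom = small_sheet()
    cfg = SolverConfig(implicit=False, dt_diffusion=10.0, dt_reaction=0.1)
    with pytest.raises(ConfigurationError):
        run_simulation(geom, SPEC, HeterogeneityField.uniform(geom), None,
                       edge_protocol(geom), None, 1.0, cfg,
                       baseline_cell_state)


@pytest.mark.parametrize("implicit", [True, False])
def test_diffusion_conserves_mean_on_insulated_domain(implicit, rng):
    """No-flux boundaries: the diffusion substep preserves the spatial
    mean of Vm to near machine precision."""
    geom = small_sheet()
    active = np.flatnonzero(geom.inside)
    L = assemble_diffusion(geom, SPEC, None, active)
    V = rng.uniform(-85.0, 20.0, len(active))
    mean0 = V.mean()
    dt = 0.01 if not implicit else 0.1
    if implicit:
        lu = splu(sp.identity(len(active), format="csc") - dt * L.tocsc())
        for _ in range(50):
            V = lu.solve(V)
    else:
        for _ in range(50):
            V = V + dt * (L @ V)
    assert abs(V.mean() - mean0) / abs(mean0) <= 1e-10


def test_quiescent_tissue_stays_at_rest(baseline_cell_state):
    geom = small_sheet(6, 6)
    protocol = PacingProtocol(root_points=[])
    cfg = SolverConfig(record_frames=False)
    res = run_simulation(geom, SPEC, HeterogeneityField.uniform(geom), None,
                         protocol, None, 200.0, cfg, baseline_cell_state,
                         stim_times=np.array([]))
    v_end = res.final_state[0]
    assert np.max(np.abs(v_end - baseline_cell_state.vm)) < 0.5
    assert len(res.event_times) == 0


def test_rod_activation_monotone_with_distance(baseline_cell_state):
    geom = make_geometry("rod", [20.0], 1000.0)
    stim = np.flatnonzero(geom.centroids[:, 0] <= 1.0)
    protocol = PacingProtocol(root_points=[RootPoint(np.zeros(3), 1.0, 0.0,
                                                     stim)])
    cfg = SolverConfig(record_frames=False)
    res = run_simulation(geom, SPEC, HeterogeneityField.uniform(geom), None,
                         protocol, None, 80.0, cfg, baseline_cell_state)
    act = res.activation_latest
    assert np.all(np.isfinite(act))
    assert np.all(np.diff(act[3:]) > 0)


def test_halving_dt_changes_vm_below_half_mv(baseline_cell_state):
    geom = small_sheet(8, 8)
    protocol = edge_protocol(geom)
    het = HeterogeneityField.uniform(geom)
    fields = []
    for dt_r, dt_d in [(0.02, 0.1), (0.01, 0.05)]:
        cfg = SolverConfig(dt_reaction=dt_r, dt_diffusion=dt_d,
                           record_frames=False)
        res = run_simulation(geom, SPEC, het, None, protocol, None, 100.0,
                             cfg, baseline_cell_state)
        fields.append(res.final_state[0])
    assert np.max(np.abs(fields[0] - fields[1])) < 0.5


def test_fully_clefted_region_interior_is_isolated(baseline_cell_state):
    """With every intra-region face split, interior region elements are
    removed and never activated by external pacing."""
    geom = small_sheet(12, 12)
    tag_sac_region(geom, [6.0, 6.0, 0.0], 3.0, 1.0)
    elem_a, axis, elem_b = region_faces(geom)
    faces = np.stack([elem_a, axis], axis=1).astype(np.int64)
    cleft = CleftSet(faces, np.ones(len(faces)), seed=0)
    from sacsim.fibrosis import find_isolated

    cleft.removed = find_isolated(geom, cleft)
    interior = np.flatnonzero(geom.sac_layer >= 2)
    assert np.all(np.isin(interior, cleft.removed))
    protocol = edge_protocol(geom)
    cfg = SolverConfig(record_frames=False)
    res = run_simulation(geom, SPEC, HeterogeneityField.uniform(geom),
                         cleft, protocol, None, 120.0, cfg,
                         baseline_cell_state)
    assert not np.any(np.isin(res.event_elems, interior))
    # everything still present activated
    assert np.isfinite(res.activation_latest).all()


def test_empty_cleftset_reproduces_nonfibrotic_solution(
        baseline_cell_state):
    geom = small_sheet(8, 6)
    tag_sac_region(geom, [4.0, 3.0, 0.0], 2.0, 1.0)
    protocol = edge_protocol(geom)
    cfg = SolverConfig(record_frames=False)
    args = (geom, SPEC, HeterogeneityField.uniform(geom))
    r1 = run_simulation(*args, None, protocol, None, 60.0, cfg,
                        baseline_cell_state)
    r2 = run_simulation(*args, CleftSet.empty(), protocol, None, 60.0, cfg,
                        baseline_cell_state)
    np.testing.assert_array_equal(r1.final_state[0], r2.final_state[0])


def test_endocardial_fast_layer_speeds_activation(baseline_cell_state):
    geom = make_geometry("slab", [20.0, 8.0, 5.0], 1000.0)
    # 2 mm sites: reliable capture at this coarse desk-scale resolution
    protocol = place_root_points(geom, site_radius=2.0)
    het = HeterogeneityField.uniform(geom)
    cfg = SolverConfig(record_frames=False)
    spec_fast = ConductivitySpec(sigma_l=0.2, sigma_t=0.06, endo_sigma=2.0)
    done = {}
    for name, spec in [("plain", SPEC), ("fast", spec_fast)]:
        res = run_simulation(geom, spec, het, None, protocol, None, 200.0,
                             cfg, baseline_cell_state)
        act = res.activation_latest
        assert np.isfinite(act).all()
        done[name] = act.max()
        # activation proceeds endo -> epi
        endo = geom.endo_mask[res.active]
        assert act[endo].mean() < act[~endo].mean()
    assert done["fast"] < done["plain"]


class TestPhiE:
    def test_uniform_field_gives_zero(self):
        geom = small_sheet()
        active = np.flatnonzero(geom.inside)
        frames = np.full((3, len(active)), -20.0)
        phi = recover_phi_e(frames, geom, SPEC, active,
                            default_electrode(geom))
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_dipole_source_falls_off_as_inverse_square(self):
        """A planar Vm front (the discrete dipole layer: net current
        dipole sum sigma grad V dV != 0) recovers the closed-form
        point-dipole 1/r^2 falloff at electrode distances much larger
        than the tissue."""
        geom = make_geometry("slab", [20.0, 20.0, 20.0], 1000.0)
        active = np.flatnonzero(geom.inside)
        x = geom.centroids[active, 0]
        V = np.where(x < 10.0, 1.0, -1.0)
        center = 0.5 * geom.dims_mm
        phis = []
        dists = [200.0, 400.0, 800.0]
        for d in dists:
            e = center + np.array([d, 0, 0])
            phis.append(recover_phi_e(V[None, :], geom, SPEC, active, e)[0])
        for i in (0, 1):
            ratio = phis[i] / phis[i + 1]
            assert ratio == pytest.approx(
                (dists[i + 1] / dists[i]) ** 2, rel=0.05)

    def test_mirror_symmetric_halves_contribute_equally(self):
        geom = make_geometry("slab", [20.0, 20.0, 8.0], 1000.0)
        active = np.flatnonzero(geom.inside)
        x = geom.centroids[active, 0]
        electrode = 0.5 * geom.dims_mm + np.array([0, 0, 150.0])
        w = lead_field(geom, SPEC, active, electrode, SolverConfig())
        # activation pattern mirror-symmetric about the electrode axis
        V = np.where(np.abs(x - 10.0) < 4.0, 10.0, -80.0)
        left = (x < 10.0)
        phi_left = np.dot(w[left], V[left])
        phi_right = np.dot(w[~left], V[~left])
        assert phi_left == pytest.approx(phi_right, abs=1e-12)

    def test_electrode_inside_tissue_rejected(self):
        geom = small_sheet()
        active = np.flatnonzero(geom.inside)
        with pytest.raises(ConfigurationError):
            lead_field(geom, SPEC, active, [5.0, 5.0, 0.5], SolverConfig())


def test_identical_inputs_give_identical_outputs(baseline_cell_state):
    geom = small_sheet(8, 6)
    protocol = edge_protocol(geom)
    cfg = SolverConfig(record_frames=False)
    runs = [run_simulation(geom, SPEC, HeterogeneityField.uniform(geom),
                           None, protocol, None, 50.0, cfg,
                           baseline_cell_state) for _ in range(2)]
    np.testing.assert_array_equal(runs[0].final_state[0],
                                  runs[1].final_state[0])
    np.testing.assert_array_equal(runs[0].phi_e, runs[1].phi_e)
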