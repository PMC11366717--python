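"""APD-gradient heterogeneity and conduction-velocity calibration.

Two ingredients of tissue heterogeneity live here:

* the IKs scaling field producing linear APD gradients along the
  apicobasal and transmural coordinates (factor 1-2 in each direction by
  default, multiplying to 1 at the basal endocardium and 4 at the apical
  epicardium, i.e. APDs from 290 down to 206 ms at BCL 500 ms);
* monodomain conductivities calibrated on a 10 cm rod at 530 um
  resolution so the planar-wave conduction velocity hits its clinical
  targets (0.56 m/s along fibers, 0.21 m/s across; 2 m/s isotropic in the
  fast endocardial layer), plus fibrotic CV slowing (20/40/60 %), global
  or confined to the SAC region, re-calibrated through the same rod map
  rather than scaled naively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import TissueGeometry, make_geometry


@dataclass
class HeterogeneityField:
    """Per-element multiplicative IKs scaling factors."""

    iks_scale: np.ndarray

    @classmethod
    def uniform(cls, geom: TissueGeometry, value: float = 1.0):
        return cls(np.full(geom.n_elements, float(value)))


def build_iks_field(geom: TissueGeometry, ab_range=(1.0, 2.0),
                    tm_range=(1.0, 2.0)) -> HeterogeneityField:
    """IKs scaling as a product of two linear ramps.

    The apicobasal factor runs from ``ab_range[0]`` at the base to
    ``ab_range[1]`` at the apex; the transmural factor from
    ``tm_range[0]`` at the endocardium to ``tm_range[1]`` at the
    epicardium.  Element value is the product (1 basal-endo ... 4
    apical-epi for the default ranges).
    """
    for lo, hi in (ab_range, tm_range):
        if lo < 1.0 or hi < lo:
            raise ValueError("scaling ranges must satisfy 1 <= lo <= hi")
    ab_lo, ab_hi = ab_range
    tm_lo, tm_hi = tm_range
    f_ab = ab_lo + (ab_hi - ab_lo) * (1.0 - geom.apicobasal)
    f_tm = tm_lo + (tm_hi - tm_lo) * geom.transmural
    return HeterogeneityField(f_ab * f_tm)


@dataclass
class ConductivitySpec:
    """Effective monodomain conductivities (S/m) and membrane constants.

    ``region_scale_l/t`` apply to the scope in ``region_scope``
    ("global" or "sac_region") and represent fibrotic CV slowing.
    """

    sigma_l: float
    sigma_t: float
    chi: float = 1400.0  # 1/cm
    cm: float = 1.0  # uF/cm^2
    endo_sigma: float | None = None  # isotropic fast-layer conductivity
    region_scope: str | None = None
    region_scale_l: float = 1.0
    region_scale_t: float = 1.0

    def __post_init__(self):
        if self.sigma_l <= 0 or self.sigma_t <= 0:
            raise ValueError("conductivities must be positive")
        if self.sigma_l < self.sigma_t:
            raise ValueError("sigma_l must be >= sigma_t")

    def diffusivity(self, sigma: float) -> float:
        """Convert sigma (S/m) to a diffusivity in mm^2/ms."""
        return sigma / (self.chi * self.cm) * 1000.0


#: clinical CV targets (m/s)
CV_LONGITUDINAL = 0.56
CV_TRANSVERSE = 0.21
CV_ENDO_LAYER = 2.0

#: rod used for every calibration: 10 cm at 530 um
ROD_LENGTH_MM = 100.0
ROD_SPACING_UM = 530.0


class CalibrationError(RuntimeError):
    pass


def _prepaced_cell(variant: str, iks_scale: float, bcl: float):
    """Cached 50-beat prepaced cell state (copied on use)."""
    from .cell.protocols import CellParams, init_and_prepace

    key = (variant, iks_scale, bcl)
    if key not in _PREPACE_CACHE:
        _PREPACE_CACHE[key] = init_and_prepace(
            CellParams(variant=variant, iks_scale=iks_scale), bcl, 50)
    return _PREPACE_CACHE[key].copy()


_PREPACE_CACHE: dict = {}


def measure_rod_cv(sigma: float, direction: str = "longitudinal",
                   rod_length_mm: float = ROD_LENGTH_MM,
                   spacing_um: float = ROD_SPACING_UM,
                   chi: float = 1400.0, cm: float = 1.0,
                   cell_params=None, exclusion: float = 0.25,
                   bcl: float = 500.0, cv_guess: float = 0.4) -> float:
    """Planar-wave CV (m/s) on a paced rod for a trial conductivity.

    The rod is paced at one end from the prepaced limit cycle; the CV is
    the inverse slope of activation time vs distance over the central
    ``1 - 2*exclusion`` span.
    """
    from .cell.protocols import CellParams, init_and_prepace
    from .solver import SolverConfig, run_simulation
    from .protocols import measure_cv
    from .geometry import PacingProtocol, RootPoint

    fiber_direction = "axial" if direction == "longitudinal" else "transverse"
    geom = make_geometry("rod", [rod_length_mm], spacing_um,
                         fiber_direction=fiber_direction)
    spec = ConductivitySpec(sigma_l=sigma, sigma_t=sigma, chi=chi, cm=cm)
    if cell_params is None:
        cell_params = CellParams()
    init = _prepaced_cell(cell_params.variant, cell_params.iks_scale, bcl)
    stim_elems = np.flatnonzero(geom.centroids[:, 0] <= 1.0)
    protocol = PacingProtocol(
        bcl=bcl, n_prepace_beats=0,
        root_points=[RootPoint(np.zeros(3), 1.0, 0.0, stim_elems)])
    het = HeterogeneityField.uniform(geom, cell_params.iks_scale)
    # generous margin on the expected crossing time of the planar wave
    duration = rod_length_mm / (0.5 * cv_guess) + 30.0
    config = SolverConfig(record_frames=False)
    res = run_simulation(geom, spec, het, None, protocol, None, duration,
                         config, init)
    return measure_cv(res, geom, exclusion=exclusion)


def _calibrate_sigma(target_cv: float, direction: str, rel_tol: float,
                     **rod_kw) -> float:
    """Root-find sigma for a CV target using the sqrt(sigma) scaling.

    An initial measurement fixes the CV-to-sigma map through the
    cable-theory proportionality CV ~ sqrt(sigma); bisection on the
    bracketed residual then polishes to ``rel_tol``.
    """
    from .protocols import MeasurementError

    def residual(sigma):
        # a wave too slow to cross the rod (or blocked) reads as CV ~ 0
        try:
            return measure_rod_cv(sigma, direction, **rod_kw) - target_cv
        except MeasurementError:
            return -target_cv

    sigma0 = 0.2
    cv0 = measure_rod_cv(sigma0, direction, **rod_kw)
    rod_kw = dict(rod_kw, cv_guess=target_cv)
    sigma = sigma0 * (target_cv / cv0) ** 2
    lo, hi = sigma / 1.6, sigma * 1.6
    f_lo = residual(lo)
    f_hi = residual(hi)
    tries = 0
    while f_lo > 0 or f_hi < 0:
        if f_lo > 0:
            lo /= 2.0
            f_lo = residual(lo)
        if f_hi < 0:
            hi *= 2.0
            f_hi = residual(hi)
        tries += 1
        if tries > 6:
            raise CalibrationError(
                f"bracket exhaustion for CV {target_cv}: last bracket "
                f"[{lo:.4g}, {hi:.4g}] S/m")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if abs(f_mid) < rel_tol * target_cv:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not converge for CV {target_cv}: "
        f"bracket [{lo:.4g}, {hi:.4g}] S/m")


def calibrate_conductivity(target_cv_l: float = CV_LONGITUDINAL,
                           target_cv_t: float = CV_TRANSVERSE,
                           endo_cv: float | None = CV_ENDO_LAYER,
                           rel_tol: float = 0.005,
                           **rod_kw) -> ConductivitySpec:
    """Calibrate sigma_l, sigma_t (and the endocardial-layer sigma).

    Each conductivity is tuned on the standard rod until the measured CV
    is within ``rel_tol`` (default 0.5 %, inside the 1 % acceptance band)
    of its target.
    """
    sigma_l = _calibrate_sigma(target_cv_l, "longitudinal", rel_tol, **rod_kw)
    sigma_t = _calibrate_sigma(target_cv_t, "transverse", rel_tol, **rod_kw)
    endo_sigma = None
    if endo_cv is not None:
        endo_sigma = _calibrate_sigma(endo_cv, "longitudinal", rel_tol,
                                      **rod_kw)
    return ConductivitySpec(sigma_l=sigma_l, sigma_t=sigma_t,
                            endo_sigma=endo_sigma,
                            chi=rod_kw.get("chi", 1400.0),
                            cm=rod_kw.get("cm", 1.0))


def apply_cv_slowing(spec: ConductivitySpec, fraction: float,
                     scope: str = "global",
                     baseline_cv_l: float = CV_LONGITUDINAL,
                     baseline_cv_t: float = CV_TRANSVERSE,
                     rel_tol: float = 0.01, **rod_kw) -> ConductivitySpec:
    """Fibrotic CV slowing by ``fraction`` in ``scope``.

    The slowed conductivities are re-calibrated on the rod against the
    reduced CV targets (CV does not scale linearly with sigma), and the
    resulting sigma ratios are stored as region scaling factors.
    """
    if fraction == 0:
        return spec
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if scope not in ("global", "sac_region"):
        raise ValueError("scope must be 'global' or 'sac_region'")
    sl = _calibrate_sigma((1 - fraction) * baseline_cv_l, "longitudinal",
                          rel_tol, **rod_kw)
    st = _calibrate_sigma((1 - fraction) * baseline_cv_t, "transverse",
                          rel_tol, **rod_kw)
    return replace(spec, region_scope=scope,
                   region_scale_l=sl / spec.sigma_l,
                   region_scale_t=st / spec.sigma_t)
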