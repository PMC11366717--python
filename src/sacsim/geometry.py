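"""Synthetic tissue geometries: rod, sheet and 3D wall slab.

These stand in for a patient ventricular mesh while preserving the
structure the reentry mechanisms depend on: an apicobasal and a
transmural normalized coordinate, rotating fiber orientations, a
fast-conducting endocardial layer, four endocardial pacing root points,
and a layered spherical SAC (stretch) region.

Axis convention (element-centered, positions in mm, 0-based indices):

* x -- apicobasal axis: apex at x=0 (apicobasal=0), base at x=L
  (apicobasal=1);
* y -- lateral axis (transmural axis for the 2D sheet);
* z -- transmural axis for the slab: endocardium at z=0 (transmural=0),
  epicardium at z=T (transmural=1).

Fibers rotate linearly from +60 deg at the endocardium to -60 deg at the
epicardium, in the x-y plane, about the transmural axis; the sheet-normal
vector is the in-plane unit vector perpendicular to the fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded


class GeometryError(ValueError):
    """Inconsistent geometry configuration."""


@dataclass
class RootPoint:
    center: np.ndarray  # mm
    radius: float  # mm
    delay: float  # ms
    elements: np.ndarray  # flat indices of stimulated elements


@dataclass
class PacingProtocol:
    """Sinus pacing: four endocardial root points, RV point 5 ms late."""

    bcl: float = 500.0
    n_prepace_beats: int = 3
    root_points: list[RootPoint] = field(default_factory=list)
    stim_amplitude: float = 100.0  # uA/uF
    stim_duration: float = 1.0  # ms

    def __post_init__(self):
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")


@dataclass
class TissueGeometry:
    kind: str
    shape: tuple[int, int, int]
    spacing: float  # mm
    inside: np.ndarray  # bool, flat (n,)
    apicobasal: np.ndarray  # flat (n,)
    transmural: np.ndarray
    fibers: np.ndarray  # (n, 3) unit vectors
    sheet_normal: np.ndarray  # (n, 3) unit vectors
    sac_layer: np.ndarray  # int, 0 outside; 1..K outer->inner shells
    endo_mask: np.ndarray  # bool
    centroids: np.ndarray  # (n, 3) mm
    sac_center: np.ndarray | None = None
    sac_radius: float = 0.0
    shell_width: float = 0.0
    endo_layer_mm: float = 1.0

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    @property
    def dims_mm(self) -> np.ndarray:
        return self.spacing * np.asarray(self.shape)

    def flat_index(self, ix, iy=0, iz=0) -> int:
        return int(np.ravel_multi_index((ix, iy, iz), self.shape))


def _transmural_laplace(n: int) -> np.ndarray:
    """Normalized 1D Laplace solution across ``n`` element layers.

    Dirichlet values 0 / 1 on the endo / epi faces, element-centered
    unknowns (half-cell boundary spacing), min-max normalized so the
    coordinate spans [0, 1] over element centers; on a flat wall this is
    the linear depth fraction, recovered here to solver precision.
    """
    if n == 1:
        return np.array([0.5])
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0
    ab[2, :-1] = 1.0
    ab[1, :] = -2.0
    ab[1, 0] = ab[1, -1] = -3.0
    rhs = np.zeros(n)
    rhs[-1] = -2.0
    u = solve_banded((1, 1), ab, rhs)
    return (u - u[0]) / (u[-1] - u[0])


def make_geometry(kind: str, dimensions, spacing: float,
                  fiber_rotation: bool = True,
                  fiber_angle_range: tuple[float, float] = (60.0, -60.0),
                  fiber_direction: str = "axial",
                  endo_layer_mm: float = 1.0) -> TissueGeometry:
    """Build a rod, sheet or slab geometry.

    Parameters
    ----------
    kind : {"rod", "sheet", "slab"}
    dimensions : sequence of mm extents (1, 2 or 3 values).
    spacing : element edge length in micrometers.
    fiber_rotation : rotate fibers across the transmural coordinate
        (sheet/slab); when off, fibers align with +x everywhere.
    fiber_angle_range : endo and epi fiber angles in degrees.
    fiber_direction : rod only; "axial" or "transverse" fibers.
    """
    dims = np.atleast_1d(np.asarray(dimensions, dtype=float))
    h = spacing / 1000.0  # mm
    expected = {"rod": 1, "sheet": 2, "slab": 3}
    if kind not in expected:
        raise GeometryError(f"unknown geometry kind {kind!r}")
    if dims.size != expected[kind]:
        raise GeometryError(
            f"{kind} needs {expected[kind]} dimension(s), got {dims.size}")
    if np.any(dims < 2 * h):
        raise GeometryError("each dimension must be at least 2*spacing")

    counts = [int(np.ceil(d * 1000.0 / spacing)) for d in dims]
    shape = tuple(counts + [1] * (3 - len(counts)))
    nx, ny, nz = shape
    n = nx * ny * nz

    ix, iy, iz = np.unravel_index(np.arange(n), shape)
    centroids = h * (np.stack([ix, iy, iz], axis=1) + 0.5)

    apicobasal = _span01(ix, nx)
    if kind == "rod":
        transmural = np.zeros(n)
    elif kind == "sheet":
        transmural = _transmural_laplace(ny)[iy]
    else:
        transmural = _transmural_laplace(nz)[iz]

    fibers = np.zeros((n, 3))
    sheet_normal = np.zeros((n, 3))
    if kind == "rod":
        if fiber_direction == "axial":
            fibers[:, 0] = 1.0
            sheet_normal[:, 1] = 1.0
        elif fiber_direction == "transverse":
            fibers[:, 1] = 1.0
            sheet_normal[:, 0] = 1.0
        else:
            raise GeometryError("fiber_direction must be axial|transverse")
    else:
        if fiber_rotation:
            a_endo, a_epi = fiber_angle_range
            ang = np.deg2rad(a_endo + (a_epi - a_endo) * transmural)
        else:
            ang = np.zeros(n)
        fibers[:, 0] = np.cos(ang)
        fibers[:, 1] = np.sin(ang)
        # in-plane perpendicular: fiber x z_hat
        sheet_normal[:, 0] = np.sin(ang)
        sheet_normal[:, 1] = -np.cos(ang)

    if kind == "sheet":
        endo_mask = centroids[:, 1] < endo_layer_mm
    elif kind == "slab":
        endo_mask = centroids[:, 2] < endo_layer_mm
    else:
        endo_mask = np.zeros(n, dtype=bool)

    return TissueGeometry(
        kind=kind, shape=shape, spacing=h,
        inside=np.ones(n, dtype=bool),
        apicobasal=apicobasal, transmural=transmural,
        fibers=fibers, sheet_normal=sheet_normal,
        sac_layer=np.zeros(n, dtype=np.int64),
        endo_mask=endo_mask, centroids=centroids,
        endo_layer_mm=endo_layer_mm,
    )


def _span01(idx, n):
    if n == 1:
        return np.zeros(len(idx), dtype=float)
    return idx / (n - 1.0)


def tag_sac_region(geom: TissueGeometry, center, radius: float,
                   shell_width: float = 1.0) -> TissueGeometry:
    """Tag elements of the layered spherical SAC region (in place).

    Shell ``k`` collects centroids with ``radius - k*w <= d < radius -
    (k-1)*w`` (half-open bins); the innermost shell has the highest index.
    """
    center = np.asarray(center, dtype=float)
    if radius < shell_width:
        raise GeometryError("radius must be at least shell_width")
    if np.any(center < 0) or np.any(center[: len(geom.dims_mm)] >
                                    geom.dims_mm):
        raise GeometryError("SAC center outside the domain")
    d = np.linalg.norm(geom.centroids - center, axis=1)
    layer = np.zeros(geom.n_elements, dtype=np.int64)
    tagged = d < radius
    layer[tagged] = np.ceil((radius - d[tagged]) / shell_width).astype(int)
    layer[tagged] = np.maximum(layer[tagged], 1)
    geom.sac_layer = layer
    geom.sac_center = center
    geom.sac_radius = float(radius)
    geom.shell_width = float(shell_width)
    if not np.any(tagged & geom.inside):
        warnings.warn("SAC sphere does not overlap the domain",
                      RuntimeWarning)
    return geom


def default_sac_center(geom: TissueGeometry, transmural_frac: float = 0.5,
                       lateral_frac: float = 0.5) -> np.ndarray:
    """SAC center 1/3 of the apicobasal distance from the apex, mid-wall."""
    L = geom.dims_mm
    c = np.array([L[0] / 3.0, 0.0, 0.0])
    if geom.kind == "sheet":
        c[1] = transmural_frac * L[1]
    elif geom.kind == "slab":
        c[1] = lateral_frac * L[1]
        c[2] = transmural_frac * L[2]
    return c


#: (apicobasal fraction, lateral fraction, delay ms) of the default
#: four-root-point layout: three LV/septal sites fire together, the
#: RV-like site 5 ms later.
DEFAULT_ROOT_LAYOUT = (
    (0.25, 0.30, 0.0),
    (0.55, 0.70, 0.0),
    (0.80, 0.35, 0.0),
    (0.45, 0.90, 5.0),
)


def place_root_points(geom: TissueGeometry, layout=DEFAULT_ROOT_LAYOUT,
                      site_radius: float = 1.0, bcl: float = 500.0,
                      n_prepace_beats: int = 3,
                      stim_amplitude: float = 100.0,
                      stim_duration: float = 1.0) -> PacingProtocol:
    """Place spherical stimulus sites on the endocardial face."""
    if geom.kind not in ("sheet", "slab"):
        raise GeometryError("root points need a sheet or slab geometry")
    L = geom.dims_mm
    points = []
    for f_ab, f_lat, delay in layout:
        if geom.kind == "sheet":
            center = np.array([f_ab * L[0], 0.0, 0.0])
        else:
            center = np.array([f_ab * L[0], f_lat * L[1], 0.0])
        d = np.linalg.norm(geom.centroids - center, axis=1)
        elems = np.flatnonzero((d <= site_radius) & geom.inside)
        if elems.size == 0:
            raise GeometryError(
                f"root point at {center} captures no elements")
        points.append(RootPoint(center, site_radius, float(delay), elems))
    return PacingProtocol(bcl=bcl, n_prepace_beats=n_prepace_beats,
                          root_points=points,
                          stim_amplitude=stim_amplitude,
                          stim_duration=stim_duration)
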