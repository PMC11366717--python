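"""Fibrotic microstructure: insulating clefts inside the SAC region.

Fibrosis is modeled as electrically insulating clefts between adjacent
elements.  On the structured grid a "cleft" zeroes the conducting face
between two neighbors, which in the finite-volume flux formulation is
equivalent to duplicating (splitting) the shared facet of an unstructured
mesh.  Each interior face between two SAC-region elements is split with
independent probability

    p = a * |cos(theta)|,

where ``theta`` is the angle between the face normal and the local
fiber-sheet-normal direction, and the density parameter ``a`` rises
linearly from 0.1 in the outermost SAC shell to 1.0 in the innermost
shell (using the shell index of the deeper adjacent element).  Elements
left with no conducting face are removed from the active tissue, like
fully isolated elements cut from a split mesh.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TissueGeometry

A_OUTER = 0.1
A_INNER = 1.0

_AXES = np.eye(3)


@dataclass
class CleftSet:
    """Sampled set of non-conducting inter-element faces.

    A face is keyed by ``(element, axis)``: the face between ``element``
    and its +axis neighbor on the grid.
    """

    faces: np.ndarray  # (m, 2) int: flat element index, axis
    a_field: np.ndarray  # (m,) density parameter of each split face
    seed: int
    removed: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64))
    params: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, seed: int = 0):
        return cls(np.zeros((0, 2), dtype=np.int64), np.zeros(0), seed)

    def __len__(self):
        return len(self.faces)

    def to_csv(self, path):
        df = pd.DataFrame({"element": self.faces[:, 0],
                           "axis": self.faces[:, 1], "a": self.a_field})
        with open(path, "w") as f:
            f.write(f"# seed={self.seed} params={self.params!r}\n")
            df.to_csv(f, sep="\t", index=False)
            f.write("# removed: " + ",".join(map(str, self.removed)) + "\n")


def region_faces(geom: TissueGeometry):
    """Interior faces of the SAC region: (element, axis, neighbor) triples."""
    shape = geom.shape
    layer = geom.sac_layer.reshape(shape)
    inside = geom.inside.reshape(shape)
    out = []
    for axis in range(3):
        if shape[axis] == 1:
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ok = (layer[tuple(sl_a)] > 0) & (layer[tuple(sl_b)] > 0) \
            & inside[tuple(sl_a)] & inside[tuple(sl_b)]
        idx = np.argwhere(ok)
        flat_a = np.ravel_multi_index(idx.T, shape)
        nb = idx.copy()
        nb[:, axis] += 1
        flat_b = np.ravel_multi_index(nb.T, shape)
        out.append((flat_a, np.full(len(flat_a), axis), flat_b))
    if not out:
        return (np.zeros(0, dtype=np.int64),) * 3
    return tuple(np.concatenate(parts) for parts in zip(*out))


def cleft_probability(geom: TissueGeometry, elem_a, axis, elem_b):
    """Per-face split probability ``a * |cos theta|`` and its ``a``."""
    n_shells = int(geom.sac_layer.max())
    k_deep = np.maximum(geom.sac_layer[elem_a], geom.sac_layer[elem_b])
    if n_shells > 1:
        a = A_OUTER + (A_INNER - A_OUTER) * (k_deep - 1) / (n_shells - 1)
    else:
        a = np.full(len(elem_a), A_INNER)
    s = 0.5 * (geom.sheet_normal[elem_a] + geom.sheet_normal[elem_b])
    norms = np.linalg.norm(s, axis=1)
    norms[norms == 0] = 1.0
    s = s / norms[:, None]
    cos_theta = np.abs(np.take_along_axis(s, axis[:, None], axis=1)[:, 0])
    return a * cos_theta, a


def generate_clefts(geom: TissueGeometry, seed: int) -> CleftSet:
    """Sample the cleft set; reproducible from (geometry, seed)."""
    if not np.any(geom.sac_layer > 0):
        raise ValueError("geometry has no SAC-region tags")
    elem_a, axis, elem_b = region_faces(geom)
    p, a = cleft_probability(geom, elem_a, axis, elem_b)
    rng = np.random.default_rng(seed)
    split = rng.random(len(p)) < p
    faces = np.stack([elem_a[split], axis[split]], axis=1).astype(np.int64)
    cleft = CleftSet(faces, a[split], seed,
                     params={"a_outer": A_OUTER, "a_inner": A_INNER,
                             "radius": geom.sac_radius})
    cleft.removed = find_isolated(geom, cleft)
    return cleft


def face_keys(elem, axis):
    """Stable integer key of the face between ``elem`` and its +axis
    neighbor (axis < 4)."""
    return np.asarray(elem, dtype=np.int64) * 4 + np.asarray(axis)


def find_isolated(geom: TissueGeometry, cleft: CleftSet) -> np.ndarray:
    """Elements whose every face is split or a domain boundary."""
    shape = geom.shape
    inside = geom.inside.reshape(shape)
    split = face_keys(cleft.faces[:, 0], cleft.faces[:, 1])
    conducting = np.zeros(geom.n_elements, dtype=np.int64)
    for axis in range(3):
        if shape[axis] == 1:
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ok = inside[tuple(sl_a)] & inside[tuple(sl_b)]
        idx = np.argwhere(ok)
        flat_a = np.ravel_multi_index(idx.T, shape)
        nb = idx.copy()
        nb[:, axis] += 1
        flat_b = np.ravel_multi_index(nb.T, shape)
        open_face = ~np.isin(face_keys(flat_a, axis), split)
        np.add.at(conducting, flat_a[open_face], 1)
        np.add.at(conducting, flat_b[open_face], 1)
    isolated = np.flatnonzero((conducting == 0) & geom.inside)
    return isolated
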