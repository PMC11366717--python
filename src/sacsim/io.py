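"""Artifact output: legacy-VTK fields, delimited traces, run manifests."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd


def export_vtk(path, geom, cell_fields=None, vector_fields=None):
    """Write the geometry and per-element fields as legacy VTK
    STRUCTURED_POINTS (ASCII), one value per element (cell data)."""
    nx, ny, nz = geom.shape
    h = geom.spacing
    cell_fields = cell_fields or {}
    vector_fields = vector_fields or {}
    n = geom.n_elements
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("sacsim tissue geometry\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"CELL_DATA {n}\n")
        for name, arr in cell_fields.items():
            arr = np.asarray(arr).reshape(geom.shape)
            # VTK cell ordering: x fastest
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            f.write(" ".join(f"{v:g}" for v in flat) + "\n")
        for name, arr in vector_fields.items():
            arr = np.asarray(arr).reshape(geom.shape + (3,))
            flat = np.transpose(arr, (2, 1, 0, 3)).reshape(-1, 3)
            f.write(f"VECTORS {name} float\n")
            for v in flat:
                f.write(f"{v[0]:g} {v[1]:g} {v[2]:g}\n")


def geometry_fields(geom):
    """Standard field dictionary for :func:`export_vtk`."""
    return {
        "sac_layer": geom.sac_layer.astype(float),
        "transmural": geom.transmural,
        "apicobasal": geom.apicobasal,
        "endo_mask": geom.endo_mask.astype(float),
        "inside": geom.inside.astype(float),
    }


def full_field(geom, active, values, fill=np.nan):
    """Scatter per-active-element values onto the full grid."""
    out = np.full(geom.n_elements, fill)
    out[active] = values
    return out


def export_trace(path, times, values, names=("t_ms", "value")):
    pd.DataFrame({names[0]: times, names[1]: values}).to_csv(
        path, sep="\t", index=False)


def write_manifest(path, cfg_hash: str, seed: int, extra=None):
    from . import __version__

    manifest = {"config_hash": cfg_hash, "seed": seed,
                "version": __version__,
                "created": time.strftime("%Y-%m-%dT%H:%M:%S")}
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def save_checkpoint(path, V, S, drive):
    np.savez(path, V=V, S=S, g_sac=drive.g_sac, g_target=drive.g_target,
             phase=drive.phase)


def load_checkpoint(path):
    from .sac import SACDrive

    z = np.load(path, allow_pickle=False)
    return z["V"], z["S"], SACDrive(float(z["g_sac"]), float(z["g_target"]),
                                    str(z["phase"]))
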