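"""Chunked-array (HDF5) containers for grids, fields and deformations.

Each container stores the arrays plus enough metadata (grid edges, spacing,
origin, frequency) to reconstruct the object stand-alone.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .dielectrics import MaterialGrid, RectilinearGrid
from .fdtd import FieldVolume
from .registration import FFDGrid

__all__ = [
    "save_material_grid", "load_material_grid",
    "save_field_volume", "load_field_volume",
    "save_ffd", "load_ffd",
    "save_registration_result", "load_registration_result",
]


def _write_edges(group, grid: RectilinearGrid) -> None:
    for name, e in zip("xyz", grid.edges):
        group.create_dataset(f"edges_{name}", data=e)


def _read_edges(group) -> RectilinearGrid:
    return RectilinearGrid(tuple(np.asarray(group[f"edges_{a}"]) for a in "xyz"))


def save_material_grid(mat: MaterialGrid, path: str) -> None:
    with h5py.File(path, "w") as fh:
        _write_edges(fh, mat.grid)
        for name in ("sigma", "eps_r", "rho", "implant", "tissue"):
            fh.create_dataset(name, data=getattr(mat, name),
                              compression="gzip", compression_opts=1)
        if mat.labels is not None:
            fh.create_dataset("labels", data=mat.labels,
                              compression="gzip", compression_opts=1)


def load_material_grid(path: str) -> MaterialGrid:
    with h5py.File(path, "r") as fh:
        grid = _read_edges(fh)
        kw = {name: np.asarray(fh[name])
              for name in ("sigma", "eps_r", "rho", "implant", "tissue")}
        labels = np.asarray(fh["labels"]) if "labels" in fh else None
    return MaterialGrid(grid, kw["sigma"], kw["eps_r"], kw["rho"],
                        kw["implant"].astype(np.int8),
                        kw["tissue"].astype(bool), labels=labels)


def save_field_volume(field: FieldVolume, path: str) -> None:
    with h5py.File(path, "w") as fh:
        _write_edges(fh, field.grid)
        for name in ("Ex", "Ey", "Ez"):
            fh.create_dataset(name, data=getattr(field, name),
                              compression="gzip", compression_opts=1)
        fh.attrs["frequency"] = field.frequency
        fh.attrs["scale"] = field.scale


def load_field_volume(path: str) -> FieldVolume:
    with h5py.File(path, "r") as fh:
        grid = _read_edges(fh)
        comps = [np.asarray(fh[n]) for n in ("Ex", "Ey", "Ez")]
        freq = float(fh.attrs["frequency"])
        scale = float(fh.attrs.get("scale", 1.0))
    return FieldVolume(grid, *comps, frequency=freq, scale=scale)


def save_ffd(grid: FFDGrid, path: str, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("disp", data=grid.disp, compression="gzip",
                          compression_opts=1)
        fh.attrs["origin"] = grid.origin
        fh.attrs["spacing"] = grid.spacing
        if meta:
            fh.attrs["meta"] = json.dumps(meta)


def load_ffd(path: str) -> FFDGrid:
    with h5py.File(path, "r") as fh:
        return FFDGrid(np.asarray(fh.attrs["origin"]), float(fh.attrs["spacing"]),
                       np.asarray(fh["disp"]))


def save_registration_result(result, path: str) -> None:
    """One HDF5 file: per-level control grids plus JSON metadata."""
    with h5py.File(path, "w") as fh:
        fh.attrs["meta"] = json.dumps({
            "schedule_mm": result.schedule_mm,
            "rmse_mm": result.rmse_mm,
            "iterations": result.iterations,
            "initial_rmse_mm": result.initial_rmse_mm,
            "n_points": result.n_points,
            "similarity": {
                "rotation": result.similarity.rotation.tolist(),
                "scale": result.similarity.scale,
                "translation": result.similarity.translation.tolist(),
            },
        })
        for i, g in enumerate(result.levels):
            grp = fh.create_group(f"level_{i}")
            grp.create_dataset("disp", data=g.disp, compression="gzip",
                               compression_opts=1)
            grp.attrs["origin"] = g.origin
            grp.attrs["spacing"] = g.spacing


def load_registration_result(path: str):
    from .registration import RegistrationResult, SimilarityTransform

    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        levels = []
        for i in range(len(meta["schedule_mm"])):
            grp = fh[f"level_{i}"]
            levels.append(FFDGrid(np.asarray(grp.attrs["origin"]),
                                  float(grp.attrs["spacing"]),
                                  np.asarray(grp["disp"])))
    s = meta["similarity"]
    return RegistrationResult(
        similarity=SimilarityTransform(np.asarray(s["rotation"]), s["scale"],
                                       np.asarray(s["translation"])),
        levels=levels,
        schedule_mm=meta["schedule_mm"],
        rmse_mm=meta["rmse_mm"],
        iterations=meta["iterations"],
        initial_rmse_mm=meta["initial_rmse_mm"],
        n_points=meta["n_points"],
    )
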