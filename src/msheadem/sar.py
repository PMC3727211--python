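"""SAR maps (raw, 1 g, 10 g, whole-head), normalisation and model comparison.

Conventions
-----------
* E-field phasors are *peak* amplitudes, so the time-averaged absorbed power
  density is ``p = sigma |E|^2 / 2`` and the raw (unaveraged) SAR per cell is
  ``SAR = sigma |E|^2 / (2 rho)`` (W/kg).
* SAR is not computed in the space occupied by the implant or in air: those
  cells are masked to zero and excluded from averaging masses.
* Mass-averaged SAR follows the IEEE/IEC-style cube-growing rule: for every
  tissue cell, a cube centred on the cell grows through a deterministic
  geometric ladder of half-widths until the enclosed tissue mass reaches the
  target (1 g or 10 g); the averaged SAR is enclosed absorbed power divided
  by enclosed mass.  Cells whose cube leaves the domain before reaching the
  target mass are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dielectrics import MaterialGrid
from .fdtd import FieldVolume

__all__ = [
    "SARMap",
    "ProfileReport",
    "local_sar",
    "averaged_sar",
    "whole_head_sar",
    "normalize_to_reference",
    "line_profile",
    "count_extrema",
    "compare_models",
]


@dataclass
class SARMap:
    """Raw and optional mass-averaged SAR on one grid (W/kg)."""

    grid_shape: tuple
    raw: np.ndarray
    materials: MaterialGrid
    avg_1g: np.ndarray | None = None
    avg_10g: np.ndarray | None = None
    valid_1g: np.ndarray | None = None
    valid_10g: np.ndarray | None = None

    def _peak(self, arr: np.ndarray, valid: np.ndarray | None):
        mask = self.materials.tissue.copy()
        if valid is not None:
            mask &= valid
        if not mask.any():
            raise ValueError("no valid tissue cells")
        vals = np.where(mask, arr, -np.inf)
        idx = np.unravel_index(np.argmax(vals), arr.shape)
        cx, cy, cz = self.materials.grid.cell_centers()
        loc = np.array([cx[idx[0]], cy[idx[1]], cz[idx[2]]])
        return float(arr[idx]), loc

    @property
    def peak_raw(self) -> float:
        return self._peak(self.raw, None)[0]

    @property
    def peak_raw_location(self) -> np.ndarray:
        return self._peak(self.raw, None)[1]

    @property
    def peak_1g(self) -> float:
        return self._peak(self.avg_1g, self.valid_1g)[0]

    @property
    def peak_10g(self) -> float:
        return self._peak(self.avg_10g, self.valid_10g)[0]

    def whole_volume_sar(self) -> float:
        return whole_head_sar(self, self.materials)


@dataclass
class ProfileReport:
    """|E| samples along a named line plus extrema counts."""

    name: str
    points: np.ndarray
    values: np.ndarray
    n_zero_minima: int
    n_maxima: int


def local_sar(fieldvol: FieldVolume, materials: MaterialGrid) -> SARMap:
    """Raw per-cell SAR = sigma |E|^2 / (2 rho); air/implant masked to zero."""
    if fieldvol.Ex.shape != materials.grid.shape:
        raise ValueError("field and material grids do not match")
    if np.any(materials.rho <= 0):
        raise ValueError("non-positive density in the material grid")
    e2 = (np.abs(fieldvol.Ex) ** 2 + np.abs(fieldvol.Ey) ** 2
          + np.abs(fieldvol.Ez) ** 2).astype(np.float64)
    sar = materials.sigma.astype(np.float64) * e2 / (2.0 * materials.rho)
    sar[~materials.tissue] = 0.0
    return SARMap(materials.grid.shape, sar, materials)


def _integral3(a: np.ndarray) -> np.ndarray:
    """3-D summed-area table with a zero border."""
    s = np.zeros(tuple(n + 1 for n in a.shape))
    s[1:, 1:, 1:] = a.cumsum(0).cumsum(1).cumsum(2)
    return s


def _box_sum(s: np.ndarray, i0, i1, j0, j1, k0, k1):
    """Sum over index box [i0, i1) x [j0, j1) x [k0, k1) from a summed table."""
    return (s[i1, j1, k1] - s[i0, j1, k1] - s[i1, j0, k1] - s[i1, j1, k0]
            + s[i0, j0, k1] + s[i0, j1, k0] + s[i1, j0, k0] - s[i0, j0, k0])


def averaged_sar(raw: SARMap, materials: MaterialGrid, target_mass_g: float,
                 ladder_factor: float = 1.07) -> tuple[np.ndarray, np.ndarray]:
    """Cube-averaged SAR for every tissue cell.

    Returns ``(avg, valid)``: the averaged map (W/kg, zero outside tissue) and
    a validity mask (False where the cube could not reach the target mass
    inside the domain).  The cube half-width ladder starts at half the
    smallest cell and multiplies by ``ladder_factor``; a cell's cube is the
    first ladder entry whose enclosed tissue mass reaches the target.
    """
    grid = materials.grid
    mass = materials.cell_mass_kg()
    power = raw.raw * mass  # W per cell
    target_kg = target_mass_g * 1e-3
    if mass.sum() < target_kg:
        raise ValueError(
            f"domain holds {mass.sum() * 1e3:.2f} g of tissue; cannot average over "
            f"{target_mass_g} g")
    smass = _integral3(mass)
    spow = _integral3(power)

    centers = grid.cell_centers()
    edges = grid.edges
    lo, hi = grid.bounds
    shape = grid.shape

    tissue_idx = np.argwhere(materials.tissue)
    pos = np.stack([centers[a][tissue_idx[:, a]] for a in range(3)], axis=1)
    n = len(tissue_idx)
    h = np.full(n, 0.5 * float(grid.min_cell_sizes().min()))
    avg_val = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    valid = np.ones(n, dtype=bool)
    max_h = float(np.max(hi - lo))

    active = np.arange(n)
    while len(active):
        ha = h[active]
        pa = pos[active]
        idx0, idx1 = [], []
        for a in range(3):
            # cells whose centres fall inside the physical cube
            i0 = np.searchsorted(centers[a], pa[:, a] - ha, side="left")
            i1 = np.searchsorted(centers[a], pa[:, a] + ha, side="right")
            idx0.append(i0)
            idx1.append(i1)
        m = _box_sum(smass, idx0[0], idx1[0], idx0[1], idx1[1], idx0[2], idx1[2])
        reached = m >= target_kg
        if reached.any():
            sel = active[reached]
            p = _box_sum(spow, idx0[0][reached], idx1[0][reached],
                         idx0[1][reached], idx1[1][reached],
                         idx0[2][reached], idx1[2][reached])
            avg_val[sel] = p / m[reached]
            done[sel] = True
        # cubes that already span the whole domain but lack mass are invalid
        oob = (~reached) & (ha >= max_h)
        if oob.any():
            sel = active[oob]
            valid[sel] = False
            done[sel] = True
        h[active[~reached & ~oob]] *= ladder_factor
        active = active[~reached & ~oob]

    avg = np.zeros(shape)
    vmask = np.zeros(shape, dtype=bool)
    avg[tuple(tissue_idx.T)] = avg_val
    vmask[tuple(tissue_idx.T)] = valid
    return avg, vmask


def add_averaged(raw: SARMap, materials: MaterialGrid,
                 masses_g=(1.0, 10.0)) -> SARMap:
    """Attach 1 g / 10 g cube-averaged maps to a raw SAR map."""
    for g in masses_g:
        avg, valid = averaged_sar(raw, materials, g)
        if g == 1.0:
            raw.avg_1g, raw.valid_1g = avg, valid
        elif g == 10.0:
            raw.avg_10g, raw.valid_10g = avg, valid
    return raw


def whole_head_sar(raw: SARMap, materials: MaterialGrid) -> float:
    """Whole-volume SAR: total absorbed power over total tissue mass (W/kg)."""
    mass = materials.cell_mass_kg()
    total_mass = mass.sum()
    if total_mass <= 0:
        raise ValueError("no tissue mass in the domain")
    return float((raw.raw * mass).sum() / total_mass)


def normalize_to_reference(fields: list[FieldVolume], reference_sar_w: float,
                           target_w_kg: float = 3.2):
    """Scale field sets so the no-implant whole-head SAR equals the target.

    SAR scales with |E|^2, so a single field scale factor
    ``sqrt(target / reference)`` is applied to every supplied field volume.
    Returns ``(scaled_fields, scale_factor)``.
    """
    if reference_sar_w <= 0:
        raise ValueError("reference whole-head SAR must be positive")
    scale = float(np.sqrt(target_w_kg / reference_sar_w))
    return [f.scaled(scale) for f in fields], scale


def line_profile(fieldvol: FieldVolume, start_mm, end_mm, step_mm: float = 0.1,
                 name: str = "profile") -> tuple[np.ndarray, np.ndarray]:
    """Trilinear |E| samples along a straight line (start and end inclusive)."""
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    length = np.linalg.norm(end - start)
    n = max(int(np.ceil(length / step_mm)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    pts = start + t[:, None] * (end - start)
    interp = fieldvol.interpolator()
    try:
        vals = interp(pts)
    except ValueError as exc:
        raise ValueError(f"profile line leaves the grid: {exc}") from exc
    return pts, np.asarray(vals)


def count_extrema(samples: np.ndarray, zero_tol: float) -> tuple[int, int]:
    """Count near-zero local minima and local maxima of a 1-D profile.

    Runs of equal values are compressed first, so a flat zero plateau (e.g.
    the interior of an electrode contact) counts as a single minimum.  Strict
    local minima with value <= ``zero_tol`` are counted as zero-minima;
    maxima are all strict local maxima including plateau ends.
    """
    v = np.asarray(samples, dtype=float)
    if len(v) < 3:
        return 0, 0
    keep = np.concatenate([[True], np.diff(v) != 0.0])
    w = v[keep]
    if len(w) < 3:
        return 0, 0
    interior = w[1:-1]
    left, right = w[:-2], w[2:]
    is_min = (interior < left) & (interior < right)
    is_max = (interior > left) & (interior > right)
    n_min = int((is_min & (interior <= zero_tol)).sum())
    n_max = int(is_max.sum())
    # endpoints that strictly dominate their neighbour count as maxima
    if w[0] > w[1]:
        n_max += 1
    if w[-1] > w[-2]:
        n_max += 1
    return n_min, n_max


def compare_models(a: FieldVolume, b: FieldVolume, probes: np.ndarray):
    """Peak-location shift and per-probe |E| differences between two models.

    The |E| argmax of each model is located on its own grid and the shift is
    the Euclidean distance between the two world-space peak locations (mm);
    probe differences are ``|E|_a - |E|_b`` at matched world points.
    """

    def peak_loc(f: FieldVolume):
        mag = f.e_mag()
        idx = np.unravel_index(np.argmax(mag), mag.shape)
        cx, cy, cz = f.grid.cell_centers()
        return np.array([cx[idx[0]], cy[idx[1]], cz[idx[2]]]), float(mag[idx])

    loc_a, peak_a = peak_loc(a)
    loc_b, peak_b = peak_loc(b)
    shift = float(np.linalg.norm(loc_a - loc_b))
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    try:
        da = a.interpolator()(probes)
        db = b.interpolator()(probes)
    except ValueError as exc:
        raise ValueError(f"probe outside a model grid: {exc}") from exc
    diff = np.asarray(da) - np.asarray(db)
    return {
        "peak_shift_mm": shift,
        "peak_a": peak_a,
        "peak_b": peak_b,
        "peak_a_location_mm": loc_a,
        "peak_b_location_mm": loc_b,
        "probe_diff_mean": float(diff.mean()),
        "probe_diff_sd": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        "probe_diff": diff,
    }
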