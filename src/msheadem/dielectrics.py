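"""Tissue dielectric tables, the multiscale rectilinear grid and material
assignment.

Electrical properties are the 128 MHz literature values used throughout:
grey matter sigma = 0.58 S/m, eps_r = 73.51; white matter 0.34 S/m, 52.53;
the platinum/iridium conductor 4e6 S/m and the urethane insulation
1e-10 S/m, eps_r = 3.  Basal-ganglia nuclei take grey-matter properties and
the medullary laminae white-matter properties.  Tissue mass densities are not
part of that table and are bundled as editable defaults (brain 1040, skin
1100, bone 1900, CSF 1010 kg/m^3, otherwise 1000).

The multiscale simulation grid is a graded rectilinear (nonuniform) Yee mesh:
uniform fine cells across a region of interest, geometrically graded up to
uniform coarse cells elsewhere, with a bounded adjacent-cell ratio and a
single global timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import LabelVolume
from .geometry import IMPLANT_CONDUCTOR, IMPLANT_INSULATION

__all__ = [
    "TissueProperties",
    "RectilinearGrid",
    "MaterialGrid",
    "DEFAULT_TISSUE_TABLE",
    "LABEL_TISSUE_MAP",
    "material_for",
    "load_tissue_table",
    "save_tissue_table",
    "build_multiscale_grid",
    "uniform_grid",
    "sample_labels",
    "assign_materials",
]

PEC_SIGMA = 1.0e5  # cells at or above this conductivity are treated as PEC


@dataclass(frozen=True)
class TissueProperties:
    """Electrical conductivity (S/m), relative permittivity, density (kg/m^3)."""

    sigma: float
    eps_r: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.eps_r < 1:
            raise ValueError("eps_r must be >= 1")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")


DEFAULT_TISSUE_TABLE: dict[str, TissueProperties] = {
    "air": TissueProperties(0.0, 1.0, 1.2),
    "grey_matter": TissueProperties(0.58, 73.51, 1040.0),
    "white_matter": TissueProperties(0.34, 52.53, 1040.0),
    # shell tissues: 128 MHz literature values; densities are bundled defaults
    "skin": TissueProperties(0.52, 65.4, 1100.0),
    "bone": TissueProperties(0.067, 14.7, 1900.0),
    "csf": TissueProperties(2.14, 84.0, 1010.0),
    # implant materials
    "conductor": TissueProperties(4.0e6, 1.0, 21450.0),
    "insulation": TissueProperties(1.0e-10, 3.0, 1100.0),
}

# structure/label name -> tissue entry; nuclei map to grey matter, laminae to
# white matter.
LABEL_TISSUE_MAP: dict[str, str] = {
    "background": "air",
    "air": "air",
    "skin": "skin",
    "skull": "bone",
    "bone": "bone",
    "csf": "csf",
    "white_matter": "white_matter",
    "grey_matter": "grey_matter",
    "caudate": "grey_matter",
    "putamen": "grey_matter",
    "gpe": "grey_matter",
    "gpi": "grey_matter",
    "GPe": "grey_matter",
    "GPi": "grey_matter",
    "eml": "white_matter",
    "iml": "white_matter",
    "EML": "white_matter",
    "IML": "white_matter",
    "conductor": "conductor",
    "insulation": "insulation",
}


def material_for(label: str, table: dict[str, TissueProperties] | None = None) -> TissueProperties:
    """Electrical properties for a structure name (nuclei resolve to grey
    matter, laminae to white matter)."""
    table = table if table is not None else DEFAULT_TISSUE_TABLE
    key = LABEL_TISSUE_MAP.get(label, LABEL_TISSUE_MAP.get(label.lower(), label))
    if key not in table:
        known = sorted(set(table) | set(LABEL_TISSUE_MAP))
        raise KeyError(f"unknown tissue/structure '{label}'; known names: {known}")
    return table[key]


def scale_table_to_frequency(
    frequency_hz: float,
    table: dict[str, TissueProperties] | None = None,
    reference_hz: float = 128e6,
) -> dict[str, TissueProperties]:
    """Loss-tangent-preserving frequency scaling of the tissue table.

    A geometrically reduced phantom driven at a proportionally higher
    frequency reproduces the electromagnetic behaviour of the full-scale
    problem only if the loss tangent ``sigma / (omega eps0 eps_r)`` is kept:
    tissue conductivities are therefore multiplied by
    ``frequency / reference``.  Implant materials (the metallic conductor and
    the insulation) are left untouched — the conductor is effectively a
    perfect conductor at any RF frequency and the insulation loss is
    negligible either way.
    """
    table = table if table is not None else DEFAULT_TISSUE_TABLE
    ratio = float(frequency_hz) / float(reference_hz)
    out = {}
    for name, p in table.items():
        if name in ("conductor", "insulation") or p.sigma >= PEC_SIGMA:
            out[name] = p
        else:
            out[name] = TissueProperties(p.sigma * ratio, p.eps_r, p.rho)
    return out


def load_tissue_table(path: str) -> dict[str, TissueProperties]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: TissueProperties(**v) for k, v in raw.items()}


def save_tissue_table(table: dict[str, TissueProperties], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: vars(v) for k, v in table.items()}, fh)


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass
class RectilinearGrid:
    """Rectilinear cell grid defined by per-axis strictly increasing edges (mm)."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    fine_box: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("grid edges must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_sizes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.diff(e) for e in self.edges)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([e[0] for e in self.edges]),
                np.array([e[-1] for e in self.edges]))

    def cell_volumes(self) -> np.ndarray:
        dx, dy, dz = self.cell_sizes()
        return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]

    def max_adjacent_ratio(self) -> float:
        r = 1.0
        for d in self.cell_sizes():
            if len(d) > 1:
                rr = np.maximum(d[1:] / d[:-1], d[:-1] / d[1:])
                r = max(r, float(rr.max()))
        return r

    @property
    def total_volume(self) -> float:
        return float(np.prod([e[-1] - e[0] for e in self.edges]))

    def min_cell_sizes(self) -> np.ndarray:
        return np.array([d.min() for d in self.cell_sizes()])


def _axis_segment(length: float, fine: float, coarse: float, ratio: float) -> np.ndarray:
    """Cell sizes filling ``length`` from the fine region out to the boundary:
    geometric growth from ``fine`` to ``coarse`` then uniform coarse cells,
    slightly rescaled so the segment closes exactly."""
    if length <= 1e-12:
        return np.empty(0)
    growth = min(ratio, 1.4)
    trans = []
    s = fine * growth
    while s < coarse * 0.999:
        trans.append(s)
        s *= growth
    trans = np.asarray(trans)
    rem = length - trans.sum()
    if rem <= 0:
        # short segment: geometric cells only, rescaled to fit
        k = 1
        while k <= len(trans) and trans[:k].sum() < length:
            k += 1
        sizes = trans[:k].copy()
        sizes *= length / sizes.sum()
        return sizes
    n_coarse = max(int(round(rem / coarse)), 1)
    coarse_sizes = np.full(n_coarse, rem / n_coarse)
    sizes = np.concatenate([trans, coarse_sizes])
    return sizes


def _build_axis(lo: float, hi: float, rlo: float | None, rhi: float | None,
                fine: float, coarse: float, ratio: float) -> np.ndarray:
    if rlo is None:  # uniform coarse axis
        n = max(int(round((hi - lo) / coarse)), 1)
        return np.linspace(lo, hi, n + 1)
    nf = max(int(round((rhi - rlo) / fine)), 1)
    rhi = rlo + nf * fine  # snap the fine block to whole fine cells
    below = _axis_segment(rlo - lo, fine, coarse, ratio)[::-1]
    above = _axis_segment(hi - rhi, fine, coarse, ratio)
    sizes = np.concatenate([below, np.full(nf, fine), above])
    edges = lo + np.concatenate([[0.0], np.cumsum(sizes)])
    edges[-1] = hi
    return edges


def build_multiscale_grid(
    head_extent, roi=None, fine_mm: float = 0.2, coarse_mm: float = 1.0,
    grading_ratio: float = 1.5,
) -> RectilinearGrid:
    """Build the two-resolution simulation grid.

    Parameters
    ----------
    head_extent : (lo, hi) pair of 3-vectors
        Overall domain box in mm (including any absorbing-boundary margin).
    roi : (lo, hi) pair or None
        Region of interest meshed at ``fine_mm``; ``None`` or a degenerate box
        yields a uniform coarse grid.  The fine block is snapped to whole fine
        cells and transitions geometrically to ``coarse_mm`` with adjacent
        cell ratios bounded by ``grading_ratio``.
    """
    lo, hi = (np.asarray(v, dtype=float) for v in head_extent)
    if roi is not None:
        rlo, rhi = (np.asarray(v, dtype=float) for v in roi)
        if np.any(rhi <= rlo):
            roi = None
        elif np.any(rlo < lo) or np.any(rhi > hi):
            raise ValueError("roi must lie inside the head extent")
    edges = []
    for a in range(3):
        if roi is None:
            edges.append(_build_axis(lo[a], hi[a], None, None, fine_mm, coarse_mm,
                                     grading_ratio))
        else:
            edges.append(_build_axis(lo[a], hi[a], rlo[a], rhi[a], fine_mm, coarse_mm,
                                     grading_ratio))
    grid = RectilinearGrid(tuple(edges),
                           fine_box=None if roi is None else (rlo, rhi))
    return grid


def uniform_grid(head_extent, spacing_mm: float) -> RectilinearGrid:
    """Uniform grid over a box (the single-resolution model)."""
    return build_multiscale_grid(head_extent, roi=None, coarse_mm=spacing_mm)


# ---------------------------------------------------------------------------
# Material assignment
# ---------------------------------------------------------------------------

@dataclass
class MaterialGrid:
    """Per-cell electrical properties plus implant/tissue flags on a grid."""

    grid: RectilinearGrid
    sigma: np.ndarray
    eps_r: np.ndarray
    rho: np.ndarray
    implant: np.ndarray  # int8: 0 none / 1 conductor / 2 insulation
    tissue: np.ndarray   # bool: biological tissue (not air, not implant)
    labels: np.ndarray | None = None

    @property
    def pec(self) -> np.ndarray:
        return self.sigma >= PEC_SIGMA

    def cell_mass_kg(self) -> np.ndarray:
        """Tissue mass per cell (kg); zero for air and implant cells."""
        vol_m3 = self.grid.cell_volumes() * 1e-9
        m = self.rho * vol_m3
        m[~self.tissue] = 0.0
        return m


def sample_labels(grid: RectilinearGrid, volumes: list[LabelVolume]) -> np.ndarray:
    """Nearest-neighbour labels at every cell centre.

    ``volumes`` are tried in priority order (finest first); the first volume
    containing a cell centre supplies its label, cells outside all volumes are
    background (0).
    """
    cx, cy, cz = grid.cell_centers()
    pts = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1).reshape(-1, 3)
    out = np.full(len(pts), -1, dtype=np.int16)
    for vol in volumes:
        todo = out < 0
        if not todo.any():
            break
        got = vol.sample_nn(pts[todo], fill=-1)
        tmp = out[todo]
        tmp[got >= 0] = got[got >= 0]
        out[todo] = tmp
    out[out < 0] = 0
    return out.reshape(grid.shape)


def assign_materials(
    labels: np.ndarray | LabelVolume,
    implant_overlay: np.ndarray | None,
    table: dict[str, TissueProperties] | None = None,
    label_names: dict[int, str] | None = None,
    grid: RectilinearGrid | None = None,
) -> MaterialGrid:
    """Map labels (plus an implant overlay) to per-cell electrical properties.

    The implant overlay overrides the tissue underneath it; tissue/air/implant
    flags partition the cells.
    """
    from .phantoms import LABEL_NAMES

    if isinstance(labels, LabelVolume):
        if grid is None:
            lo, hi = labels.bounds
            grid = RectilinearGrid(tuple(
                labels.origin[a] + np.arange(labels.shape[a] + 1) * labels.spacing[a]
                for a in range(3)))
        labels = labels.labels
    if grid is None:
        raise ValueError("grid must be supplied when labels is a bare array")
    labels = np.asarray(labels)
    if labels.shape != grid.shape:
        raise ValueError(f"labels shape {labels.shape} does not match grid {grid.shape}")
    if implant_overlay is not None:
        implant_overlay = np.asarray(implant_overlay, dtype=np.int8)
        if implant_overlay.shape != labels.shape:
            raise ValueError("implant overlay grid does not match the label grid")
    else:
        implant_overlay = np.zeros(labels.shape, dtype=np.int8)

    table = table if table is not None else DEFAULT_TISSUE_TABLE
    label_names = label_names if label_names is not None else LABEL_NAMES

    sigma = np.zeros(labels.shape, dtype=np.float32)
    eps = np.ones(labels.shape, dtype=np.float32)
    rho = np.full(labels.shape, table["air"].rho, dtype=np.float32)
    for lab in np.unique(labels):
        name = label_names.get(int(lab), "air" if lab == 0 else None)
        if name is None:
            raise KeyError(f"label id {int(lab)} has no name mapping")
        props = material_for(name, table)
        m = labels == lab
        sigma[m], eps[m], rho[m] = props.sigma, props.eps_r, props.rho

    for code, name in ((IMPLANT_CONDUCTOR, "conductor"), (IMPLANT_INSULATION, "insulation")):
        m = implant_overlay == code
        if m.any():
            props = material_for(name, table)
            sigma[m], eps[m], rho[m] = props.sigma, props.eps_r, props.rho

    tissue = (labels > 0) & (implant_overlay == 0)
    return MaterialGrid(grid, sigma, eps, rho, implant_overlay, tissue, labels=labels)
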