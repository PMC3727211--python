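"""Surface meshing of labelled structures and the four-contact DBS lead.

The lead follows the construction used for commercial deep-brain leads: a
smooth cubic-spline centerline (the wire), an insulation tube swept along it,
and an array of four cylindrical electrode contacts at the distal end, all
connected by a continuous conducting core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline, interp1d
from skimage.measure import marching_cubes

from .core import LabelVolume

__all__ = [
    "SurfaceMesh",
    "LeadSpec",
    "LeadGeometry",
    "extract_surface",
    "build_lead",
    "rasterize_lead",
    "mesh_rmse",
    "IMPLANT_NONE",
    "IMPLANT_CONDUCTOR",
    "IMPLANT_INSULATION",
]

IMPLANT_NONE, IMPLANT_CONDUCTOR, IMPLANT_INSULATION = 0, 1, 2


@dataclass
class SurfaceMesh:
    """Triangulated surface with vertices in mm world coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index beyond vertex array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def transformed(self, func) -> "SurfaceMesh":
        return SurfaceMesh(np.asarray(func(self.vertices)), self.faces)

    def save(self, path: str) -> None:
        self.as_trimesh().export(path)

    @classmethod
    def load(cls, path: str) -> "SurfaceMesh":
        m = trimesh.load_mesh(path, process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


def extract_surface(vol: LabelVolume, label: int, step_size: int = 1,
                    smooth_sigma_vox: float = 1.0) -> SurfaceMesh:
    """Triangulate the boundary of one label as a watertight surface.

    The label mask is converted to an indicator volume, lightly smoothed (a
    Gaussian of ``smooth_sigma_vox`` voxels suppresses the staircase area
    inflation of a binary isosurface) and the 0.5 level set extracted with
    marching cubes; vertex coordinates are returned in mm world space
    (voxel-centre convention).
    """
    from scipy.ndimage import gaussian_filter

    mask = vol.labels == label
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"label {label} not present in volume")
    if n < 4:
        raise ValueError(f"label {label} occupies only {n} voxel(s); surface is degenerate")
    ind = np.pad(mask.astype(np.float32), 2)  # closed at the array boundary
    if smooth_sigma_vox > 0:
        ind = gaussian_filter(ind, smooth_sigma_vox)
        if ind.max() <= 0.5:  # structure too thin for this smoothing
            ind = np.pad(mask.astype(np.float32), 2)
    verts, faces, _, _ = marching_cubes(ind, level=0.5, spacing=tuple(vol.spacing),
                                        step_size=step_size)
    verts -= vol.spacing  # one extra pad layer relative to the formula below
    # padded index 1 is voxel 0, whose centre sits at origin + 0.5*spacing
    verts = verts + (vol.origin - 0.5 * vol.spacing)
    return SurfaceMesh(verts, faces)


def mesh_rmse(a: SurfaceMesh | np.ndarray, b: SurfaceMesh | np.ndarray) -> float:
    """Root-mean-square distance between corresponding vertices (mm)."""
    va = np.asarray(getattr(a, "vertices", a), dtype=float)
    vb = np.asarray(getattr(b, "vertices", b), dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"vertex counts differ: {va.shape} vs {vb.shape}")
    return float(np.sqrt(((va - vb) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# DBS lead
# ---------------------------------------------------------------------------

@dataclass
class LeadSpec:
    """Parameters of a four-contact DBS lead.

    Defaults follow a commercial four-contact layout (1.5 mm long contacts
    with 1.5 mm inter-contact spacing and a 1.27 mm contact diameter); the
    insulation is a 1 mm-radius tube swept along the spline centerline.
    ``control_points_mm`` are ordered proximal -> distal; the distal tip is
    the end implanted in the target nucleus.
    """

    control_points_mm: np.ndarray
    insulation_radius_mm: float = 1.0
    n_contacts: int = 4
    contact_length_mm: float = 1.5
    contact_gap_mm: float = 1.5
    contact_radius_mm: float = 0.635
    core_radius_mm: float = 0.25
    tip_clearance_mm: float = 0.0

    def __post_init__(self) -> None:
        self.control_points_mm = np.asarray(self.control_points_mm, dtype=float)
        if self.control_points_mm.ndim != 2 or self.control_points_mm.shape[0] < 4 \
                or self.control_points_mm.shape[1] != 3:
            raise ValueError("need at least four 3-D spline control points")
        for name in ("insulation_radius_mm", "contact_length_mm", "contact_gap_mm",
                     "contact_radius_mm", "core_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["control_points_mm"] = self.control_points_mm.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LeadSpec":
        return cls(**{**d, "control_points_mm": np.asarray(d["control_points_mm"])})


@dataclass
class LeadGeometry:
    """Arc-length-parameterised lead: centerline, contact intervals, radii.

    ``contact_intervals`` are (s_start, s_end) pairs in arc length measured
    from the proximal end, ordered distal -> proximal and disjoint.  The
    conducting core is continuous along the whole lead (the four electrodes
    are connected by the wire).
    """

    centerline_samples: np.ndarray  # (m, 3) points at uniform arc length
    arc_length: float
    contact_intervals: list[tuple[float, float]]
    spec: LeadSpec
    _interp: object = field(default=None, repr=False)

    def point_at(self, s) -> np.ndarray:
        """Centerline point(s) at arc length(s) ``s`` from the proximal end."""
        if self._interp is None:
            m = len(self.centerline_samples)
            svals = np.linspace(0.0, self.arc_length, m)
            self._interp = interp1d(svals, self.centerline_samples, axis=0,
                                    assume_sorted=True)
        return self._interp(np.clip(s, 0.0, self.arc_length))

    @property
    def distal_tip(self) -> np.ndarray:
        return self.centerline_samples[-1]

    def in_contact(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s)
        out = np.zeros(s.shape, dtype=bool)
        for a, b in self.contact_intervals:
            out |= (s >= a) & (s <= b)
        return out

    def contact_centers(self) -> np.ndarray:
        return np.stack([self.point_at(0.5 * (a + b)) for a, b in self.contact_intervals])

    def bounds(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        r = max(self.spec.insulation_radius_mm, self.spec.contact_radius_mm) + pad
        return self.centerline_samples.min(axis=0) - r, self.centerline_samples.max(axis=0) + r


def build_lead(spec: LeadSpec, samples_per_mm: float = 20.0) -> LeadGeometry:
    """Construct the lead geometry from its spec.

    A natural cubic spline interpolates the control points; the curve is then
    re-parameterised by arc length and the ``n_contacts`` contact intervals are
    laid out from the distal tip, separated by ``contact_gap_mm`` of
    insulation.
    """
    cp = spec.control_points_mm
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("control points are coincident")
    spline = CubicSpline(chord, cp, axis=0)
    # dense sampling -> arc-length reparameterisation
    t = np.linspace(0.0, chord[-1], max(int(chord[-1] * samples_per_mm * 4), 200))
    p = spline(t)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    m = max(int(total * samples_per_mm), 50)
    s_uniform = np.linspace(0.0, total, m + 1)
    samples = interp1d(s, p, axis=0, assume_sorted=True)(s_uniform)

    span = spec.n_contacts * spec.contact_length_mm + (spec.n_contacts - 1) * spec.contact_gap_mm
    if spec.tip_clearance_mm + span > total:
        raise ValueError(
            f"contact array ({span:.2f} mm plus {spec.tip_clearance_mm:.2f} mm tip "
            f"clearance) does not fit on the {total:.2f} mm lead"
        )
    intervals = []
    end = total - spec.tip_clearance_mm
    for _ in range(spec.n_contacts):
        start = end - spec.contact_length_mm
        intervals.append((start, end))
        end = start - spec.contact_gap_mm
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if b1 > a0:
            raise ValueError("contact intervals overlap")
    return LeadGeometry(samples, total, intervals, spec)


def rasterize_lead(lead: LeadGeometry, grid) -> np.ndarray:
    """Voxelise the lead onto a rectilinear grid as an implant overlay.

    ``grid`` is anything exposing per-axis cell-centre arrays via
    ``cell_centers()`` (a :class:`~msheadem.dielectrics.RectilinearGrid`) or a
    :class:`~msheadem.core.LabelVolume`.  Returns an int8 array over the grid
    cells with values ``IMPLANT_NONE`` / ``IMPLANT_CONDUCTOR`` /
    ``IMPLANT_INSULATION``:

    * within a contact interval, cells inside the contact radius are
      conductor and the contact surface is exposed to tissue (no insulation
      ring over the contacts);
    * elsewhere the continuous wire core (conductor) is wrapped in insulation
      out to the insulation radius.
    """
    from scipy.spatial import cKDTree

    centers = _grid_centers(grid)
    shape = tuple(len(c) for c in centers)
    lo, hi = lead.bounds(pad=0.0)
    sel = [np.nonzero((c >= lo[a] - 1e-9) & (c <= hi[a] + 1e-9))[0] for a, c in enumerate(centers)]
    if any(len(sl) == 0 for sl in sel):
        raise ValueError("lead does not intersect the grid")
    glo, ghi = (np.array([c[0] for c in centers]), np.array([c[-1] for c in centers]))
    if np.any(lead.centerline_samples.min(axis=0) < glo - 1.0) or \
       np.any(lead.centerline_samples.max(axis=0) > ghi + 1.0):
        # tolerate a lead whose proximal end leaves the grid, but not one
        # entirely misplaced
        inside = np.all((lead.centerline_samples >= glo) & (lead.centerline_samples <= ghi),
                        axis=1)
        if not inside.any():
            raise ValueError("lead lies outside the grid bounds")

    overlay = np.zeros(shape, dtype=np.int8)
    sub = np.stack(np.meshgrid(centers[0][sel[0]], centers[1][sel[1]], centers[2][sel[2]],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    # nearest point on a finely resampled centerline
    m = len(lead.centerline_samples)
    svals = np.linspace(0.0, lead.arc_length, m)
    tree = cKDTree(lead.centerline_samples)
    dist, idx = tree.query(sub)
    s_near = svals[idx]

    spec = lead.spec
    r_out = max(spec.insulation_radius_mm, spec.contact_radius_mm)
    cand = dist <= r_out + 1e-9
    cls = np.zeros(len(sub), dtype=np.int8)
    in_contact = lead.in_contact(s_near)
    core = dist <= spec.core_radius_mm
    contact = in_contact & (dist <= spec.contact_radius_mm)
    insul = (~in_contact) & (dist <= spec.insulation_radius_mm)
    cls[insul & cand] = IMPLANT_INSULATION
    cls[(core | contact) & cand] = IMPLANT_CONDUCTOR
    overlay[np.ix_(sel[0], sel[1], sel[2])] = cls.reshape(len(sel[0]), len(sel[1]), len(sel[2]))
    # the conducting core is continuous: cells traversed by the centerline are
    # conductor even when the wire radius is below the cell size, so the
    # staircased path never breaks into disconnected segments
    inside = np.all((lead.centerline_samples >= glo) & (lead.centerline_samples <= ghi),
                    axis=1)
    line = lead.centerline_samples[inside]
    if len(line):
        idx3 = np.stack([
            np.clip(np.searchsorted(centers[a], line[:, a]) - 0, 0, shape[a] - 1)
            for a in range(3)
        ], axis=1)
        # nearest cell centre per sample
        for a in range(3):
            c = centers[a]
            j = np.clip(np.searchsorted(c, line[:, a]), 1, len(c) - 1)
            idx3[:, a] = np.where(np.abs(line[:, a] - c[j - 1]) <= np.abs(line[:, a] - c[j]),
                                  j - 1, j)
        overlay[idx3[:, 0], idx3[:, 1], idx3[:, 2]] = IMPLANT_CONDUCTOR
    return overlay


def _grid_centers(grid) -> list[np.ndarray]:
    if hasattr(grid, "cell_centers"):
        return list(grid.cell_centers())
    if isinstance(grid, LabelVolume):
        return [grid.axis_centers(a) for a in range(3)]
    raise TypeError(f"unsupported grid type {type(grid)!r}")
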