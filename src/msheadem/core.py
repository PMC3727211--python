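"""Core spatial containers shared by every stage of the pipeline.

All coordinates are in millimetres.  The voxel convention used throughout the
package is *voxel-centred*: the world coordinate of voxel ``(i, j, k)`` of a
:class:`LabelVolume` is ``origin + (index + 0.5) * spacing``, with axes aligned
to the world axes.  Array index order is ``(x, y, z)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume", "LandmarkSet"]


@dataclass
class LabelVolume:
    """Integer tissue/structure labels on a regular axis-aligned grid.

    Parameters
    ----------
    labels : ndarray of int16, shape (nx, ny, nz)
        Label id per voxel; 0 is background/air.
    spacing : array-like of 3 floats
        Voxel edge lengths in mm.
    origin : array-like of 3 floats
        World coordinate of the *corner* of voxel (0, 0, 0); the centre of
        that voxel sits at ``origin + 0.5 * spacing``.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).copy()

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an (nx, ny, nz, 3) array (mm)."""
        cx, cy, cz = (self.axis_centers(a) for a in range(3))
        grid = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)
        return grid

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + np.asarray(self.shape) * self.spacing
        return lo, hi

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices for world points (may be out of bounds)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(np.int64)

    def sample_nn(self, points: np.ndarray, fill: int = -1) -> np.ndarray:
        """Nearest-neighbour label lookup at world points.

        Points outside the volume return ``fill``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        shape = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(pts), fill, dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def mask(self, label_ids) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``label_ids``."""
        return np.isin(self.labels, np.atleast_1d(label_ids))

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        # NIfTI maps voxel indices to the coordinates of voxel centres.
        affine[:3, 3] = self.origin + 0.5 * self.spacing
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "LabelVolume":
        img = nib.load(path)
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3] - 0.5 * spacing
        return cls(np.asanyarray(img.dataobj).astype(np.int16), spacing, origin)


@dataclass
class LandmarkSet:
    """Named fiducial points (mm); the pipeline uses three per volume.

    The canonical triplet mirrors the anterior commissure, posterior
    commissure and the superior point of the interhemispheric fissure.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    @property
    def names(self) -> list[str]:
        return list(self.points.keys())

    def as_array(self, names=None) -> np.ndarray:
        names = names if names is not None else self.names
        return np.stack([self.points[n] for n in names])

    def is_collinear(self, tol: float = 1e-9) -> bool:
        arr = self.as_array()
        if len(arr) < 3:
            return True
        v1, v2 = arr[1] - arr[0], arr[2] - arr[0]
        area = 0.5 * np.linalg.norm(np.cross(v1, v2))
        scale = max(np.linalg.norm(v1), np.linalg.norm(v2), 1.0)
        return area <= tol * scale**2

    def transformed(self, func) -> "LandmarkSet":
        return LandmarkSet({k: np.asarray(func(v[None, :]))[0] for k, v in self.points.items()})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.tolist() for k, v in self.points.items()}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "LandmarkSet":
        with open(path) as fh:
            return cls({k: np.asarray(v) for k, v in json.load(fh).items()})
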