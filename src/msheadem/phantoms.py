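"""Synthetic two-resolution head phantoms with exact ground truth.

The phantom is an analytic, ellipsoid-based stand-in for a segmented human
head: nested shells (skin, skull, CSF, white matter) with deep grey-matter
nuclei (caudate-, putamen-, GPe- and GPi-like blobs) embedded in the white
matter and separated by thin medullary laminae.  The laminae are deliberately
thinner than the coarse (1 mm) voxel size but thicker than the fine (0.2 mm)
one, so rasterising the same geometry at the two resolutions reproduces the
loss of sub-millimetric anatomy that motivates multiscale modelling.

Everything is a pure function of (spec, seed), so the downstream registration
and field solvers can be validated against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelVolume, LandmarkSet
from .registration import FFDGrid, SimilarityTransform, ffd_displacement

__all__ = [
    "Nucleus",
    "Lamina",
    "HeadPhantomSpec",
    "MicroAtlas",
    "LABELS",
    "LABEL_NAMES",
    "NUCLEUS_LABELS",
    "default_head_spec",
    "make_head_phantom",
    "make_micro_atlas",
    "make_probe_points",
]

# Canonical label ids used by the default phantom.
LABELS = {
    "background": 0,
    "skin": 1,
    "skull": 2,
    "csf": 3,
    "white_matter": 4,
    "caudate": 10,
    "putamen": 11,
    "gpe": 12,
    "gpi": 13,
    "eml": 20,  # external medullary lamina (putamen | GPe)
    "iml": 21,  # internal medullary lamina (GPe | GPi)
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
NUCLEUS_LABELS = (LABELS["caudate"], LABELS["putamen"], LABELS["gpe"], LABELS["gpi"])
LAMINA_LABELS = (LABELS["eml"], LABELS["iml"])


@dataclass
class Nucleus:
    """Ellipsoidal deep-nucleus blob (all lengths in mm)."""

    name: str
    center: np.ndarray
    semiaxes: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semiaxes = np.asarray(self.semiaxes, dtype=float)
        if np.any(self.semiaxes <= 0):
            raise ValueError(f"nucleus {self.name}: semiaxes must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - self.center) / self.semiaxes
        return (q**2).sum(axis=-1) <= 1.0

    def surface_points(self, n: int = 200) -> np.ndarray:
        # deterministic Fibonacci sphere scaled to the ellipsoid
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        sph = np.stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
        )
        return self.center + sph * self.semiaxes


@dataclass
class Lamina:
    """Thin planar sheet of white matter separating two nuclei.

    The sheet is the slab ``|(p - point) . normal| <= thickness/2`` clipped to
    an ellipsoidal extent.
    """

    name: str
    point: np.ndarray
    normal: np.ndarray
    thickness: float
    extent_center: np.ndarray
    extent_semiaxes: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.extent_center = np.asarray(self.extent_center, dtype=float)
        self.extent_semiaxes = np.asarray(self.extent_semiaxes, dtype=float)
        if self.thickness <= 0:
            raise ValueError(f"lamina {self.name}: thickness must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.abs((pts - self.point) @ self.normal)
        q = (pts - self.extent_center) / self.extent_semiaxes
        return (d <= self.thickness / 2.0) & ((q**2).sum(axis=-1) <= 1.0)


@dataclass
class HeadPhantomSpec:
    """Full analytic description of the two-resolution head phantom."""

    outer_semiaxes_mm: np.ndarray
    shell_thicknesses_mm: dict[str, float]
    nuclei: list[Nucleus] = field(default_factory=list)
    laminae: list[Lamina] = field(default_factory=list)
    landmarks: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outer_semiaxes_mm = np.asarray(self.outer_semiaxes_mm, dtype=float)
        if np.any(self.outer_semiaxes_mm <= 0):
            raise ValueError("outer semiaxes must be positive")
        for k in ("skin", "skull", "csf"):
            if k not in self.shell_thicknesses_mm:
                raise ValueError(f"missing shell thickness: {k}")

    @property
    def shell_semiaxes(self) -> dict[str, np.ndarray]:
        """Outer semiaxes of each shell boundary, from the skin inwards."""
        o = self.outer_semiaxes_mm
        th = self.shell_thicknesses_mm
        s = {"skin": o}
        s["skull"] = s["skin"] - th["skin"]
        s["csf"] = s["skull"] - th["skull"]
        s["white_matter"] = s["csf"] - th["csf"]
        if np.any(s["white_matter"] <= 0):
            raise ValueError("shells consume the whole head; no white-matter core left")
        return s

    def validate(self) -> None:
        wm = self.shell_semiaxes["white_matter"]
        labels = [n.label for n in self.nuclei] + [l.label for l in self.laminae]
        if len(labels) != len(set(labels)):
            raise ValueError("nucleus/lamina labels must be unique")
        for nuc in self.nuclei:
            q = nuc.surface_points(400) / wm
            if np.any((q**2).sum(axis=1) >= 1.0):
                raise ValueError(
                    f"nucleus '{nuc.name}' is not strictly inside the white matter"
                )


def default_head_spec(seed: int = 0) -> HeadPhantomSpec:
    """The standard desk-scale phantom used by the test and demo fixtures.

    A reduced-scale head (outer semiaxes 16 x 19 x 17 mm) keeps whole-head
    field simulations tractable on one CPU while preserving the anatomy that
    matters for the study: four pallidal/striatal blobs and two laminae of
    0.4 / 0.3 mm thickness, i.e. below the 1 mm coarse voxel and above the
    0.2 mm fine voxel.  Lamina mid-planes sit on integer x coordinates so
    that 1 mm voxel centres (at half-integers) never fall inside them.
    """
    nuclei = [
        Nucleus("caudate", (-2.5, 4.5, 3.0), (3.0, 4.5, 3.5), LABELS["caudate"]),
        Nucleus("putamen", (-5.5, -1.0, 0.0), (2.6, 4.2, 3.4), LABELS["putamen"]),
        Nucleus("gpe", (-1.4, -1.5, -0.5), (2.2, 3.2, 2.6), LABELS["gpe"]),
        Nucleus("gpi", (1.6, -1.8, -1.0), (1.6, 2.4, 2.0), LABELS["gpi"]),
    ]
    laminae = [
        Lamina(
            "eml",
            point=(-3.0, -1.2, -0.2),
            normal=(1.0, 0.0, 0.0),
            thickness=0.4,
            extent_center=(-3.0, -1.3, -0.3),
            extent_semiaxes=(1.0, 3.6, 3.0),
            label=LABELS["eml"],
        ),
        Lamina(
            "iml",
            point=(0.0, -1.7, -0.8),
            normal=(1.0, 0.0, 0.0),
            thickness=0.3,
            extent_center=(0.0, -1.7, -0.8),
            extent_semiaxes=(1.0, 2.8, 2.3),
            label=LABELS["iml"],
        ),
    ]
    return HeadPhantomSpec(
        outer_semiaxes_mm=(16.0, 19.0, 17.0),
        shell_thicknesses_mm={"skin": 1.5, "skull": 2.0, "csf": 1.5},
        nuclei=nuclei,
        laminae=laminae,
        landmarks={"AC": (0.0, 6.0, -1.0), "PC": (0.0, -5.0, -1.0), "apex": (0.0, 0.0, 14.0)},
        seed=seed,
    )


def label_at_points(spec: HeadPhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Analytic label of arbitrary world points (innermost primitive wins)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = np.zeros(len(pts), dtype=np.int16)
    shells = spec.shell_semiaxes

    def _inside(semiaxes):
        q = pts / semiaxes
        return (q**2).sum(axis=1) <= 1.0

    out[_inside(shells["skin"])] = LABELS["skin"]
    out[_inside(shells["skull"])] = LABELS["skull"]
    out[_inside(shells["csf"])] = LABELS["csf"]
    wm = _inside(shells["white_matter"])
    out[wm] = LABELS["white_matter"]
    # nuclei override white matter; later entries (smaller structures) override
    for nuc in spec.nuclei:
        out[wm & nuc.contains(pts)] = nuc.label
    for lam in spec.laminae:
        out[wm & lam.contains(pts)] = lam.label
    return out


def make_head_phantom(
    spec: HeadPhantomSpec, spacing_mm: float, margin_mm: float = 2.0
) -> tuple[LabelVolume, LandmarkSet]:
    """Rasterise the phantom at a given isotropic voxel spacing.

    Labels are assigned at voxel centres; the volume origin falls on integer
    millimetre coordinates so that rasterisations at different spacings share
    the same world frame.
    """
    spacing = float(spacing_mm)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    spec.validate()
    extent = np.ceil(spec.outer_semiaxes_mm + margin_mm)
    origin = -extent
    n = np.ceil(2 * extent / spacing - 1e-9).astype(int)
    axes = [origin[a] + (np.arange(n[a]) + 0.5) * spacing for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    labels = label_at_points(spec, pts).reshape(tuple(n))
    vol = LabelVolume(labels, spacing * np.ones(3), origin)
    lms = LandmarkSet({k: np.asarray(v, dtype=float) for k, v in spec.landmarks.items()})
    return vol, lms


# ---------------------------------------------------------------------------
# Micro-resolution atlas with a known deformation
# ---------------------------------------------------------------------------

@dataclass
class MicroAtlas:
    """A 0.2 mm atlas of the nuclei region, related to the head volume by a
    *known* transform ``W = T_ffd o S`` (similarity followed by an FFD warp in
    head space).  The atlas is the floating dataset: atlas-space point ``x``
    corresponds to head-space point ``W(x)``, which is exactly the transform a
    registration of atlas onto head should recover.
    """

    volume: LabelVolume
    true_ffd: FFDGrid
    true_similarity: SimilarityTransform
    landmarks: LandmarkSet

    def true_transform(self, points: np.ndarray) -> np.ndarray:
        pts = self.true_similarity.apply(points)
        return pts + ffd_displacement(self.true_ffd, pts, extend_zero=True)


def _random_similarity(rng: np.random.Generator, max_angle_deg=8.0, max_scale_dev=0.06,
                       max_shift_mm=3.0) -> SimilarityTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    scale = 1.0 + rng.uniform(-max_scale_dev, max_scale_dev)
    t = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    return SimilarityTransform(R, scale, t)


def make_micro_atlas(
    head: LabelVolume,
    warp_amplitude_mm: float,
    warp_spacing_mm: float,
    seed: int,
    head_landmarks: LandmarkSet | None = None,
    atlas_spacing_mm: float = 0.2,
    region_labels=NUCLEUS_LABELS + LAMINA_LABELS,
    margin_mm: float = 2.0,
    misalign: bool = True,
) -> MicroAtlas:
    """Build the micro-resolution "ex-vivo" atlas of the nuclei region.

    The nuclei sub-volume of ``head`` is resampled at ``atlas_spacing_mm``
    under a random smooth FFD warp composed with a random similarity
    misalignment.  The warp carries two octaves of detail — zero-mean bounded
    control displacements of amplitude ``a`` on a ``warp_spacing_mm`` lattice
    plus amplitude ``a/2`` on the half-spacing lattice — so a coarse-to-fine
    registration recovers it progressively rather than at a single level.
    The exact transform (one control grid on the fine lattice, obtained by
    exact dyadic subdivision of the coarse octave) is returned as ground
    truth.

    ``warp_amplitude_mm`` must stay below half the control spacing; that bound
    keeps the Jacobian of the cubic B-spline field positive (no folding).
    """
    from .registration import subdivide_ffd

    a = float(warp_amplitude_mm)
    delta = float(warp_spacing_mm)
    if a >= delta / 2.0:
        raise ValueError(
            f"warp amplitude {a} mm must be < half the control spacing {delta} mm "
            "to avoid folding"
        )
    rng = np.random.default_rng(seed)

    region = head.mask(list(region_labels))
    if not region.any():
        raise ValueError("head volume contains none of the requested region labels")
    idx = np.argwhere(region)
    lo = head.origin + idx.min(axis=0) * head.spacing - margin_mm
    hi = head.origin + (idx.max(axis=0) + 1) * head.spacing + margin_mm

    # known FFD warp in head space; border control shells stay zero so the
    # field vanishes continuously at the edge of the lattice support
    def _bounded(shape, amp):
        d = rng.uniform(-amp, amp, size=shape)
        d[:2], d[-2:] = 0.0, 0.0
        d[:, :2], d[:, -2:] = 0.0, 0.0
        d[:, :, :2], d[:, :, -2:] = 0.0, 0.0
        return d

    coarse = FFDGrid.covering(lo - a, hi + a, delta)
    coarse.disp = _bounded(coarse.disp.shape, a)
    ffd = subdivide_ffd(coarse)
    ffd.disp = ffd.disp + _bounded(ffd.disp.shape, a / 2.0)

    sim = _random_similarity(rng) if misalign else SimilarityTransform.identity()
    sim_inv = sim.inverse()

    # atlas grid: map the head-space region box into atlas space and pad
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    alo = sim_inv.apply(corners).min(axis=0) - a - margin_mm
    ahi = sim_inv.apply(corners).max(axis=0) + a + margin_mm
    n = np.ceil((ahi - alo) / atlas_spacing_mm).astype(int)
    axes = [alo[k] + (np.arange(n[k]) + 0.5) * atlas_spacing_mm for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    mapped = sim.apply(pts)
    mapped += ffd_displacement(ffd, mapped, extend_zero=True)
    labels = head.sample_nn(mapped, fill=0).reshape(tuple(n))
    vol = LabelVolume(labels.astype(np.int16), atlas_spacing_mm * np.ones(3), alo)

    if head_landmarks is None:
        head_landmarks = LandmarkSet(
            {"AC": (0.0, 6.0, -1.0), "PC": (0.0, -5.0, -1.0), "apex": (0.0, 0.0, 14.0)}
        )
    # landmarks lie outside the warp support, so W reduces to the similarity
    atlas_lms = head_landmarks.transformed(sim_inv.apply)
    return MicroAtlas(vol, ffd, sim, atlas_lms)


def make_probe_points(
    head: LabelVolume, n_per_layer: int, seed: int, layer_labels=None
) -> dict[str, np.ndarray]:
    """Sample reproducible probe points on named tissue layers.

    Returns, for each requested label, ``n_per_layer`` voxel-centre points
    carrying that label (mirroring probe sets along the grey-matter and skin
    layers used for model comparison).
    """
    if layer_labels is None:
        layer_labels = {"skin": LABELS["skin"], "grey_matter": LABELS["gpi"]}
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, lab in layer_labels.items():
        idx = np.argwhere(head.labels == lab)
        if len(idx) == 0:
            raise ValueError(f"layer '{name}' (label {lab}) is empty in this volume")
        if n_per_layer > len(idx):
            raise ValueError(
                f"requested {n_per_layer} points on layer '{name}' but it has "
                f"only {len(idx)} voxels"
            )
        sel = rng.choice(len(idx), size=n_per_layer, replace=False)
        out[name] = head.origin + (idx[sel] + 0.5) * head.spacing
    return out
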