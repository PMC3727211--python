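"""Landmark similarity alignment and hierarchical non-rigid ICP over B-spline
free-form deformations (FFD).

The deformation model is the classic uniform cubic B-spline FFD: a lattice of
control-point displacement vectors ``phi[i, j, k]`` with uniform spacing
``delta`` induces the smooth displacement field

    u(x) = sum_{l,m,n=0..3} B_l(u) B_m(v) B_n(w) phi[i+l, j+m, k+n]

where ``i = floor(tx) - 1``, ``u = tx - floor(tx)`` and ``tx = (x - origin)/delta``
(similarly for y, z), and ``B_0..B_3`` are the cubic B-spline basis polynomials.
The basis is a partition of unity, so a constant control field translates every
point rigidly, and each control point only influences a 4*delta support cube.

Surface registration follows a coarse-to-fine schedule of lattice spacings:
at every level, a non-rigid iterative-closest-point loop alternates
nearest-neighbour correspondence with a damped scattered-data B-spline fit of
the correspondence displacements, each level being initialised from the
refined field of the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import spline_filter
from scipy.sparse.linalg import lsqr
from scipy.spatial import cKDTree

__all__ = [
    "SimilarityTransform",
    "FFDGrid",
    "RegistrationResult",
    "fit_similarity_landmarks",
    "ffd_displacement",
    "ffd_transform",
    "fit_ffd_scattered",
    "refine_ffd",
    "NonRigidICP",
    "icp_nonrigid",
]


# ---------------------------------------------------------------------------
# Similarity (rotation + isotropic scale + translation) from landmarks
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTransform:
    """Rigid rotation, isotropic scale and translation: ``x -> s R x + t``."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.scale = float(self.scale)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(Rinv, sinv, -sinv * Rinv @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


def fit_similarity_landmarks(floating, reference) -> SimilarityTransform:
    """Closed-form least-squares similarity transform mapping ``floating``
    onto ``reference`` (orthogonal Procrustes with isotropic scale).

    Both arguments are :class:`~msheadem.core.LandmarkSet` or (n, 3) arrays of
    corresponding points; landmark sets are matched by name.  The centroids of
    the two point sets are aligned exactly, then rotation and scale minimise
    the summed squared displacements between corresponding points.
    """
    from .core import LandmarkSet

    if isinstance(floating, LandmarkSet) and isinstance(reference, LandmarkSet):
        names = floating.names
        src = floating.as_array(names)
        dst = reference.as_array(names)
    else:
        src = np.atleast_2d(np.asarray(floating, dtype=float))
        dst = np.atleast_2d(np.asarray(reference, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need at least three corresponding landmarks")

    def _collinear(pts: np.ndarray) -> bool:
        c = pts - pts.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        return s[1] <= 1e-9 * max(s[0], 1.0)

    if _collinear(src) or _collinear(dst):
        raise ValueError("landmarks are collinear; similarity fit is degenerate")

    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    cov = cd.T @ cs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (cs**2).sum() / len(src)
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(R, scale, t)


# ---------------------------------------------------------------------------
# FFD lattice and evaluation
# ---------------------------------------------------------------------------

def bspline_weights(u: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at local coordinate ``u`` in [0, 1).

    Returns an array of shape ``u.shape + (4,)`` with ``B_0..B_3``.
    """
    u = np.asarray(u, dtype=float)
    one = 1.0 - u
    out = np.empty(u.shape + (4,))
    out[..., 0] = one**3 / 6.0
    out[..., 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
    out[..., 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    out[..., 3] = u**3 / 6.0
    return out


@dataclass
class FFDGrid:
    """Control-point lattice of displacement vectors with uniform spacing.

    ``disp[i, j, k]`` is the 3-vector displacement (mm) of control point
    ``(i, j, k)`` located at ``origin + (i, j, k) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    disp: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("disp must have shape (nx, ny, nz, 3)")
        if min(self.disp.shape[:3]) < 4:
            raise ValueError("lattice needs at least 4 control points per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    @classmethod
    def covering(cls, lo, hi, spacing: float) -> "FFDGrid":
        """Empty lattice whose B-spline support covers the box [lo, hi]."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        spacing = float(spacing)
        # need local coordinate t in [1, n-3] over the whole box
        n = np.ceil((hi - lo) / spacing).astype(int) + 5
        origin = lo - 2.0 * spacing
        return cls(origin, spacing, np.zeros((*n, 3)))

    @property
    def support_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Box inside which the field may be evaluated."""
        n = np.asarray(self.shape)
        lo = self.origin + 1.0 * self.spacing
        hi = self.origin + (n - 3.0) * self.spacing
        return lo, hi

    def control_positions(self) -> np.ndarray:
        axes = [self.origin[a] + np.arange(self.shape[a]) * self.spacing for a in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.disp, axis=-1).max())


def _ffd_index_weights(grid: FFDGrid, points: np.ndarray, check: bool = True):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t = (pts - grid.origin) / grid.spacing
    base = np.floor(t).astype(np.int64)
    u = t - base
    n = np.asarray(grid.shape)
    if check:
        bad = np.any((base < 1) | (base > n - 3), axis=1)
        if np.any(bad):
            p = pts[np.argmax(bad)]
            raise ValueError(
                f"point {tuple(np.round(p, 3))} outside FFD lattice support "
                f"(support box {grid.support_bounds})"
            )
    else:
        base = np.clip(base, 1, n - 3)
    idx = base - 1  # first of the 4 contributing control points per axis
    w = [bspline_weights(u[:, a]) for a in range(3)]  # each (N, 4)
    return pts, idx, w


def ffd_displacement(grid: FFDGrid, points: np.ndarray, extend_zero: bool = False) -> np.ndarray:
    """Evaluate the FFD displacement field at world points (vectorised).

    With ``extend_zero`` the field is taken to be zero outside the lattice
    support instead of raising; the lattice border controls should be zero for
    this extension to remain continuous.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if extend_zero:
        lo, hi = grid.support_bounds
        inside = np.all((pts >= lo) & (pts <= hi), axis=1)
        out = np.zeros((len(pts), 3))
        if np.any(inside):
            out[inside] = ffd_displacement(grid, pts[inside])
        return out

    _, idx, (wx, wy, wz) = _ffd_index_weights(grid, pts)
    # gather the 4x4x4 neighbourhoods: (N, 4, 4, 4, 3)
    off = np.arange(4)
    gi = idx[:, 0, None] + off  # (N, 4)
    gj = idx[:, 1, None] + off
    gk = idx[:, 2, None] + off
    block = grid.disp[
        gi[:, :, None, None],
        gj[:, None, :, None],
        gk[:, None, None, :],
    ]
    w = wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
    return np.einsum("nlmo,nlmoc->nc", w, block)


def ffd_transform(grid: FFDGrid, points: np.ndarray, extend_zero: bool = False) -> np.ndarray:
    """Displace world points through the FFD: ``x -> x + u(x)``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts + ffd_displacement(grid, pts, extend_zero=extend_zero)


def _design_matrix(grid: FFDGrid, points: np.ndarray) -> sparse.csr_matrix:
    pts, idx, (wx, wy, wz) = _ffd_index_weights(grid, points)
    n = len(pts)
    nx, ny, nz = grid.shape
    off = np.arange(4)
    gi = idx[:, 0, None, None, None] + off[None, :, None, None]
    gj = idx[:, 1, None, None, None] + off[None, None, :, None]
    gk = idx[:, 2, None, None, None] + off[None, None, None, :]
    cols = ((gi * ny) + gj) * nz + gk  # (N,4,4,4)
    w = wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
    rows = np.repeat(np.arange(n), 64)
    A = sparse.coo_matrix(
        (w.ravel(), (rows, cols.ravel())), shape=(n, nx * ny * nz)
    )
    return A.tocsr()


def fit_ffd_scattered(
    points: np.ndarray,
    displacements: np.ndarray,
    lattice: FFDGrid,
    ridge: float = 1e-6,
) -> tuple[FFDGrid, float]:
    """Fit control-point displacements to scattered displacement samples.

    Solves, per component, the damped least-squares problem
    ``min ||A c - d||^2 + ridge ||c||^2`` where ``A`` holds the tensor-product
    B-spline weights of each sample point.  The mild ridge term suppresses
    oscillations of under-constrained control points while barely biasing the
    fit.  Returns the fitted grid and the residual RMS (mm).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.atleast_2d(np.asarray(displacements, dtype=float))
    if len(pts) == 0:
        raise ValueError("no points to fit")
    if pts.shape != d.shape:
        raise ValueError("points and displacements must have matching shapes")
    A = _design_matrix(lattice, pts)
    n, ncp = A.shape
    lam = float(ridge)
    # Exact ridge solution via a direct sparse factorisation.  When the
    # lattice is small the (ncp x ncp) normal equations are cheapest; at fine
    # spacings (many more controls than samples) the dual (n x n) form
    # c = A^T (A A^T + lam I)^-1 d is sparse because only points within a
    # common 4*delta support couple.
    if ncp <= n:
        M = (A.T @ A + lam * sparse.identity(ncp, format="csr")).tocsc()
        rhs = A.T @ d
        coef = sparse.linalg.splu(M).solve(rhs)
    else:
        G = (A @ A.T + lam * sparse.identity(n, format="csr")).tocsc()
        y = sparse.linalg.splu(G).solve(d)
        coef = A.T @ y
    grid = FFDGrid(lattice.origin, lattice.spacing, coef.reshape(*lattice.shape, 3))
    resid = A @ coef - d
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return grid, rms


def subdivide_ffd(grid: FFDGrid) -> FFDGrid:
    """Exact dyadic refinement of a uniform cubic B-spline lattice.

    Knot doubling for uniform cubic B-splines: even coefficients become
    ``(c[i-1] + 6 c[i] + c[i+1]) / 8`` and odd ones ``(c[i] + c[i+1]) / 2``,
    which reproduces the induced field exactly.  The outermost control ring is
    treated as zero, so lattices whose border controls vanish (the package's
    convention for synthetic warps) are refined without boundary error.
    """

    def refine_axis(c: np.ndarray, axis: int) -> np.ndarray:
        c = np.moveaxis(c, axis, 0)
        n = c.shape[0]
        pad = np.zeros((1,) + c.shape[1:])
        cp = np.concatenate([pad, c, pad])  # zero border ring
        even = (cp[:-2] + 6.0 * cp[1:-1] + cp[2:]) / 8.0   # at old nodes 0..n-1
        odd = (cp[1:-1][:-1] + cp[1:-1][1:]) / 2.0          # at half positions
        out = np.empty((2 * n - 1,) + c.shape[1:])
        out[0::2] = even
        out[1::2] = odd
        return np.moveaxis(out, 0, axis)

    d = grid.disp
    for ax in range(3):
        d = refine_axis(d, ax)
    return FFDGrid(grid.origin, grid.spacing / 2.0, d)


def refine_ffd(coarse: FFDGrid, new_spacing: float) -> FFDGrid:
    """Resample a deformation onto a finer lattice (hierarchical refinement).

    The fine control coefficients are chosen so that the fine field
    *interpolates* the coarse field exactly at the fine lattice nodes (cubic
    B-spline prefiltering); between nodes the deviation is far below the
    control spacing.  Constant (translation) fields are reproduced exactly.
    """
    new_spacing = float(new_spacing)
    if new_spacing >= coarse.spacing:
        raise ValueError("new_spacing must be smaller than the coarse spacing")
    lo, hi = coarse.support_bounds
    fine = FFDGrid.covering(lo, hi, new_spacing)
    nodes = fine.control_positions().reshape(-1, 3)
    # clamp nodes in the margin outside the coarse support onto its boundary
    samples = ffd_displacement(
        coarse, np.clip(nodes, lo + 1e-9, hi - 1e-9)
    ).reshape(*fine.shape, 3)
    coef = np.empty_like(samples)
    for c in range(3):
        coef[..., c] = spline_filter(samples[..., c], order=3, mode="mirror")
    fine.disp = coef
    return fine


# ---------------------------------------------------------------------------
# Non-rigid ICP over a coarse-to-fine FFD schedule
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE_MM: tuple[float, ...] = (20.0, 10.0, 5.0, 3.0, 1.0, 0.5)


@dataclass
class RegistrationResult:
    """Outcome of a hierarchical non-rigid surface registration.

    Attributes
    ----------
    similarity : SimilarityTransform
        The landmark/pre-alignment transform applied before the FFD stage
        (identity if the sources were pre-aligned).
    levels : list of FFDGrid
        Fitted lattice at every schedule level; the *last* entry encodes the
        full non-rigid displacement (each level refits the total field).
    schedule_mm, rmse_mm, iterations : per-level metadata.
    """

    similarity: SimilarityTransform
    levels: list[FFDGrid]
    schedule_mm: list[float]
    rmse_mm: list[float]
    iterations: list[int]
    initial_rmse_mm: float = float("nan")
    n_points: int = 0

    @property
    def final_ffd(self) -> FFDGrid:
        return self.levels[-1]

    @property
    def final_rmse_mm(self) -> float:
        return self.rmse_mm[-1]

    def transform(self, points: np.ndarray, level: int = -1) -> np.ndarray:
        """Map floating-space points into reference space."""
        pts = self.similarity.apply(points)
        return ffd_transform(self.levels[level], pts, extend_zero=True)

    def summary(self) -> str:
        lines = [
            "Hierarchical non-rigid ICP registration",
            "=" * 47,
            f"{'level':>6} {'spacing (mm)':>13} {'iters':>6} {'RMSE (mm)':>11}",
            f"{'init':>6} {'-':>13} {'-':>6} {self.initial_rmse_mm:>11.4f}",
        ]
        for i, (s, it, r) in enumerate(zip(self.schedule_mm, self.iterations, self.rmse_mm)):
            lines.append(f"{i:>6} {s:>13.2f} {it:>6d} {r:>11.4f}")
        lines.append("=" * 47)
        lines.append(f"points: {self.n_points}")
        return "\n".join(lines)

    def plot_rmse(self, ax=None):
        from .plotting import plot_registration_rmse

        return plot_registration_rmse(self, ax=ax)


class NonRigidICP:
    """Coarse-to-fine non-rigid ICP between two triangulated surfaces.

    The floating surface is deformed towards the reference (target) surface.
    At each lattice-spacing level of ``schedule_mm`` the algorithm iterates

    1. nearest-neighbour correspondence from the currently-deformed floating
       vertices to the target vertices (spatial KD-tree),
    2. a damped scattered-data B-spline fit of the *total* correspondence
       displacements on that level's lattice,

    until the RMSE change drops below ``tol`` or ``max_iter`` is reached.
    Each level is initialised by refining the previous level's field, so the
    deformation is adjusted gradually while detail increases.

    Parameters
    ----------
    source, target : SurfaceMesh or (n, 3) vertex arrays
        Floating and reference surfaces.  The source is reduced to its vertex
        set; a target *mesh* is subdivided (up to ``target_subdivisions``
        rounds) so that nearest-neighbour queries approximate point-to-surface
        correspondence even when the reference mesh is coarse.
    schedule_mm : sequence of float
        Decreasing control-point spacings.
    max_points : int
        Floating vertices are subsampled (deterministically) to at most this
        many correspondence points to bound the cost of large meshes.
    trim_fraction : float
        Fraction of worst correspondences discarded each iteration (robust
        trimming; 0 disables it).
    """

    def __init__(
        self,
        source,
        target,
        schedule_mm=DEFAULT_SCHEDULE_MM,
        max_iter: int = 50,
        tol: float = 1e-3,
        ridge: float = 0.1,
        trim_fraction: float = 0.0,
        max_points: int = 6000,
        target_subdivisions: int = 2,
        seed: int = 0,
    ) -> None:
        self.source_vertices = _as_vertices(source)
        self.target_vertices = _as_vertices(_densify(target, target_subdivisions))
        self.schedule_mm = [float(s) for s in schedule_mm]
        if any(b >= a for a, b in zip(self.schedule_mm, self.schedule_mm[1:])):
            raise ValueError("schedule_mm must be strictly decreasing")
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.ridge = float(ridge)
        self.trim_fraction = float(trim_fraction)
        self.max_points = int(max_points)
        self.seed = int(seed)

    def fit(self) -> RegistrationResult:
        src = self.source_vertices
        if len(src) > self.max_points:
            rng = np.random.default_rng(self.seed)
            sel = rng.choice(len(src), self.max_points, replace=False)
            sel.sort()
            src = src[sel]
        tree = cKDTree(self.target_vertices)

        both = np.vstack([src, self.target_vertices])
        lo, hi = both.min(axis=0), both.max(axis=0)
        span = float(np.linalg.norm(hi - lo))
        d0, _ = tree.query(src)
        initial_rmse = float(np.sqrt((d0**2).mean()))
        if initial_rmse > 0.5 * span:
            raise ValueError(
                "surfaces do not overlap (initial RMSE exceeds the lattice span); "
                "apply a rigid/similarity pre-registration first"
            )

        current: FFDGrid | None = None
        levels: list[FFDGrid] = []
        rmses: list[float] = []
        iters: list[int] = []
        for spacing in self.schedule_mm:
            pad = max(2.0 * spacing, 2.0)
            lattice = FFDGrid.covering(lo - pad, hi + pad, spacing)
            if current is None:
                base = FFDGrid(lattice.origin, lattice.spacing, np.zeros_like(lattice.disp))
            else:
                # the previous level's total field initialises this level,
                # re-expressed on this lattice by B-spline prefiltered sampling
                nodes = lattice.control_positions().reshape(-1, 3)
                slo, shi = current.support_bounds
                samples = ffd_displacement(
                    current, np.clip(nodes, slo + 1e-9, shi - 1e-9)
                ).reshape(*lattice.shape, 3)
                coef = np.empty_like(samples)
                for c in range(3):
                    coef[..., c] = spline_filter(samples[..., c], order=3, mode="mirror")
                base = FFDGrid(lattice.origin, lattice.spacing, coef)

            # Each iteration fits only the *increment* on top of the level's
            # initialisation: the minimum-norm scattered fit then leaves the
            # smooth inherited field untouched away from the surface data.
            base_disp = ffd_displacement(base, src)
            grid = base
            dist, _ = tree.query(src + base_disp)
            best_rmse = float(np.sqrt((dist**2).mean()))
            best_grid = base
            prev_rmse = best_rmse
            it = 0
            for it in range(1, self.max_iter + 1):
                deformed = src + ffd_displacement(grid, src)
                dist, nn = tree.query(deformed)
                pts, desired = src, self.target_vertices[nn] - src - base_disp
                if self.trim_fraction > 0:
                    keep = dist <= np.quantile(dist, 1.0 - self.trim_fraction)
                    pts, desired = src[keep], desired[keep]
                delta, _ = fit_ffd_scattered(pts, desired, lattice, ridge=self.ridge)
                grid = FFDGrid(lattice.origin, lattice.spacing, base.disp + delta.disp)
                dist, _ = tree.query(src + ffd_displacement(grid, src))
                rmse = float(np.sqrt((dist**2).mean()))
                if rmse < best_rmse:
                    best_rmse, best_grid = rmse, grid
                if abs(prev_rmse - rmse) < self.tol:
                    break
                prev_rmse = rmse
            current = best_grid
            levels.append(best_grid)
            rmses.append(best_rmse)
            iters.append(it)
        return RegistrationResult(
            similarity=SimilarityTransform.identity(),
            levels=levels,
            schedule_mm=self.schedule_mm,
            rmse_mm=rmses,
            iterations=iters,
            initial_rmse_mm=initial_rmse,
            n_points=len(src),
        )


def _densify(obj, rounds: int):
    faces = getattr(obj, "faces", None)
    if faces is None or rounds <= 0 or len(np.atleast_2d(faces)) == 0:
        return obj
    import trimesh

    tm = trimesh.Trimesh(np.asarray(obj.vertices), np.asarray(faces), process=False)
    for _ in range(rounds):
        if len(tm.vertices) > 60000:
            break
        tm = tm.subdivide()
    return tm.vertices


def _as_vertices(obj) -> np.ndarray:
    verts = getattr(obj, "vertices", obj)
    verts = np.atleast_2d(np.asarray(verts, dtype=float))
    if verts.shape[1] != 3:
        raise ValueError("expected (n, 3) vertices")
    return verts


def icp_nonrigid(source, target, schedule_mm=DEFAULT_SCHEDULE_MM, max_iter: int = 50,
                 tol: float = 1e-3, **kw) -> RegistrationResult:
    """Functional wrapper around :class:`NonRigidICP`."""
    return NonRigidICP(source, target, schedule_mm=schedule_mm,
                       max_iter=max_iter, tol=tol, **kw).fit()
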