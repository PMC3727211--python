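"""Self-contained validation experiments.

Each function builds its own small fixture, runs one slice of the package and
returns plain numbers.  They back both the test suite and the reproduction
script (``scripts/acceptance.py``); the independent oracles used here (direct
polynomial evaluation, exhaustive cube search, analytic plane-wave physics)
are deliberately separate from the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from .core import LabelVolume
from .dielectrics import RectilinearGrid, assign_materials
from .fdtd import C0, FDTDSimulation, SimulationParams, SourceSpec
from .metrics import centroid_distance, overlap_metrics
from .registration import (FFDGrid, SimilarityTransform, ffd_displacement,
                           fit_similarity_landmarks)
from .sar import averaged_sar, local_sar

__all__ = [
    "ffd_brute_force_check",
    "similarity_recovery_check",
    "metrics_oracle_check",
    "vacuum_dispersion_check",
    "fresnel_check",
    "pml_reflection_check",
    "sar_cube_oracle_check",
    "full_study_summary",
]


# ---------------------------------------------------------------------------
# FFD / registration oracles
# ---------------------------------------------------------------------------

def bspline_eval_brute(grid: FFDGrid, point: np.ndarray) -> np.ndarray:
    """Direct tensor-product evaluation of the cubic B-spline FFD at a single
    point, written as three explicit nested loops over the 4x4x4 neighbourhood
    with the basis polynomials spelled out."""
    p = np.asarray(point, dtype=float)
    t = (p - grid.origin) / grid.spacing
    base = np.floor(t).astype(int)
    u = t - base

    def B(l, x):
        if l == 0:
            return (1 - x) ** 3 / 6.0
        if l == 1:
            return (3 * x**3 - 6 * x**2 + 4) / 6.0
        if l == 2:
            return (-3 * x**3 + 3 * x**2 + 3 * x + 1) / 6.0
        return x**3 / 6.0

    out = np.zeros(3)
    for l in range(4):
        for m in range(4):
            for n in range(4):
                w = B(l, u[0]) * B(m, u[1]) * B(n, u[2])
                out += w * grid.disp[base[0] - 1 + l, base[1] - 1 + m, base[2] - 1 + n]
    return out


def ffd_brute_force_check(seed: int = 0, n_points: int = 200) -> dict:
    """Partition-of-unity and single-control-point behaviour of the FFD
    against the brute-force evaluator."""
    rng = np.random.default_rng(seed)
    grid = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
    pts = rng.uniform(1.0, 19.0, size=(n_points, 3))

    # constant control field translates rigidly (partition of unity)
    v = np.array([1.25, -0.5, 0.75])
    grid.disp[...] = v
    err_const = float(np.abs(ffd_displacement(grid, pts) - v).max())

    # random field vs brute force
    grid.disp = rng.normal(0.0, 1.0, size=grid.disp.shape)
    vec = ffd_displacement(grid, pts)
    err_brute = max(
        float(np.abs(vec[i] - bspline_eval_brute(grid, pts[i])).max())
        for i in range(min(n_points, 60))
    )

    # single displaced control point: field localised to its 4-delta support
    grid.disp[...] = 0.0
    grid.disp[4, 4, 4, 0] = 1.0
    far = pts[np.abs(pts - (grid.origin + 4 * grid.spacing)).max(axis=1)
              >= 2 * grid.spacing]
    err_local = float(np.abs(ffd_displacement(grid, far)).max()) if len(far) else 0.0
    return {
        "constant_field_max_err_mm": err_const,
        "brute_force_max_err_mm": err_brute,
        "locality_leak_mm": err_local,
    }


def similarity_recovery_check(seed: int = 0, n_trials: int = 100) -> dict:
    """Recover random rotation/scale/translation triplets from landmarks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        pts = rng.uniform(-20, 20, size=(3, 3))
        while np.linalg.svd(pts - pts.mean(0), compute_uv=False)[1] < 1.0:
            pts = rng.uniform(-20, 20, size=(3, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(-np.pi, np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        true = SimilarityTransform(R, rng.uniform(0.5, 2.0), rng.uniform(-10, 10, 3))
        fit = fit_similarity_landmarks(pts, true.apply(pts))
        worst = max(worst, float(np.abs(fit.matrix - true.matrix).max()))
    return {"similarity_recovery_max_err": worst, "n_trials": n_trials}


def metrics_oracle_check(seed: int = 0, n_trials: int = 50) -> dict:
    """Dc/PM/P+ against brute-force voxel counting on random mask pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        shape = (10, 10, 10)
        pred = rng.random(shape) < 0.3
        gt = rng.random(shape) < 0.3
        if not gt.any():
            gt[5, 5, 5] = True
        if not pred.any():
            pred[4, 4, 4] = True
        pm, pp, tp, fp, fn = overlap_metrics(pred, gt)
        # brute force by explicit loops over voxels
        btp = bfp = bfn = 0
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    if pred[i, j, k] and gt[i, j, k]:
                        btp += 1
                    elif pred[i, j, k]:
                        bfp += 1
                    elif gt[i, j, k]:
                        bfn += 1
        bpm = 100.0 * btp / (btp + bfn)
        bpp = 100.0 * btp / (btp + bfp) if (btp + bfp) else float("nan")
        spacing = rng.uniform(0.5, 2.0)
        dc = centroid_distance(pred, gt, spacing)
        ci = np.argwhere(pred).mean(axis=0)
        cj = np.argwhere(gt).mean(axis=0)
        bdc = float(np.linalg.norm((ci - cj) * spacing))
        worst = max(worst, abs(pm - bpm), abs(pp - bpp) if btp + bfp else 0.0,
                    abs(dc - bdc), float(abs(tp - btp) + abs(fp - bfp) + abs(fn - bfn)))
    return {"metrics_oracle_max_abs_err": worst, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# FDTD physics
# ---------------------------------------------------------------------------

def _column(nz: int, dx_mm: float, ncross: int = 4) -> RectilinearGrid:
    ex = np.arange(ncross + 1) * dx_mm
    ez = np.arange(nz + 1) * dx_mm
    return RectilinearGrid((ex, ex, ez))


def _column_params(frequency, source, periods):
    return SimulationParams(frequency=frequency, source=source,
                            pmc_axes=(True, False, False),
                            max_periods=periods, min_periods=periods,
                            convergence_db=-1e-9)


def vacuum_dispersion_check(cells_per_wavelength: int = 20,
                            frequency: float = 1e9) -> dict:
    """Numerical phase velocity of a plane wave in vacuum.

    A uniform soft source plane in a thin column (PMC side walls make the
    propagation exactly one-dimensional) launches a CW wave; the phase slope
    of the steady-state phasor between two probes yields the numerical phase
    velocity, compared with c.
    """
    lam = C0 / frequency * 1e3
    dx = lam / cells_per_wavelength
    nz = 12 * cells_per_wavelength
    grid = _column(nz, dx)
    mat = assign_materials(np.zeros(grid.shape, np.int16), None, grid=grid)
    src = SourceSpec("plane", amplitude=1.0, component="y", plane_axis=2,
                     position_mm=(0, 0, int(1.5 * cells_per_wavelength) * dx))
    res = FDTDSimulation(mat, _column_params(frequency, src, 16)).run()
    Ey = res.field.Ey[1, 1, :]
    cz = grid.cell_centers()[2] * 1e-3
    i1, i2 = 3 * cells_per_wavelength, 8 * cells_per_wavelength
    ph = np.unwrap(np.angle(Ey))
    k = -(ph[i2] - ph[i1]) / (cz[i2] - cz[i1])
    vp = 2 * math.pi * frequency / abs(k)
    return {"phase_velocity_err_pct": (vp / C0 - 1.0) * 100.0, "vp_m_s": vp}


def fresnel_check(eps_r: float = 4.0, cells_per_wavelength: int = 40,
                  frequency: float = 1e9) -> dict:
    """Normal-incidence reflection from a dielectric half-space.

    The steady-state standing wave in the vacuum region is decomposed into
    forward and backward plane waves (using the numerical-dispersion
    wavenumber); ``|r|`` is compared with the analytic Fresnel coefficient
    ``(1 - sqrt(eps_r)) / (1 + sqrt(eps_r))``.
    """
    lam = C0 / frequency * 1e3
    dx = lam / cells_per_wavelength
    nz = 13 * cells_per_wavelength
    grid = _column(nz, dx)
    mat = assign_materials(np.zeros(grid.shape, np.int16), None, grid=grid)
    mat.eps_r[:, :, 8 * cells_per_wavelength:] = eps_r
    src = SourceSpec("plane", amplitude=1.0, component="y", plane_axis=2,
                     position_mm=(0, 0, int(1.5 * cells_per_wavelength) * dx))
    sim = FDTDSimulation(mat, _column_params(frequency, src, 30))
    res = sim.run()
    Ey = res.field.Ey[1, 1, :]
    cz = grid.cell_centers()[2] * 1e-3
    dzm = dx * 1e-3
    w = 2 * math.pi * frequency
    k = 2 / dzm * math.asin(math.sin(w * sim.dt / 2) * dzm / (C0 * sim.dt))
    sl = slice(3 * cells_per_wavelength, int(7.5 * cells_per_wavelength))
    zz = cz[sl]
    A = np.stack([np.exp(-1j * k * zz), np.exp(1j * k * zz)], axis=1)
    (a, b), *_ = np.linalg.lstsq(A, Ey[sl], rcond=None)
    r_num = float(abs(b / a))
    n2 = math.sqrt(eps_r)
    r_true = abs((1 - n2) / (1 + n2))
    return {
        "fresnel_r": r_num,
        "fresnel_r_true": r_true,
        "fresnel_rel_err_pct": (r_num / r_true - 1.0) * 100.0,
    }


def pml_reflection_check(cells_per_wavelength: int = 20,
                         frequency: float = 1e9, layers: int = 7) -> dict:
    """Normal-incidence reflection of the CPML boundary from a vacuum pulse.

    A modulated Gaussian pulse is launched towards the far boundary in a thin
    column; a second run with a much longer column provides the
    reflection-free reference, and the residual at the probe is the boundary
    reflection in dB.
    """
    lam = C0 / frequency * 1e3
    dx = lam / cells_per_wavelength

    def run(nz):
        grid = _column(nz, dx)
        mat = assign_materials(np.zeros(grid.shape, np.int16), None, grid=grid)
        src = SourceSpec("plane", amplitude=1.0, component="y", plane_axis=2,
                         position_mm=(0, 0, 20 * dx), envelope="gaussian",
                         pulse_center_periods=4.0, pulse_spread_periods=1.0)
        par = _column_params(frequency, src, 16)
        par.pml_layers = layers
        sim = FDTDSimulation(mat, par, probes={"p": (1, (1, 1, 60))})
        return np.array(sim.run().probes["p"])

    short = run(120)
    ref = run(420)
    n = min(len(short), len(ref))
    refl = float(np.abs(short[:n] - ref[:n]).max() / np.abs(ref).max())
    return {"pml_reflection_db": 20.0 * math.log10(max(refl, 1e-300)),
            "pml_layers": layers}


# ---------------------------------------------------------------------------
# SAR oracles
# ---------------------------------------------------------------------------

def sar_cube_oracle_check(seed: int = 0, n: int = 5, dx_mm: float = 3.0) -> dict:
    """Cube-averaged SAR against exhaustive search on a small grid, plus the
    power bookkeeping identity."""
    rng = np.random.default_rng(seed)
    e = np.arange(n + 1) * dx_mm
    grid = RectilinearGrid((e, e, e))
    labels = np.full(grid.shape, 4, np.int16)  # white-matter-like tissue
    mat = assign_materials(labels, None, grid=grid)
    Ex = (rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape))
    zero = np.zeros(grid.shape, np.complex64)
    from .fdtd import FieldVolume

    fv = FieldVolume(grid, Ex.astype(np.complex64), zero, zero, 1e8)
    sm = local_sar(fv, mat)
    avg, valid = averaged_sar(sm, mat, 1.0)

    mass = mat.cell_mass_kg()
    power = sm.raw * mass
    cx, cy, cz = grid.cell_centers()

    def brute(i, j, k):
        h = 0.5 * dx_mm
        while True:
            msum = psum = 0.0
            for a in range(n):
                for b in range(n):
                    for c in range(n):
                        if (abs(cx[a] - cx[i]) <= h and abs(cy[b] - cy[j]) <= h
                                and abs(cz[c] - cz[k]) <= h):
                            msum += mass[a, b, c]
                            psum += power[a, b, c]
            if msum >= 1e-3:
                return psum / msum, True
            if h >= n * dx_mm:
                return 0.0, False
            h *= 1.07

    worst = 0.0
    valid_ok = True
    for i in range(n):
        for j in range(n):
            for k in range(n):
                v, ok = brute(i, j, k)
                valid_ok &= (ok == bool(valid[i, j, k]))
                if ok:
                    worst = max(worst, abs(v - avg[i, j, k]))

    # power bookkeeping: sum of per-cell power equals SAR_w * tissue mass
    from .sar import whole_head_sar

    sar_w = whole_head_sar(sm, mat)
    book = abs(power.sum() - sar_w * mass.sum()) / max(power.sum(), 1e-300)
    return {
        "cube_oracle_max_abs_err": worst,
        "cube_oracle_valid_flags_match": bool(valid_ok),
        "power_bookkeeping_rel_err": float(book),
    }


# ---------------------------------------------------------------------------
# full desk-scale study
# ---------------------------------------------------------------------------

def full_study_summary(seed: int = 0, run_em: bool = True) -> dict:
    """Run the packaged experiment and distil its headline numbers.

    Executes the whole chain (phantom, atlas, hierarchical registration,
    label propagation, lead embedding, the three field simulations, SAR
    analysis) at the default desk-scale study conditions and returns the
    quantities the study is about.
    """
    from .pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(seed=int(seed), run_em=run_em)
    report = run_pipeline(cfg)
    out: dict = {"report": report}
    reg = report.registration
    rmse = np.array(list(reg["rmse_table_mm"].values()))          # (S, L)
    dc = np.array(list(reg["dc_table_mm"].values()))              # (S, L+1)
    sched = list(reg["schedule_mm"])
    i3 = sched.index(3.0) + 1  # dc table row 0 is the similarity-only value
    mean_dc = dc.mean(axis=0)
    out["icp_final_rmse_mm"] = float(rmse[:, -1].max())
    out["icp_rmse_max_increase_mm"] = float(np.diff(rmse, axis=1).max())
    out["dc_gain_beyond_3mm_pct"] = float(
        100.0 * (mean_dc[i3] - mean_dc[-1]) / mean_dc[0])
    out["dc_affine_mm"] = float(mean_dc[0])
    out["dc_final_mm"] = float(mean_dc[-1])
    for s in ("caudate", "putamen", "gpe", "gpi"):
        out[f"{s}_pm_pct"] = reg["scores"][s]["pm_pct"]
        out[f"{s}_pplus_pct"] = reg["scores"][s]["pplus_pct"]
    out["laminae_present_in_ms_model"] = reg["scores"]["laminae_present"]

    if run_em:
        em = report.em
        out["noimplant_sar_w_w_kg"] = em["mres_noimplant"]["sar_w"]
        # comparisons restricted to the electrode neighbourhood (fine ROI)
        out["raw_peak_sar_ratio_ms_over_mres"] = (
            em["ms"]["roi_peak_raw"] / em["mres"]["roi_peak_raw"])
        out["sar_w_rel_diff_pct"] = 100.0 * abs(
            em["ms"]["sar_w"] - em["mres"]["sar_w"]) / em["mres"]["sar_w"]
        out["peak_e_ratio_ms_over_mres"] = (
            em["ms"]["roi_peak_e_vm"] / em["mres"]["roi_peak_e_vm"])
        out["peak_shift_mm"] = em["roi_peak_shift_mm"]
        prof = em["profiles"]["right"]
        out["ms_profile_zero_minima"] = prof["ms_zero_minima"]
        out["ms_profile_local_maxima"] = prof["ms_maxima"]
        out["mres_profile_zero_minima"] = prof["mres_zero_minima"]
        for name in ("ms", "mres", "mres_noimplant"):
            out[f"{name}_sar_w"] = em[name]["sar_w"]
            out[f"{name}_peak_raw_sar"] = em[name]["peak_raw"]
            out[f"{name}_peak_1g_sar"] = em[name]["peak_1g"]
            out[f"{name}_peak_10g_sar"] = em[name]["peak_10g"]
    return out
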