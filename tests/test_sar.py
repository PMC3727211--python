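import numpy as np
import pytest

from msheadem.dielectrics import RectilinearGrid, assign_materials, uniform_grid
from msheadem.fdtd import FieldVolume
from msheadem.sar import (add_averaged, averaged_sar, compare_models,
                          count_extrema, line_profile, local_sar,
                          normalize_to_reference, whole_head_sar)


def tissue_block(n=12, dx=2.0, label=4):
    g = uniform_grid(((0, 0, 0), (n * dx, n * dx, n * dx)), dx)
    labels = np.full(g.shape, label, np.int16)
    return g, assign_materials(labels, None, grid=g)


def field_of(grid, ex):
    zero = np.zeros(grid.shape, np.complex64)
    return FieldVolume(grid, np.asarray(ex, np.complex64), zero.copy(),
                       zero.copy(), 1e8)


class TestLocalSar:
    def test_formula_arithmetic(self):
        g = uniform_grid(((0, 0, 0), (4, 4, 4)), 1.0)
        labels = np.full(g.shape, 3, np.int16)  # CSF: sigma 2.14, rho 1010
        mat = assign_materials(labels, None, grid=g)
        mat.sigma[...] = 2.0
        mat.rho[...] = 1000.0
        fv = field_of(g, np.full(g.shape, 10.0))
        sar = local_sar(fv, mat)
        assert sar.raw[1, 1, 1] == pytest.approx(0.1)  # sigma E^2 / (2 rho)

    def test_implant_and_air_masked(self):
        g, mat = tissue_block(6)
        mat.implant[2, 2, 2] = 1
        mat.tissue[2, 2, 2] = False
        mat.tissue[0, 0, 0] = False
        fv = field_of(g, np.full(g.shape, 5.0))
        sar = local_sar(fv, mat)
        assert sar.raw[2, 2, 2] == 0.0
        assert sar.raw[0, 0, 0] == 0.0
        assert sar.raw[3, 3, 3] > 0.0

    def test_zero_field_zero_map(self):
        g, mat = tissue_block(6)
        sar = local_sar(field_of(g, np.zeros(g.shape)), mat)
        assert sar.raw.max() == 0.0


class TestAveragedSar:
    def test_uniform_field_interior_equals_raw(self):
        g, mat = tissue_block(12)
        fv = field_of(g, np.full(g.shape, 10.0))
        sm = add_averaged(local_sar(fv, mat), mat)
        interior = sm.avg_1g[4:8, 4:8, 4:8]
        assert np.allclose(interior, sm.raw[5, 5, 5], rtol=1e-9)

    def test_hot_cell_peak_ordering(self, rng):
        g, mat = tissue_block(12)
        ex = np.full(g.shape, 1.0)
        ex[6, 6, 6] = 100.0
        sm = add_averaged(local_sar(field_of(g, ex), mat), mat)
        assert sm.peak_10g <= sm.peak_1g <= sm.peak_raw

    def test_target_mass_exceeding_domain_rejected(self):
        g, mat = tissue_block(4, dx=1.0)  # tiny block, far below 1 kg
        sm = local_sar(field_of(g, np.ones(g.shape)), mat)
        with pytest.raises(ValueError, match="cannot average"):
            averaged_sar(sm, mat, 1000.0)


class TestWholeVolumeSar:
    def test_uniform(self):
        g, mat = tissue_block(8)
        fv = field_of(g, np.full(g.shape, 10.0))
        sm = local_sar(fv, mat)
        assert whole_head_sar(sm, mat) == pytest.approx(sm.raw[2, 2, 2])

    def test_quadratic_scaling(self):
        g, mat = tissue_block(8)
        s1 = whole_head_sar(local_sar(field_of(g, np.full(g.shape, 10.0)), mat), mat)
        s2 = whole_head_sar(local_sar(field_of(g, np.full(g.shape, 20.0)), mat), mat)
        assert s2 == pytest.approx(4.0 * s1)

    def test_matches_explicit_sum(self, rng):
        g, mat = tissue_block(6)
        ex = rng.random(g.shape) * 10
        sm = local_sar(field_of(g, ex), mat)
        mass = mat.cell_mass_kg()
        expect = float((sm.raw * mass).sum() / mass.sum())
        assert whole_head_sar(sm, mat) == pytest.approx(expect, rel=1e-12)


class TestNormalization:
    def test_scale_factors(self):
        g, mat = tissue_block(6)
        f = field_of(g, np.ones(g.shape))
        scaled, s = normalize_to_reference([f], 3.2, 3.2)
        assert s == pytest.approx(1.0)
        scaled, s = normalize_to_reference([f], 4 * 3.2, 3.2)
        assert s == pytest.approx(0.5)

    def test_recomputed_sar_w_hits_target(self, rng):
        g, mat = tissue_block(8)
        f = field_of(g, rng.random(g.shape) * 30)
        ref = whole_head_sar(local_sar(f, mat), mat)
        (fs,), s = normalize_to_reference([f], ref, 3.2)
        new = whole_head_sar(local_sar(fs, mat), mat)
        assert new == pytest.approx(3.2, rel=1e-6)

    def test_zero_reference_rejected(self):
        g, mat = tissue_block(4)
        with pytest.raises(ValueError, match="positive"):
            normalize_to_reference([field_of(g, np.ones(g.shape))], 0.0)


class TestExtremaProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=3,
                    max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_counts_bounded_and_nonnegative(self, samples):
        nmin, nmax = count_extrema(np.array(samples), 1e-6)
        assert nmin >= 0 and nmax >= 0
        assert nmin + nmax <= len(samples)

    @given(st.lists(st.floats(min_value=0.1, max_value=10.0), min_size=3,
                    max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_zero_minima_require_near_zero_values(self, samples):
        nmin, _ = count_extrema(np.array(samples), 1e-6)
        assert nmin == 0  # all values are bounded away from zero


class TestProfilesAndComparison:
    def test_constant_profile_no_extrema(self):
        assert count_extrema(np.full(50, 3.0), 1e-6) == (0, 0)

    def test_alternating_profile(self):
        assert count_extrema(np.array([1.0, 0.0, 1.0, 0.0, 1.0]), 1e-9) == (2, 3)

    def test_zero_plateau_counts_once(self):
        prof = np.array([2.0, 1.0, 0.0, 0.0, 0.0, 1.0, 2.0, 1.0, 0.5])
        nmin, nmax = count_extrema(prof, 1e-9)
        assert nmin == 1
        assert nmax == 2  # the two shoulders at the ends of the valley

    def test_line_profile_trilinear_on_linear_field(self):
        g = uniform_grid(((0, 0, 0), (10, 10, 10)), 1.0)
        cx, cy, cz = g.cell_centers()
        ex = np.broadcast_to(cz, g.shape).astype(np.complex64)
        f = field_of(g, ex)
        pts, vals = line_profile(f, (5, 5, 1.0), (5, 5, 9.0), step_mm=0.5)
        assert np.allclose(vals, pts[:, 2], atol=1e-5)

    def test_line_outside_grid_rejected(self):
        g = uniform_grid(((0, 0, 0), (10, 10, 10)), 1.0)
        f = field_of(g, np.ones(g.shape))
        with pytest.raises(ValueError, match="grid"):
            line_profile(f, (5, 5, 5), (5, 5, 50))

    def test_identical_models_zero_shift(self):
        g, mat = tissue_block(8)
        f = field_of(g, np.arange(np.prod(g.shape)).reshape(g.shape) * 1.0)
        out = compare_models(f, f, np.array([[8.0, 8.0, 8.0]]))
        assert out["peak_shift_mm"] == 0.0
        assert out["probe_diff_mean"] == 0.0

    def test_translated_peak_shift(self):
        g, mat = tissue_block(10)
        ex = np.zeros(g.shape)
        ex[4, 4, 4] = 10.0
        ex2 = np.zeros(g.shape)
        ex2[5, 4, 4] = 10.0
        out = compare_models(field_of(g, ex), field_of(g, ex2),
                             np.array([[10.0, 10.0, 10.0]]))
        assert out["peak_shift_mm"] == pytest.approx(2.0)  # one 2 mm voxel
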