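import math

import numpy as np
import pytest

from msheadem.dielectrics import (RectilinearGrid, assign_materials,
                                  build_multiscale_grid, uniform_grid)
from msheadem.fdtd import (C0, FDTDSimulation, SimulationParams, SourceSpec,
                           courant_dt, make_source)


class TestCourant:
    def test_uniform_1mm_closed_form(self):
        g = uniform_grid(((0, 0, 0), (10, 10, 10)), 1.0)
        dt = courant_dt(g, 1.0)
        expect = 1e-3 / (C0 * math.sqrt(3.0))
        assert dt == pytest.approx(expect, rel=1e-12)
        assert dt == pytest.approx(1.9245e-12, rel=1e-4)

    def test_reported_millimetre_timestep_is_stable(self):
        """A 1.07 ps step lies below the 1 mm-grid Courant limit."""
        g = uniform_grid(((0, 0, 0), (10, 10, 10)), 1.0)
        assert 1.07e-12 <= courant_dt(g, 1.0)

    def test_halving_cells_halves_dt(self):
        g1 = uniform_grid(((0, 0, 0), (10, 10, 10)), 1.0)
        g2 = uniform_grid(((0, 0, 0), (10, 10, 10)), 0.5)
        assert courant_dt(g2, 1.0) == pytest.approx(courant_dt(g1, 1.0) / 2)

    def test_graded_grid_uses_smallest_cells(self):
        g = build_multiscale_grid(((0, 0, 0), (30, 30, 30)),
                                  ((10, 10, 10), (14, 14, 14)), 0.2, 1.0)
        ref = 1.0 / (C0 * math.sqrt(3 / (0.2e-3) ** 2))
        assert courant_dt(g, 1.0) == pytest.approx(ref, rel=1e-9)


class TestSources:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown source"):
            make_source("warp_drive")

    def test_quadrature_components_orthogonal(self):
        src = make_source("cp_planewave", direction=(1, 0, 0), pol1=(0, 1, 0))
        assert src.quadrature


def small_vacuum(n=24, dx=5.0):
    g = uniform_grid(((0, 0, 0), (n * dx, n * dx, n * dx)), dx)
    mat = assign_materials(np.zeros(g.shape, np.int16), None, grid=g)
    return g, mat


class TestSolverBasics:
    def test_zero_amplitude_source_zero_fields(self):
        g, mat = small_vacuum()
        src = SourceSpec("dipole", amplitude=0.0, component="z",
                         position_mm=(60, 60, 60))
        par = SimulationParams(frequency=1e9, source=src, max_periods=3,
                               min_periods=3, convergence_db=-1e-9)
        res = FDTDSimulation(mat, par).run()
        assert res.field.e_mag().max() == 0.0

    def test_cp_planewave_vacuum_is_uniform_and_circular(self):
        """In vacuum the CP drive is the ideal rotating plane wave: uniform
        |E| equal to the component amplitude."""
        g, mat = small_vacuum(n=20)
        src = SourceSpec("cp_planewave", amplitude=2.0, direction=(1, 0, 0),
                         pol1=(0, 1, 0), quadrature=True)
        par = SimulationParams(frequency=1e9, source=src, max_periods=3,
                               min_periods=3, convergence_db=-1e-9)
        res = FDTDSimulation(mat, par).run()
        # phasor norm of a circularly polarised wave is sqrt(2) x amplitude
        mag = res.field.e_mag()
        interior = mag[5:-5, 5:-5, 5:-5]
        assert np.abs(interior / (2.0 * math.sqrt(2)) - 1.0).max() < 0.02
        # rotating field: both quadrature components present, and the
        # instantaneous |E(t)| equals the component amplitude at every phase
        assert np.abs(np.abs(res.field.Ey[10, 10, 10]) - 2.0) < 0.05
        assert np.abs(np.abs(res.field.Ez[10, 10, 10]) - 2.0) < 0.05
        phases = np.exp(1j * np.linspace(0, 2 * np.pi, 16, endpoint=False))
        ey = np.real(res.field.Ey[10, 10, 10] * phases)
        ez = np.real(res.field.Ez[10, 10, 10] * phases)
        inst = np.sqrt(ey**2 + ez**2)
        assert np.abs(inst / 2.0 - 1.0).max() < 0.01

    def test_pec_cells_have_zero_field(self):
        g, mat = small_vacuum(n=20)
        mat.sigma[8:12, 8:12, 8:12] = 4.0e6
        src = SourceSpec("cp_planewave", amplitude=1.0, direction=(1, 0, 0),
                         pol1=(0, 1, 0))
        par = SimulationParams(frequency=1e9, source=src, max_periods=4,
                               min_periods=4, convergence_db=-1e-9)
        res = FDTDSimulation(mat, par).run()
        mag = res.field.e_mag()
        assert mag[9:11, 9:11, 9:11].max() == 0.0
        assert mag[2, 2, 2] > 0.1

    def test_dipole_ring_linear_mode_mirror_symmetric(self):
        g, mat = small_vacuum(n=20)
        src = SourceSpec("dipole_ring", amplitude=1.0, component="z",
                         position_mm=(50, 50, 50), ring_radius_mm=20.0,
                         ring_elements=8, quadrature=False)
        par = SimulationParams(frequency=1e9, source=src, max_periods=4,
                               min_periods=4, convergence_db=-1e-9)
        res = FDTDSimulation(mat, par).run()
        mag = res.field.e_mag()
        cy = mag.shape[1] // 2
        top = mag[:, cy + 3, :]
        bot = mag[:, cy - 1 - 3 + 1, :]  # mirror plane between cells
        sym = np.abs(top - bot) / (np.abs(top).max() + 1e-12)
        assert np.median(sym) < 0.1

    def test_energy_bounded_in_passive_vacuum(self):
        g, mat = small_vacuum(n=16)
        src = SourceSpec("dipole", amplitude=1.0, component="y",
                         position_mm=(40, 40, 40))
        par = SimulationParams(frequency=1e9, source=src, max_periods=8,
                               min_periods=8, convergence_db=-1e-9)
        res = FDTDSimulation(mat, par).run()
        U = np.array(res.convergence.energy)
        # after ramp-up the driven steady state never exceeds its running
        # maximum appreciably
        post = U[3:]
        assert post.max() <= 1.05 * post[:-1].max() + 1e-30


class TestGridRefinementConsistency:
    def test_interior_field_converges_under_refinement(self):
        """Halving the cells of a small lossy-sphere phantom changes the
        interior field by a few percent: region means within 5 %, pointwise
        values (staircase-limited) within 10 %."""
        from scipy.interpolate import RegularGridInterpolator

        from msheadem.dielectrics import scale_table_to_frequency

        def run(spacing, f=1.0e9, R=8.0, dom=36.0):
            g = uniform_grid(((0, 0, 0), (dom, dom, dom)), spacing)
            labels = np.zeros(g.shape, np.int16)
            cx, cy, cz = g.cell_centers()
            pts = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)
            c = dom / 2.0
            labels[((pts - c) ** 2).sum(-1) <= R * R] = 4
            mat = assign_materials(labels, None, scale_table_to_frequency(f),
                                   grid=g)
            src = SourceSpec("cp_planewave", amplitude=1.0, direction=(1, 0, 0),
                             pol1=(0, 1, 0))
            par = SimulationParams(frequency=f, source=src, max_periods=14,
                                   min_periods=4, convergence_db=-40.0)
            res = FDTDSimulation(mat, par).run()
            mag = res.field.e_mag()
            core = ((pts - c) ** 2).sum(-1) <= (0.75 * R) ** 2
            probe = float(RegularGridInterpolator(g.cell_centers(), mag)(
                [[c, c, c]])[0])
            return float(mag[core].mean()), probe

        m1, p1 = run(1.0)
        m2, p2 = run(0.5)
        assert abs(m1 - m2) / m2 < 0.05
        assert abs(p1 - p2) / p2 < 0.10


class TestConvergenceMonitor:
    def test_lossy_phantom_converges_with_flag(self):
        from msheadem.dielectrics import scale_table_to_frequency

        g = uniform_grid(((0, 0, 0), (60, 60, 60)), 2.0)
        labels = np.zeros(g.shape, np.int16)
        labels[8:22, 8:22, 8:22] = 4  # white-matter block
        # loss-tangent-preserving conductivity at the fixture frequency
        mat = assign_materials(labels, None,
                               scale_table_to_frequency(2.45e9), grid=g)
        src = SourceSpec("cp_planewave", amplitude=1.0, direction=(1, 0, 0),
                         pol1=(0, 1, 0))
        par = SimulationParams(frequency=2.45e9, source=src, max_periods=20,
                               min_periods=4, convergence_db=-35.0)
        res = FDTDSimulation(mat, par).run()
        assert res.convergence.converged
        assert res.convergence.final_db() <= -35.0
        assert res.n_periods < 21
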