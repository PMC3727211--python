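import math

import numpy as np
import pytest

from msheadem.core import LabelVolume
from msheadem.dielectrics import build_multiscale_grid
from msheadem.geometry import (IMPLANT_CONDUCTOR, IMPLANT_INSULATION, LeadSpec,
                               SurfaceMesh, build_lead, extract_surface,
                               mesh_rmse, rasterize_lead)


class TestExtractSurface:
    def test_sphere_area_and_distance(self, sphere_volume):
        mesh = extract_surface(sphere_volume, 1)
        assert abs(mesh.area / (4 * math.pi * 100.0) - 1.0) < 0.03
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(r - 10.0).max() <= 0.5 * math.sqrt(3)  # one voxel diagonal
        assert mesh.is_watertight

    def test_absent_label_raises(self, sphere_volume):
        with pytest.raises(ValueError, match="not present"):
            extract_surface(sphere_volume, 99)

    def test_single_voxel_label_degenerate(self):
        lab = np.zeros((8, 8, 8), np.int16)
        lab[4, 4, 4] = 1
        vol = LabelVolume(lab, 1.0, np.zeros(3))
        with pytest.raises(ValueError, match="degenerate"):
            extract_surface(vol, 1)


class TestMeshRmse:
    def test_identity_and_translation(self, sphere_volume):
        mesh = extract_surface(sphere_volume, 1)
        assert mesh_rmse(mesh, mesh) == 0.0
        moved = SurfaceMesh(mesh.vertices + [3.0, 0.0, 0.0], mesh.faces)
        assert abs(mesh_rmse(mesh, moved) - 3.0) < 1e-12

    def test_matches_direct_loop(self, rng):
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(40, 3))
        direct = math.sqrt(np.mean([np.sum((a[i] - b[i]) ** 2) for i in range(40)]))
        assert abs(mesh_rmse(a, b) - direct) < 1e-12

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError, match="differ"):
            mesh_rmse(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


def straight_lead(**kw):
    cps = np.array([[0.0, 0.0, 19.0], [0.0, 0.0, 12.0], [0.0, 0.0, 6.0],
                    [0.0, 0.0, 0.0]])
    return build_lead(LeadSpec(cps, **kw))


class TestBuildLead:
    def test_straight_arc_length(self):
        lead = straight_lead()
        assert abs(lead.arc_length - 19.0) < 1e-9

    def test_default_four_contacts_with_gaps(self):
        lead = straight_lead()
        assert len(lead.contact_intervals) == 4
        ivals = lead.contact_intervals  # distal -> proximal
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            assert a0 - b1 == pytest.approx(1.5)  # insulation gap
            assert b0 - a0 == pytest.approx(1.5)  # contact length

    def test_contacts_must_fit(self):
        cps = np.array([[0, 0, 5.0], [0, 0, 3.5], [0, 0, 2.0], [0, 0, 0.0]])
        with pytest.raises(ValueError, match="does not fit"):
            build_lead(LeadSpec(cps))

    def test_rigid_invariance(self, rng):
        """Lead geometry transforms covariantly with its control points."""
        lead = straight_lead()
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([3.0, -2.0, 5.0])
        cps2 = straight_lead().spec.control_points_mm @ R.T + t
        lead2 = build_lead(LeadSpec(cps2))
        assert abs(lead.arc_length - lead2.arc_length) < 1e-6
        assert np.allclose(lead2.distal_tip, R @ lead.distal_tip + t, atol=1e-6)
        assert np.allclose(lead.contact_intervals, lead2.contact_intervals, atol=1e-6)


@pytest.fixture(scope="module")
def fine_grid():
    return build_multiscale_grid(((-4, -4, -2), (4, 4, 21)),
                                 ((-2, -2, -2), (2, 2, 21)),
                                 fine_mm=0.2, coarse_mm=1.0)


class TestRasterizeLead:

    def test_contact_runs_fine_grid(self, fine_grid):
        """Off-axis samples show 4 disjoint conductor runs (the contacts)."""
        lead = straight_lead(contact_radius_mm=0.635, insulation_radius_mm=0.635,
                             core_radius_mm=0.25)
        overlay = rasterize_lead(lead, fine_grid)
        cx, cy, _ = fine_grid.cell_centers()
        ix = int(np.argmin(np.abs(cx - 0.5)))  # outside core, inside contact
        iy = int(np.argmin(np.abs(cy)))
        col = overlay[ix, iy, :]
        runs = 0
        prev = 0
        for v in col:
            if v == IMPLANT_CONDUCTOR and prev != IMPLANT_CONDUCTOR:
                runs += 1
            prev = v
        assert runs == 4
        assert (col == IMPLANT_INSULATION).sum() > 0

    def test_brute_force_oracle(self, fine_grid, rng):
        lead = straight_lead(contact_radius_mm=0.635, insulation_radius_mm=0.635,
                             core_radius_mm=0.25)
        overlay = rasterize_lead(lead, fine_grid)
        cx, cy, cz = fine_grid.cell_centers()
        spec = lead.spec
        mism = 0
        checked = 0
        for _ in range(300):
            i = rng.integers(len(cx))
            j = rng.integers(len(cy))
            k = rng.integers(len(cz))
            p = np.array([cx[i], cy[j], cz[k]])
            r = math.hypot(p[0], p[1])  # straight lead on the z axis
            s = p[2]
            if s < 0 or s > lead.arc_length:
                expect = 0
            elif lead.in_contact(np.array([s]))[0]:
                expect = IMPLANT_CONDUCTOR if r <= spec.contact_radius_mm else 0
            elif r <= spec.core_radius_mm:
                expect = IMPLANT_CONDUCTOR
            elif r <= spec.insulation_radius_mm:
                expect = IMPLANT_INSULATION
            else:
                expect = 0
            # skip centreline-connectivity cells and boundary-ambiguous radii
            near_edge = min(abs(r - spec.contact_radius_mm),
                            abs(r - spec.core_radius_mm),
                            abs(r - spec.insulation_radius_mm)) < 0.15
            on_axis_cell = r < 0.75 * max(np.diff(fine_grid.edges[0]).max(),
                                          np.diff(fine_grid.edges[1]).max())
            if near_edge or on_axis_cell or abs(s) < 0.5 \
                    or abs(s - lead.arc_length) < 0.5:
                continue
            checked += 1
            if overlay[i, j, k] != expect:
                mism += 1
        assert checked > 50
        assert mism == 0

    def test_coarse_grid_staircases_small_gaps(self):
        """Gaps below the cell size merge into the conductor (staircasing)."""
        lead = straight_lead(contact_length_mm=1.5, contact_gap_mm=0.5,
                             contact_radius_mm=0.635, insulation_radius_mm=0.635,
                             core_radius_mm=0.25)
        fine = build_multiscale_grid(((-4, -4, -2), (4, 4, 21)),
                                     ((-2, -2, -2), (2, 2, 21)), 0.2, 1.0)
        coarse = build_multiscale_grid(((-4, -4, -2), (4, 4, 21)), None,
                                       coarse_mm=1.0)

        def contact_runs(grid):
            overlay = rasterize_lead(lead, grid)
            cx, cy, _ = grid.cell_centers()
            ix = int(np.argmin(np.abs(cx - 0.4)))
            iy = int(np.argmin(np.abs(cy)))
            col = overlay[ix, iy, :]
            runs, prev = 0, 0
            for v in col:
                if v == IMPLANT_CONDUCTOR and prev != IMPLANT_CONDUCTOR:
                    runs += 1
                prev = v
            return runs

        assert contact_runs(fine) == 4
        assert contact_runs(coarse) < 4

    def test_lead_outside_grid(self):
        lead = straight_lead()
        far = build_multiscale_grid(((100, 100, 100), (120, 120, 120)), None,
                                    coarse_mm=1.0)
        with pytest.raises(ValueError):
            rasterize_lead(lead, far)

    def test_conductor_volume_converges(self):
        """Conductor voxel volume approaches the analytic cylinder volume."""
        lead = straight_lead(contact_radius_mm=0.635, insulation_radius_mm=0.635,
                             core_radius_mm=0.25)
        spec = lead.spec
        analytic = 4 * (math.pi * 0.635**2 * 1.5)  # contacts
        # core volume over the remaining length
        core_len = lead.arc_length - 4 * 1.5
        analytic += math.pi * 0.25**2 * core_len
        grid = build_multiscale_grid(((-3, -3, -1), (3, 3, 20)),
                                     ((-3, -3, -1), (3, 3, 20)), 0.2, 0.2)
        overlay = rasterize_lead(lead, grid)
        vol = (overlay == IMPLANT_CONDUCTOR).sum() * 0.2**3
        assert abs(vol - analytic) / analytic < 0.10
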