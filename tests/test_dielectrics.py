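import numpy as np
import pytest

from msheadem.core import LabelVolume
from msheadem.dielectrics import (DEFAULT_TISSUE_TABLE, RectilinearGrid,
                                  assign_materials, build_multiscale_grid,
                                  load_tissue_table, material_for,
                                  sample_labels, save_tissue_table,
                                  uniform_grid)
from msheadem.geometry import IMPLANT_CONDUCTOR, IMPLANT_INSULATION


class TestMaterialTable:
    @pytest.mark.parametrize("name,sigma,eps", [
        ("GPi", 0.58, 73.51),       # nuclei take grey-matter values
        ("gpe", 0.58, 73.51),
        ("IML", 0.34, 52.53),       # laminae take white-matter values
        ("white_matter", 0.34, 52.53),
        ("air", 0.0, 1.0),
        ("conductor", 4.0e6, 1.0),
        ("insulation", 1.0e-10, 3.0),
    ])
    def test_lookup(self, name, sigma, eps):
        props = material_for(name)
        assert props.sigma == pytest.approx(sigma)
        assert props.eps_r == pytest.approx(eps)

    def test_unknown_label_lists_names(self):
        with pytest.raises(KeyError, match="grey_matter"):
            material_for("unobtainium")

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "table.yaml"
        save_tissue_table(DEFAULT_TISSUE_TABLE, str(path))
        back = load_tissue_table(str(path))
        assert back["grey_matter"] == DEFAULT_TISSUE_TABLE["grey_matter"]


class TestMultiscaleGrid:
    def test_uniform_when_roi_covers_domain(self):
        g = build_multiscale_grid(((0, 0, 0), (10, 10, 10)),
                                  ((0, 0, 0), (10, 10, 10)), 0.5, 1.0)
        for d in g.cell_sizes():
            assert np.allclose(d, 0.5)

    def test_grading_ratio_bounded_and_roi_covered(self):
        g = build_multiscale_grid(((-30, -30, -30), (30, 30, 30)),
                                  ((-3, -2, -5), (3, 2, 5)), 0.2, 1.0, 1.5)
        assert g.max_adjacent_ratio() <= 1.5 + 1e-9
        for a in range(3):
            d = np.diff(g.edges[a])
            lo, hi = g.fine_box[0][a], g.fine_box[1][a]
            inside = (g.edges[a][:-1] >= lo - 1e-9) & (g.edges[a][1:] <= hi + 1e-9)
            assert np.allclose(d[inside], 0.2)

    def test_degenerate_roi_gives_uniform_coarse(self):
        g = build_multiscale_grid(((0, 0, 0), (20, 20, 20)),
                                  ((5, 5, 5), (5, 5, 5)), 0.2, 1.0)
        for d in g.cell_sizes():
            assert np.allclose(d, 1.0)

    def test_roi_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            build_multiscale_grid(((0, 0, 0), (10, 10, 10)),
                                  ((5, 5, 5), (15, 8, 8)))

    def test_total_volume_conserved(self):
        g = build_multiscale_grid(((-20, -10, -15), (20, 10, 15)),
                                  ((-2, -2, -2), (2, 2, 2)), 0.2, 1.0)
        assert g.total_volume == pytest.approx(40 * 20 * 30)
        assert g.cell_volumes().sum() == pytest.approx(40 * 20 * 30)


class TestAssignMaterials:
    def test_homogeneous_grey_matter(self):
        g = uniform_grid(((0, 0, 0), (5, 5, 5)), 1.0)
        labels = np.full(g.shape, 13, np.int16)  # GPi-analogue
        mat = assign_materials(labels, None, grid=g)
        assert np.allclose(mat.sigma, 0.58)
        assert np.allclose(mat.eps_r, 73.51)
        assert mat.tissue.all()

    def test_implant_overrides_tissue(self):
        g = uniform_grid(((0, 0, 0), (5, 5, 5)), 1.0)
        labels = np.full(g.shape, 13, np.int16)
        overlay = np.zeros(g.shape, np.int8)
        overlay[2, 2, 2] = IMPLANT_CONDUCTOR
        overlay[2, 2, 3] = IMPLANT_INSULATION
        mat = assign_materials(labels, overlay, grid=g)
        assert mat.sigma[2, 2, 2] == pytest.approx(4.0e6)
        assert mat.sigma[2, 2, 3] == pytest.approx(1.0e-10)
        assert mat.pec[2, 2, 2] and not mat.pec[2, 2, 3]

    def test_flags_partition_cells(self, head_coarse):
        vol, _ = head_coarse
        mat = assign_materials(vol, None)
        air = ~mat.tissue & (mat.implant == 0)
        n = mat.tissue.sum() + air.sum() + (mat.implant > 0).sum()
        assert n == np.prod(mat.grid.shape)

    def test_grid_mismatch_rejected(self):
        g = uniform_grid(((0, 0, 0), (5, 5, 5)), 1.0)
        with pytest.raises(ValueError, match="match"):
            assign_materials(np.zeros((2, 2, 2), np.int16), None, grid=g)


class TestSampleLabels:
    def test_fine_volume_takes_priority(self):
        coarse = LabelVolume(np.full((10, 10, 10), 4, np.int16), 1.0,
                             np.full(3, -5.0))
        fine = LabelVolume(np.full((10, 10, 10), 13, np.int16), 0.2,
                           np.full(3, -1.0))
        g = uniform_grid(((-5, -5, -5), (5, 5, 5)), 1.0)
        lab = sample_labels(g, [fine, coarse])
        cx, cy, cz = g.cell_centers()
        i = int(np.argmin(np.abs(cx)))
        assert lab[i, i, i] == 13          # inside the fine volume
        assert lab[0, 0, 0] == 4           # outside it

    def test_material_assignment_stable_under_refinement(self, head_spec):
        """Cells fully inside a structure keep their label when the grid is
        refined (consistency of the centre-sampling rule)."""
        from msheadem.phantoms import make_head_phantom

        vol, _ = make_head_phantom(head_spec, 0.4)
        box = ((-6.0, -6.0, -6.0), (6.0, 6.0, 6.0))
        g1 = uniform_grid(box, 1.0)
        g2 = uniform_grid(box, 0.5)
        l1 = sample_labels(g1, [vol])
        l2 = sample_labels(g2, [vol])
        # compare the eight fine cells inside each coarse cell
        for idx in [(2, 2, 2), (5, 5, 5), (8, 3, 6)]:
            sub = l2[2 * idx[0]:2 * idx[0] + 2, 2 * idx[1]:2 * idx[1] + 2,
                     2 * idx[2]:2 * idx[2] + 2]
            if len(np.unique(sub)) == 1:   # cell fully inside one structure
                assert sub[0, 0, 0] == l1[idx]
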