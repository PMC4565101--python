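"""Geometry presets and voxelization."""

import numpy as np
import pytest

from ectplan import (
    BACKGROUND,
    ELECTRODE_BASE,
    TUMOR,
    ElectrodeConfig,
    NeedleElectrode,
    TissueModel,
    make_asymmetric_config,
    make_asymmetric_config_from_distances,
    make_internal_config,
    make_symmetric_config,
    rasterize,
)


@pytest.fixture(scope="module")
def tissue():
    return TissueModel()


class TestSymmetricPreset:
    def test_external_pair_distances_match_device_log(self, tissue):
        cfg = make_symmetric_config(tissue)
        for a, b in [(1, 2), (1, 4), (2, 3), (3, 4)]:
            assert cfg.pair_distance(a, b) == pytest.approx(2.0)

    def test_central_pair_distance_is_sqrt2(self, tissue):
        cfg = make_symmetric_config(tissue)
        for k in (1, 2, 3, 4):
            assert cfg.pair_distance(5, k) == pytest.approx(np.sqrt(2.0))

    def test_all_needles_vertical(self, tissue):
        cfg = make_symmetric_config(tissue)
        for e in cfg:
            assert np.allclose(e.direction, (0, 0, -1))

    def test_active_segment_straddles_tumor_midplane(self, tissue):
        cfg = make_symmetric_config(tissue)
        e = cfg.get(1)
        assert e.entry_point[2] == pytest.approx(1.5)
        assert e.tip[2] == pytest.approx(-1.5)


class TestAsymmetricPreset:
    def test_center_distances_match_reconstruction(self, tissue):
        cfg = make_asymmetric_config(tissue)
        assert cfg.pair_distance(5, 1) == pytest.approx(np.sqrt(2) - 0.18, abs=1e-9)
        assert cfg.pair_distance(5, 2) == pytest.approx(1.12, abs=0.02)
        assert cfg.pair_distance(5, 3) == pytest.approx(1.19, abs=0.02)

    def test_electrode_4_unchanged(self, tissue):
        sym = make_symmetric_config(tissue)
        asym = make_asymmetric_config(tissue)
        assert asym.get(4) == sym.get(4)

    def test_central_electrode_tilt_angle(self, tissue):
        cfg = make_asymmetric_config(tissue)
        d = np.asarray(cfg.get(5).direction)
        angle = np.degrees(np.arccos(-d[2]))
        assert angle == pytest.approx(25.0)

    def test_central_needle_pivots_at_entry_toward_electrode_2(self, tissue):
        sym = make_symmetric_config(tissue)
        cfg = make_asymmetric_config(tissue)
        assert cfg.get(5).entry_point == sym.get(5).entry_point
        # at the tumor mid-plane the deep half leans toward electrode 2
        p = cfg.get(5).point_at_z(0.0)
        toward2 = np.asarray(cfg.get(2).entry_point[:2]) - np.asarray(sym.get(5).entry_point[:2])
        assert np.dot(p[:2], toward2) > 0

    def test_identity_perturbation_equals_symmetric(self, tissue):
        sym = make_symmetric_config(tissue)
        nul = make_asymmetric_config(tissue, displacements_mm={1: 0.0, 2: 0.0, 3: 0.0},
                                     tilt_deg=0.0)
        assert nul.electrodes == sym.electrodes

    def test_distance_entry_path_consistent(self, tissue):
        cfg = make_asymmetric_config_from_distances(tissue)
        assert cfg.pair_distance(5, 1) == pytest.approx(1.22, abs=1e-9)
        assert cfg.pair_distance(5, 2) == pytest.approx(1.12, abs=1e-9)

    def test_rejects_displacement_past_center(self, tissue):
        with pytest.raises(ValueError, match="past the center"):
            make_asymmetric_config(tissue, displacements_mm={1: 20.0, 2: 0, 3: 0})


class TestInternalPreset:
    @pytest.mark.parametrize("n", [4, 5])
    def test_axes_inside_midplane_ellipse(self, tissue, n):
        cfg = make_internal_config(tissue, n_electrodes=n)
        a, b, _ = tissue.tumor_semiaxes
        for e in cfg:
            x, y = e.point_at_z(0.0)[:2]
            assert (x / a) ** 2 + (y / b) ** 2 < 1.0 + 1e-12

    def test_five_electrode_variant_has_central_needle(self, tissue):
        cfg = make_internal_config(tissue, n_electrodes=5)
        assert np.allclose(cfg.get(5).point_at_z(0.0)[:2], tissue.tumor_center[:2])
        assert len(cfg) == 5

    def test_margin_zero_places_axis_one_radius_inside_surface(self, tissue):
        # on-axis placement: surface distance along the principal axis is exact
        cfg = make_internal_config(tissue, n_electrodes=4, margin=0.0)
        a, b, _ = tissue.tumor_semiaxes
        x1 = cfg.get(1).point_at_z(0.0)[0]
        assert a - x1 == pytest.approx(cfg.get(1).radius * 0.1)
        y2 = cfg.get(2).point_at_z(0.0)[1]
        assert b - y2 == pytest.approx(cfg.get(2).radius * 0.1)

    def test_oversized_margin_rejected(self, tissue):
        with pytest.raises(ValueError, match="margin too large"):
            make_internal_config(tissue, margin=1.0)


class TestValidation:
    def test_duplicate_ids_rejected(self):
        e = NeedleElectrode(1, (0, 0, 1.5))
        with pytest.raises(ValueError, match="unique"):
            ElectrodeConfig((e, NeedleElectrode(1, (1, 0, 1.5))))

    def test_overlapping_axes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ElectrodeConfig((
                NeedleElectrode(1, (0, 0, 1.5)),
                NeedleElectrode(2, (0.05, 0, 1.5)),  # 0.5 mm apart, radii 0.6 mm
            ))

    def test_tumor_must_fit_in_box(self):
        with pytest.raises(ValueError, match="inside the box"):
            TissueModel(box_side=1.0)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            NeedleElectrode(1, (0, 0, 1.5), direction=(0, 0, -2.0))


@pytest.fixture(scope="module")
def grid(tissue):
    return rasterize(tissue, make_symmetric_config(tissue), spacing=0.1)


class TestRasterize:

    def test_labels_partition_grid(self, grid):
        valid = (grid.label == BACKGROUND) | (grid.label == TUMOR) | (grid.label >= ELECTRODE_BASE)
        assert valid.all()

    def test_every_electrode_rasterized(self, grid):
        assert grid.electrode_ids == (1, 2, 3, 4, 5)

    def test_background_voxel_far_from_tumor(self, grid, tissue):
        i, j, k = grid.nearest_index((4.0, 4.0, 4.0))
        assert grid.label[i, j, k] == BACKGROUND
        assert grid.baseline_sigma[i, j, k] == tissue.sigma_background0

    def test_tumor_voxel_near_center(self, grid, tissue):
        # central electrode occupies the exact center; probe just beside it
        i, j, k = grid.nearest_index((0.3, 0.0, 0.0))
        assert grid.label[i, j, k] == TUMOR
        assert grid.baseline_sigma[i, j, k] == tissue.sigma_tumor0

    def test_tumor_volume_close_to_analytic(self, tissue):
        grid = rasterize(tissue, None, spacing=0.05)
        assert grid.tumor_volume_cm3() == pytest.approx(tissue.tumor_volume_cm3, rel=0.02)

    def test_volume_converges_with_refinement(self, tissue):
        exact = tissue.tumor_volume_cm3
        err = [abs(rasterize(tissue, None, spacing=h).tumor_volume_cm3() - exact)
               for h in (0.2, 0.1)]
        assert err[1] <= err[0] / 2.0

    def test_missed_electrode_raises_by_name(self, tissue):
        # a needle entirely outside the box intersects no voxel centers
        cfg = ElectrodeConfig((NeedleElectrode(7, (20.0, 0, 1.5)),))
        with pytest.raises(ValueError, match="electrode 7"):
            rasterize(tissue, cfg, spacing=0.2)
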