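"""WMH classification and 3D shape morphometry against analytic oracles."""

import math

import numpy as np
import pytest

from neurophenoclust import wmh_shape as ws
from neurophenoclust.synthetic_data import make_lesion_phantom

from .oracles import exact_box_counts, flood_fill_components


def grid_with_ventricle_plane(distance_vox: int, shape=(20, 9, 9)):
    """Ventricle slab at x=0; one WMH voxel `distance_vox` voxels away."""
    vent = np.zeros(shape, dtype=bool)
    vent[0] = True
    wmh = np.zeros(shape, dtype=bool)
    wmh[distance_vox, 4, 4] = True
    return wmh, vent


class TestClassification:
    @pytest.mark.parametrize("dist_mm,expected", [
        (2.9, ws.CPWMH),
        (3.0, ws.CPWMH),   # boundary inclusive
        (3.1, ws.DWMH),
    ])
    def test_three_mm_threshold(self, dist_mm, expected):
        # spacing chosen so one voxel step equals the target distance
        wmh, vent = grid_with_ventricle_plane(1)
        cmap = ws.classify_wmh(wmh, vent, spacing=(dist_mm, 1.0, 1.0))
        assert cmap.lesion_class[1] == expected

    def test_anisotropic_spacing_honoured(self):
        # 1 slice away at 4 mm slice thickness is deep despite 1 voxel step
        shape = (9, 9, 9)
        vent = np.zeros(shape, dtype=bool)
        vent[:, :, 0] = True
        wmh = np.zeros(shape, dtype=bool)
        wmh[4, 4, 1] = True
        cmap = ws.classify_wmh(wmh, vent, spacing=(0.9, 0.9, 4.0))
        assert cmap.lesion_class[1] == ws.DWMH

    def test_confluent_lesion_class_by_any_voxel(self):
        wmh, vent = grid_with_ventricle_plane(2)
        wmh[2:15, 4, 4] = True  # one lesion spanning near and far voxels
        cmap = ws.classify_wmh(wmh, vent, spacing=(1.5, 1.0, 1.0))
        assert cmap.lesion_class[1] == ws.CPWMH
        assert (cmap.voxel_class[wmh] == 1).all()

    def test_majority_rule_differs_for_mostly_deep_lesion(self):
        wmh, vent = grid_with_ventricle_plane(2)
        wmh[2:15, 4, 4] = True
        cmap = ws.classify_wmh(wmh, vent, spacing=(1.5, 1.0, 1.0), rule="majority")
        assert cmap.lesion_class[1] == ws.DWMH

    def test_growing_ventricle_never_demotes_to_deep(self, rng):
        shape = (12, 12, 6)
        wmh = rng.uniform(size=shape) < 0.15
        vent = np.zeros(shape, dtype=bool)
        vent[0:2] = True
        bigger = vent.copy()
        bigger[0:4] = True
        a = ws.classify_wmh(wmh, vent, (1, 1, 2)).voxel_class
        b = ws.classify_wmh(wmh, bigger, (1, 1, 2)).voxel_class
        assert not ((a == 1) & (b == 2)).any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ws.classify_wmh(np.zeros((4, 4, 4), bool), np.zeros((5, 4, 4), bool),
                            (1, 1, 1))


class TestExtractLesions:
    def test_two_separated_balls(self):
        m = np.zeros((30, 12, 12), dtype=bool)
        m[2:8, 4:9, 4:9] = True
        m[20:26, 4:9, 4:9] = True
        assert len(ws.extract_lesions(m)) == 2

    def test_corner_touch_is_one_component(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        m[1, 1, 1] = True
        assert len(ws.extract_lesions(m)) == 1

    def test_empty_mask_gives_empty_list(self):
        assert ws.extract_lesions(np.zeros((3, 3, 3), bool)) == []

    def test_component_count_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = rng.uniform(size=(8, 8, 8)) < 0.2
            comps = ws.extract_lesions(m)
            oracle = flood_fill_components(m)
            assert len(comps) == len(oracle)
            got = {frozenset(map(tuple, np.argwhere(c))) for c in comps}
            assert got == {frozenset(c) for c in oracle}


class TestMeshMetrics:
    def test_ball_surface_area_within_5_percent(self, ball_phantom):
        mask, truth = ball_phantom
        m = ws.mesh_metrics(mask, (1, 1, 1))
        assert m["surface_area"] == pytest.approx(truth["surface_area_mm2"], rel=0.05)
        assert m["volume"] == truth["voxel_volume_mm3"]

    def test_convex_lesion_hull_close_to_mesh(self, ball_phantom):
        mask, _ = ball_phantom
        m = ws.mesh_metrics(mask, (1, 1, 1))
        assert m["hull_volume"] == pytest.approx(m["mesh_volume"], rel=0.02)
        assert m["hull_area"] <= m["surface_area"] * 1.02

    def test_dented_ball_hull_exceeds_volume(self):
        mask, _ = make_lesion_phantom("dented_ball", radius=10.0, dent_radius=6.0)
        m = ws.mesh_metrics(mask, (1, 1, 1))
        assert m["hull_volume"] > m["mesh_volume"] * 1.02

    def test_hull_volume_against_voxel_hull_oracle(self):
        """Hull volume agrees with an exhaustive voxelized hull on a small grid.

        The oracle rasterizes the convex hull of the voxel centers by an
        inside test (Delaunay membership) on every grid center and counts.
        """
        from scipy.spatial import Delaunay

        mask, _ = make_lesion_phantom("dented_ball", radius=10.0, dent_radius=6.0)
        m = ws.mesh_metrics(mask, (1, 1, 1))
        pts = np.argwhere(mask).astype(float)
        tri = Delaunay(pts)
        grid = np.array(list(np.ndindex(mask.shape)), dtype=float)
        inside = tri.find_simplex(grid) >= 0
        oracle_volume = float(inside.sum())  # 1 mm^3 per voxel center
        assert m["hull_volume"] == pytest.approx(oracle_volume, rel=0.10)

    def test_single_voxel_flagged_degenerate(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        res = ws.mesh_metrics(m, (1, 1, 1))
        assert res["degenerate"]
        assert res["surface_area"] == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ws.mesh_metrics(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestShapeFeatures:
    def test_ball_is_convex_and_round(self, ball_phantom):
        mask, _ = ball_phantom
        f = ws.shape_features(mask, (1, 1, 1))
        assert f["solidity"] == pytest.approx(1.0, abs=0.05)
        assert f["convexity"] == pytest.approx(1.0, abs=0.05)
        assert f["concavity_index"] == pytest.approx(0.0, abs=0.1)
        assert f["eccentricity"] < 0.1

    def test_prolate_ellipsoid_eccentricity(self):
        mask, truth = make_lesion_phantom("ellipsoid", semi_axes=(20, 5, 5))
        ecc = ws.eccentricity(mask, (1, 1, 1))
        assert ecc == pytest.approx(math.sqrt(1 - 25 / 400), abs=0.02)
        assert truth["eccentricity"] == pytest.approx(0.968, abs=0.001)

    def test_dented_ball_has_positive_concavity(self):
        mask, _ = make_lesion_phantom("dented_ball", radius=10.0, dent_radius=6.0)
        f = ws.shape_features(mask, (1, 1, 1))
        assert f["concavity_index"] > 0
        assert f["solidity"] < 1
        assert f["convexity"] < 1.02

    def test_rigid_rotation_and_translation_invariance(self):
        mask, _ = make_lesion_phantom("ellipsoid", semi_axes=(10, 5, 4))
        base = ws.shape_features(mask, (1, 1, 1))
        rotated = np.rot90(mask, k=1, axes=(0, 1))
        for variant in (rotated, np.pad(mask, 2)):
            f = ws.shape_features(variant, (1, 1, 1))
            for key in ("solidity", "convexity", "eccentricity"):
                assert f[key] == pytest.approx(base[key], abs=0.01), key

    def test_planar_lesion_uses_inplane_moments(self):
        m = np.zeros((9, 9, 3), dtype=bool)
        m[1:8, 1:8, 1] = True  # square plate: in-plane moments equal
        assert ws.eccentricity(m, (1, 1, 1)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("spacing,tol", [
        ((1.0, 1.0, 1.0), 0.005),
        ((0.9, 0.9, 4.0), 0.07),
        ((0.45, 0.45, 4.0), 0.07),
    ])
    def test_ball_convexity_accurate_across_resolutions(self, spacing, tol):
        """Solidity/convexity of a ball stay near 1 from isotropic to
        thick-slice acquisition grids."""
        mask, _ = make_lesion_phantom("ball", radius=10.0, spacing=spacing)
        f = ws.shape_features(mask, spacing)
        assert abs(1 - f["solidity"]) + abs(1 - f["convexity"]) < tol


class TestFractalDimension:
    def test_segment_dimension_one(self):
        mask, _ = make_lesion_phantom("segment", length=40)
        assert ws.fractal_dimension(mask) == pytest.approx(1.0, abs=0.15)

    def test_cube_boundary_dimension_two(self):
        cube = np.zeros((68, 68, 68), dtype=bool)
        cube[2:66, 2:66, 2:66] = True
        assert ws.fractal_dimension(cube) == pytest.approx(2.0, abs=0.15)

    def test_menger_matches_exact_box_count_oracle(self):
        mask, truth = make_lesion_phantom("menger_like", level=2)
        fd = ws.fractal_dimension(mask, scales=(1, 3, 9), boundary=False)
        assert fd == pytest.approx(math.log(20) / math.log(3), abs=0.2)
        counts = ws.box_counts(mask, (1, 3, 9))
        for eps in (1, 3, 9):
            assert counts[eps] == exact_box_counts(mask, eps)

    def test_box_counts_match_oracle_on_random_masks(self, rng):
        for _ in range(5):
            m = rng.uniform(size=(16, 16, 16)) < 0.1
            if not m.any():
                continue
            counts = ws.box_counts(m, (1, 2, 4))
            for eps in (1, 2, 4):
                assert counts[eps] == exact_box_counts(m, eps)

    def test_too_few_scales_flagged_nan(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True
        assert math.isnan(ws.fractal_dimension(m))


class TestAggregation:
    def make_lesion(self, cls, solidity):
        return ws.LesionShape(
            lesion_id=1, wmh_class=cls, n_voxels=10, volume=10.0,
            surface_area=30.0, hull_volume=10.0, hull_area=30.0,
            solidity=solidity, convexity=1.0, concavity_index=2.0 - 1.0 - solidity,
            eccentricity=0.5, fractal_dimension=float("nan"),
        )

    def test_single_lesion_identity(self):
        summary = ws.aggregate_patient([self.make_lesion(ws.CPWMH, 0.8)])
        assert summary.loc[ws.CPWMH, "solidity"] == pytest.approx(0.8)
        assert summary.loc[ws.CPWMH, "n_lesions"] == 1

    def test_mean_of_two_lesions(self):
        summary = ws.aggregate_patient([
            self.make_lesion(ws.CPWMH, 0.8), self.make_lesion(ws.CPWMH, 0.6),
        ])
        assert summary.loc[ws.CPWMH, "solidity"] == pytest.approx(0.7)

    def test_absent_deep_class_flagged_missing(self):
        summary = ws.aggregate_patient([self.make_lesion(ws.CPWMH, 0.8)])
        assert bool(summary.loc[ws.DWMH, "missing"])
        assert math.isnan(summary.loc[ws.DWMH, "solidity"])


class TestHeadPhantomShapes:
    def test_planted_lesions_classified_as_constructed(self, head_phantom):
        spec, seg, _, _ = head_phantom
        lesions = ws.lesion_shapes(seg.mask("wmh"), seg.mask("ventricles"),
                                   seg.spacing)
        classes = sorted(l.wmh_class for l in lesions)
        assert classes.count(ws.CPWMH) == 1  # the planted tangent lesion
        assert classes.count(ws.DWMH) == len(lesions) - 1
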