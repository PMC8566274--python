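import numpy as np
import pytest

import freept as fp

COARSE = dict(voxel_spacing=4.0)   # quick glands for structural tests


class TestGeneratePair:
    def test_deterministic_under_seed(self):
        a = fp.generate_pair(fp.SyntheticPairConfig(seed=3, **COARSE))
        b = fp.generate_pair(fp.SyntheticPairConfig(seed=3, **COARSE))
        np.testing.assert_array_equal(a[0].coords, b[0].coords)
        np.testing.assert_array_equal(a[1].coords, b[1].coords)

    def test_distinct_seeds_distinct_glands(self):
        a = fp.generate_pair(fp.SyntheticPairConfig(seed=1, **COARSE))
        b = fp.generate_pair(fp.SyntheticPairConfig(seed=2, **COARSE))
        assert a[0].coords.shape != b[0].coords.shape or \
            not np.array_equal(a[0].coords, b[0].coords)

    def test_ground_truth_self_consistency(self, small_pair):
        _, _, truth = small_pair
        lm = truth.landmark_pairs
        mapped = truth.transform(lm.source_centroids())
        np.testing.assert_allclose(mapped, lm.target_centroids(), atol=1e-9)

    def test_identity_config_overlaps(self):
        cfg = fp.SyntheticPairConfig(seed=5, deform_amplitude=0,
                                     rigid_rotation_range=0,
                                     rigid_translation_range=0, **COARSE)
        src, tgt, truth = fp.generate_pair(cfg)
        lm = truth.landmark_pairs
        d = np.linalg.norm(lm.source_centroids() - lm.target_centroids(), axis=1)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)
        # same region: bounding boxes coincide to within a voxel
        np.testing.assert_allclose(src.coords.min(0), tgt.coords.min(0), atol=4.0)
        np.testing.assert_allclose(src.coords.max(0), tgt.coords.max(0), atol=4.0)

    def test_pure_translation_moves_landmarks_exactly(self, monkeypatch):
        cfg = fp.SyntheticPairConfig(seed=6, deform_amplitude=0,
                                     rigid_rotation_range=0,
                                     rigid_translation_range=0, **COARSE)
        src, tgt, truth = fp.generate_pair(cfg)
        truth.translation = np.array([5.0, 0.0, 0.0])
        lm = truth.landmark_pairs
        moved = truth.transform(lm.source_centroids())
        np.testing.assert_allclose(moved, lm.source_centroids() + [5, 0, 0],
                                   atol=1e-9)

    def test_displacement_bounded(self, small_pair):
        src, _, truth = small_pair
        cfg = fp.SyntheticPairConfig(seed=7, voxel_spacing=4.0)
        disp = truth.displacement_field(src.coords)
        bound = cfg.deform_amplitude * cfg.deform_rbf_count
        assert np.linalg.norm(disp, axis=1).max() <= bound + 1e-9

    def test_inverse_transform_round_trip(self, small_pair):
        src, _, truth = small_pair
        pts = src.coords[:50]
        back = truth.inverse_transform(truth.transform(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_degenerate_config_errors(self):
        with pytest.raises(ValueError):
            fp.generate_pair(fp.SyntheticPairConfig(
                seed=0, semi_axes_range=(1.0, 1.5), voxel_spacing=4.0))


class TestSliceScenarios:
    def test_scenario_slice_counts(self):
        assert fp.SliceScenario.preset(1).n_slices == 3
        assert fp.SliceScenario.preset(3).n_slices == 2
        with pytest.raises(ValueError):
            fp.SliceScenario(scenario_id=1, n_slices=2, slab_thickness=1,
                             placement=(0.2, 0.8))

    def test_slices_subset_of_target(self, small_pair):
        _, tgt, _ = small_pair
        out = fp.extract_slices(tgt, fp.SliceScenario.preset(2, 4.0), seed=1)
        pool = {tuple(c) for c in tgt.coords}
        assert len(out) >= 1
        assert all(tuple(c) in pool for c in out.coords)

    def test_full_thickness_single_slab_returns_everything(self, small_pair):
        _, tgt, _ = small_pair
        extent = tgt.coords[:, 0].max() - tgt.coords[:, 0].min()
        scen = fp.SliceScenario(scenario_id=0, n_slices=1,
                                slab_thickness=extent,
                                placement=(0.5,), jitter=0.0)
        out = fp.extract_slices(tgt, scen, seed=0)
        assert len(out) == len(tgt)   # the slab covers the whole gland

    def test_symmetric_scenario1_centroid_near_center(self):
        # symmetric synthetic gland: evenly spread slabs stay centered
        grid = np.mgrid[0:21, 0:9, 0:9].reshape(3, -1).T.astype(float)
        gland = fp.PointSet(grid)
        scen = fp.SliceScenario(scenario_id=1, n_slices=3, slab_thickness=1.0,
                                placement=(0.25, 0.5, 0.75), jitter=0.0)
        slices = fp.extract_slices(gland, scen, seed=0)
        assert fp.slice_centroid_distance(gland, slices) < 1e-9

    def test_thin_target_errors(self):
        thin = fp.PointSet(np.random.default_rng(0).normal(size=(30, 3)) * [0.1, 10, 10])
        with pytest.raises(ValueError):
            fp.extract_slice_list(thin, fp.SliceScenario.preset(1, slab_thickness=5.0))
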