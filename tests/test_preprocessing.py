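import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import freept as fp

finite_cloud = st.integers(min_value=2, max_value=40).flatmap(
    lambda n: st.just(n)).map(
    lambda n: np.random.default_rng(n).normal(scale=30.0, size=(n, 3)))


class TestNormalize:
    def test_two_point_bounding_box(self):
        ps = fp.PointSet([[0, 0, 0], [2, 4, 8]])
        out, _ = fp.normalize_unit_cube(ps)
        np.testing.assert_allclose(sorted(map(tuple, out.coords)),
                                   [(-1, -1, -1), (1, 1, 1)])

    def test_idempotent_on_cube_corners(self):
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                            for z in (-1, 1)], float)
        out, params = fp.normalize_unit_cube(fp.PointSet(corners))
        np.testing.assert_allclose(out.coords, corners)
        np.testing.assert_allclose(params.scale, 1.0)

    @given(cloud=finite_cloud)
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, cloud):
        ps = fp.PointSet(cloud)
        normed, params = fp.normalize_unit_cube(ps)
        back = fp.denormalize(normed, params)
        np.testing.assert_allclose(back.coords, ps.coords, atol=1e-12)

    @given(cloud=finite_cloud)
    @settings(max_examples=30, deadline=None)
    def test_output_in_cube_and_attains_bounds(self, cloud):
        normed, _ = fp.normalize_unit_cube(fp.PointSet(cloud))
        assert normed.coords.min() >= -1 - 1e-12
        assert normed.coords.max() <= 1 + 1e-12
        for ax in range(3):
            assert np.isclose(normed.coords[:, ax].min(), -1)
            assert np.isclose(normed.coords[:, ax].max(), 1)

    def test_degenerate_axis_maps_to_zero(self):
        ps = fp.PointSet([[1, 0, 5], [1, 2, 9]])   # x constant
        out, params = fp.normalize_unit_cube(ps)
        np.testing.assert_allclose(out.coords[:, 0], 0.0)
        back = fp.denormalize(out, params)
        np.testing.assert_allclose(back.coords, ps.coords, atol=1e-12)


class TestSubsample:
    def test_n_equals_N_is_permutation(self, rng):
        ps = fp.PointSet(rng.normal(size=(20, 3)))
        out = fp.subsample(ps, 20, seed=3)
        assert sorted(map(tuple, out.coords)) == sorted(map(tuple, ps.coords))

    def test_deterministic_and_exact_cardinality(self, rng):
        ps = fp.PointSet(rng.normal(size=(50, 3)))
        a = fp.subsample(ps, 17, seed=9)
        b = fp.subsample(ps, 17, seed=9)
        assert len(a) == 17
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_subset_multiset_property(self, rng):
        ps = fp.PointSet(rng.normal(size=(200, 3)))
        out = fp.subsample(ps, 120, seed=1)
        pool = {tuple(c) for c in ps.coords}
        assert all(tuple(c) in pool for c in out.coords)
        # without replacement: no duplicates
        assert len({tuple(c) for c in out.coords}) == 120

    def test_with_replacement_when_oversampling(self):
        ps = fp.PointSet([[0, 0, 0], [1, 1, 1]])
        out = fp.subsample(ps, 5, seed=2)
        assert len(out) == 5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fp.subsample(fp.PointSet([[0, 0, 0]]), 0, seed=0)


class TestAugment:
    def test_zero_ranges_identity(self, rng):
        ps = fp.PointSet(rng.uniform(-1, 1, size=(30, 3)), space_tag="unit_cube")
        out, applied = fp.augment_source(
            ps, fp.AugmentParams(rotation_deg=0, translation=0,
                                 scale_min=1, scale_max=1, seed=0))
        np.testing.assert_allclose(out.coords, ps.coords, atol=1e-12)
        np.testing.assert_allclose(applied["rotation_matrix"], np.eye(3))

    def test_rotation_preserves_pairwise_distances(self, rng):
        ps = fp.PointSet(rng.uniform(-1, 1, size=(25, 3)), space_tag="unit_cube")
        out, _ = fp.augment_source(
            ps, fp.AugmentParams(rotation_deg=45, translation=0,
                                 scale_min=1, scale_max=1, seed=5))
        d0 = np.linalg.norm(ps.coords[:, None] - ps.coords[None], axis=2)
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_deterministic_under_seed(self, rng):
        ps = fp.PointSet(rng.uniform(-1, 1, size=(10, 3)), space_tag="unit_cube")
        ap = fp.AugmentParams(seed=77)
        out1, a1 = fp.augment_source(ps, ap)
        out2, a2 = fp.augment_source(ps, ap)
        np.testing.assert_array_equal(out1.coords, out2.coords)
        np.testing.assert_array_equal(a1["rotation_matrix"], a2["rotation_matrix"])

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_rotation_proper_orthogonal(self, seed):
        ps = fp.PointSet(np.random.default_rng(1).uniform(-1, 1, (5, 3)))
        _, applied = fp.augment_source(ps, fp.AugmentParams(seed=seed))
        R = applied["rotation_matrix"]
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)
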