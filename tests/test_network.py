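"""Architecture contracts of the displacement-prediction network."""

import numpy as np
import pytest

import freept as fp
from freept.autodiff import Tensor
from freept.fpt import encode_set, global_feature


@pytest.fixture(scope="module")
def toy_model():
    return fp.FPTParams.init(fp.ArchitectureConfig(
        K=16, U=(32, 16, 3), seed=11))


@pytest.fixture(scope="module")
def toy_sets(toy_model):
    r = np.random.default_rng(42)
    src = fp.PointSet(r.uniform(-1, 1, (40, 3)), space_tag="unit_cube")
    tgt = fp.PointSet(r.uniform(-1, 1, (55, 3)), space_tag="unit_cube")
    return src, tgt


class TestGlobalFeature:
    def test_permutation_invariance_exact(self, toy_model, toy_sets):
        src, tgt = toy_sets
        g1 = fp.extract_global_feature(toy_model, src, tgt)
        perm = np.random.default_rng(0).permutation(len(src))
        g2 = fp.extract_global_feature(
            toy_model, src.with_coords(src.coords[perm]), tgt)
        np.testing.assert_array_equal(g1.g, g2.g)

    def test_duplication_invariance_exact(self, toy_model, toy_sets):
        src, tgt = toy_sets
        g1 = fp.extract_global_feature(toy_model, src, tgt)
        doubled = src.with_coords(np.concatenate([src.coords, src.coords]))
        g2 = fp.extract_global_feature(toy_model, doubled, tgt)
        np.testing.assert_array_equal(g1.g, g2.g)

    def test_set_order_sensitivity(self, toy_model, toy_sets):
        src, tgt = toy_sets
        g = fp.extract_global_feature(toy_model, src, tgt)
        g_swap = fp.extract_global_feature(toy_model, tgt, src)
        np.testing.assert_array_equal(g_swap.g, g.swapped().g)
        assert np.abs(g_swap.g - g.g).max() > 0   # direction is encoded

    def test_different_cardinalities_allowed(self, toy_model, toy_sets):
        src, tgt = toy_sets
        small = src.with_coords(src.coords[:3])
        g = fp.extract_global_feature(toy_model, small, tgt)
        assert g.g.shape == (32,)

    def test_no_batch_normalization(self, toy_model, toy_sets):
        """No normalization layers exist, so a set's features cannot depend
        on what else is in the batch (the property batch-norm would break)."""
        assert not any("norm" in k.lower() or "bn" in k.lower()
                       for k in toy_model.params)
        src, tgt = toy_sets
        alone = encode_set(toy_model, Tensor(src.coords[None])).data[0]
        other = np.random.default_rng(9).uniform(-1, 1, src.coords.shape)
        batched = encode_set(
            toy_model, Tensor(np.stack([src.coords, other]))).data[0]
        np.testing.assert_array_equal(alone, batched)

    def test_unnormalized_input_warns(self, toy_model):
        big = fp.PointSet(np.array([[30.0, 0, 0], [0, 5.0, 0]]))
        with pytest.warns(UserWarning, match="unnormalized"):
            fp.extract_global_feature(toy_model, big, big)


class TestTransformPoints:
    def test_zero_final_layer_identity(self, toy_sets):
        model = fp.FPTParams.init(fp.ArchitectureConfig(K=16, U=(32, 16, 3), seed=1))
        model.params["trans.2.W"].data[:] = 0.0
        model.params["trans.2.b"].data[:] = 0.0
        src, tgt = toy_sets
        g = fp.extract_global_feature(model, src, tgt)
        out, d = fp.transform_points(model, g, src)
        np.testing.assert_array_equal(out.coords, src.coords)
        np.testing.assert_array_equal(d, 0.0)

    def test_hand_computed_affine_chain(self):
        """Tiny hand-set weights: the MLP must reproduce a manual forward pass."""
        model = fp.FPTParams.init(fp.ArchitectureConfig(K=2, U=(2, 3), seed=0))
        W0 = np.arange(14).reshape(7, 2) * 0.1          # input width 2K+3 = 7
        b0 = np.array([0.5, -0.2])
        W1 = np.array([[1.0, 0.0, 2.0], [0.0, -1.0, 1.0]])
        b1 = np.array([0.0, 0.1, -0.3])
        model.params["trans.0.W"].data[:] = W0
        model.params["trans.0.b"].data[:] = b0
        model.params["trans.1.W"].data[:] = W1
        model.params["trans.1.b"].data[:] = b1
        gvec = np.array([0.3, -0.4, 0.1, 0.2])
        pt = np.array([0.5, -0.5, 0.25])
        x = np.concatenate([gvec, pt])
        manual = np.maximum(x @ W0 + b0, 0.0) @ W1 + b1 + pt
        out, _ = fp.transform_points(
            model, fp.GlobalFeature(gvec, K=2), fp.PointSet(pt[None], space_tag="unit_cube"))
        np.testing.assert_allclose(out.coords[0], manual, atol=1e-12)

    def test_batched_equals_looped(self, toy_model, toy_sets):
        src, tgt = toy_sets
        g = fp.extract_global_feature(toy_model, src, tgt)
        batched, _ = fp.transform_points(toy_model, g, src)
        looped = fp.transform_points_looped(toy_model, g, src)
        assert np.abs(batched.coords - looped).max() <= 1e-6

    def test_feature_width_mismatch_errors(self, toy_model, toy_sets):
        src, _ = toy_sets
        with pytest.raises(ValueError, match="2K"):
            fp.transform_points(toy_model, fp.GlobalFeature(np.zeros(10), K=5), src)


class TestRegister:
    def test_zero_network_is_normalization_alignment(self, small_pair):
        src, tgt, _ = small_pair
        model = fp.FPTParams.init(fp.ArchitectureConfig(K=16, U=(16, 3), seed=2))
        model.params["trans.1.W"].data[:] = 0.0
        model.params["trans.1.b"].data[:] = 0.0
        res = fp.register(model, src, tgt)
        from freept.preprocessing import normalize_unit_cube
        _, src_np = normalize_unit_cube(src)
        _, tgt_np = normalize_unit_cube(tgt)
        expected = tgt_np.invert(src_np.apply(src.coords))
        np.testing.assert_allclose(res.transformed.coords, expected, atol=1e-9)

    def test_cardinality_decoupling(self, small_pair, toy_model):
        """Small network inputs can drive the transform of a larger cloud."""
        src, tgt, _ = small_pair
        dense = fp.PointSet(np.repeat(src.coords, 3, axis=0) +
                            np.random.default_rng(0).normal(0, 0.1, (3 * len(src), 3)))
        res = fp.register(toy_model, src, tgt, points_to_transform=dense,
                          n_input_points=32, seed=0)
        assert len(res.transformed) == len(dense)
        assert np.isfinite(res.transformed.coords).all()

    def test_checkpoint_round_trip(self, tmp_path, toy_model, small_pair):
        src, tgt, _ = small_pair
        path = str(tmp_path / "model.npz")
        fp.save_params(toy_model, path)
        loaded = fp.load_params(path)
        r1 = fp.register(toy_model, src, tgt, n_input_points=32, seed=5)
        r2 = fp.register(loaded, src, tgt, n_input_points=32, seed=5)
        np.testing.assert_allclose(r1.transformed.coords,
                                   r2.transformed.coords, atol=1e-6)
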