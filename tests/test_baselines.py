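import numpy as np
import pytest

import freept as fp
from freept.baselines import _procrustes, cpd_responsibilities


def rot_z(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0],
                     [0, 0, 1.0]])


@pytest.fixture()
def cloud50(rng):
    return fp.PointSet(rng.normal(scale=10.0, size=(50, 3)))


class TestICP:
    def test_identity_case(self, cloud50):
        tf, moved, hist = fp.icp_register(cloud50, cloud50)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-10)
        assert hist[0] < 1e-12

    def test_recovers_known_rigid_transform(self, cloud50):
        R, t = rot_z(30.0), np.array([5.0, 0.0, 0.0])
        target = cloud50.with_coords(cloud50.coords @ R.T + t)
        tf, moved, hist = fp.icp_register(cloud50, target)
        # independent oracle: closed-form Procrustes on TRUE correspondences
        oracle = _procrustes(cloud50.coords, target.coords)
        np.testing.assert_allclose(tf.rotation, oracle.rotation, atol=1e-8)
        np.testing.assert_allclose(tf.translation, oracle.translation, atol=1e-8)
        rms = np.sqrt(np.mean(np.sum((moved.coords - target.coords) ** 2, 1)))
        assert rms < 1e-8

    def test_history_monotone_non_increasing(self, rng):
        for trial in range(5):
            a = fp.PointSet(rng.normal(size=(60, 3)))
            b = fp.PointSet(rng.normal(size=(70, 3)))
            _, _, hist = fp.icp_register(a, b)
            assert all(h2 <= h1 + 1e-9 for h1, h2 in zip(hist, hist[1:]))

    def test_rotation_always_proper(self, rng):
        # near-planar cloud tempts the SVD into a reflection
        pts = rng.normal(size=(40, 3)) * [10, 10, 1e-3]
        tgt = fp.PointSet(-pts + rng.normal(scale=0.1, size=pts.shape))
        tf, _, _ = fp.icp_register(fp.PointSet(pts), tgt)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0, atol=1e-8)

    def test_collinear_falls_back_to_translation(self):
        line = np.stack([np.linspace(0, 10, 20)] * 3, axis=1)  # x=y=z line
        src = fp.PointSet(line)
        tgt = fp.PointSet(line + [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="translation-only"):
            tf, _, _ = fp.icp_register(src, tgt)
        np.testing.assert_allclose(tf.rotation, np.eye(3))

    def test_deterministic(self, cloud50, rng):
        tgt = fp.PointSet(rng.normal(scale=10.0, size=(55, 3)))
        r1 = fp.icp_register(cloud50, tgt)
        r2 = fp.icp_register(cloud50, tgt)
        np.testing.assert_array_equal(r1[1].coords, r2[1].coords)


class TestCPD:
    def test_identity_pair_displacements_vanish(self, rng):
        ps = fp.PointSet(rng.uniform(0, 10, size=(80, 3)))
        moved, hist = fp.cpd_register(ps, ps)
        assert np.linalg.norm(moved.coords - ps.coords, axis=1).max() < 1e-3
        assert len(hist) >= 1

    def test_small_translation_improves_chamfer(self, rng):
        src = fp.PointSet(rng.uniform(0, 10, size=(100, 3)))
        tgt = fp.PointSet(src.coords + [1.0, 0.0, 0.0])
        moved, _ = fp.cpd_register(src, tgt)
        assert fp.chamfer_distance_mm(moved, tgt) < fp.chamfer_distance_mm(src, tgt)

    def test_em_objective_non_increasing(self, rng):
        src = fp.PointSet(rng.normal(size=(60, 3)))
        tgt = fp.PointSet(rng.normal(size=(60, 3)) + 0.5)
        _, hist = fp.cpd_register(src, tgt, fp.CPDConfig(max_iter=60))
        assert all(h2 <= h1 + 1e-8 * max(1.0, abs(h1))
                   for h1, h2 in zip(hist, hist[1:]))

    def test_responsibility_normalization(self, rng):
        moved = rng.normal(size=(12, 3))
        x = rng.normal(size=(17, 3))
        P, _ = cpd_responsibilities(moved, x, sigma2=0.5, w=0.2)
        col = P.sum(axis=0)
        assert (col <= 1.0 + 1e-12).all()
        # posterior mass per target point: mixture mass + outlier mass = 1
        d2 = ((moved[:, None] - x[None]) ** 2).sum(-1)
        num = np.exp(-d2 / 1.0)
        c = (0.2 / 0.8) * (2 * np.pi * 0.5) ** 1.5 * 12 / 17
        outlier = c / (num.sum(axis=0) + c)
        np.testing.assert_allclose(col + outlier, 1.0, atol=1e-12)
        assert np.isclose(P.sum() + outlier.sum(), 17.0)

    def test_w_zero_has_no_outlier_mass(self, rng):
        P, _ = cpd_responsibilities(rng.normal(size=(5, 3)),
                                    rng.normal(size=(6, 3)), sigma2=1.0, w=0.0)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)

    def test_deterministic(self, rng):
        src = fp.PointSet(rng.normal(size=(40, 3)))
        tgt = fp.PointSet(rng.normal(size=(45, 3)))
        m1, h1 = fp.cpd_register(src, tgt)
        m2, h2 = fp.cpd_register(src, tgt)
        np.testing.assert_array_equal(m1.coords, m2.coords)
        assert h1 == h2

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            fp.CPDConfig(w=1.0)
        with pytest.raises(ValueError):
            fp.CPDConfig(beta=0.0)
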