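"""Training objectives for unsupervised point-set registration.

Two distance-based losses between the transformed source set A = {p~s'} and
the target set B = {p~t}, both differentiable through the autodiff core:

* two-way Chamfer loss — mean (over each set) of squared Euclidean
  nearest-neighbour distances, summed over both directions;
* GMM negative log-likelihood — the target points are scored under an
  isotropic Gaussian mixture whose centres are the transformed source
  points, plus a uniform outlier component of weight ``u``.

Both accept PointSets, numpy arrays or Tensors; they return a scalar
Tensor (use ``.data`` for the plain value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, logsumexp
from .pointset import PointSet

__all__ = ["GMMLossConfig", "chamfer_loss", "gmm_nll_loss"]

_D = 3  # spatial dimension


@dataclass
class GMMLossConfig:
    sigma2: float = 0.001   # isotropic covariance, normalized-space units^2
    u: float = 0.1          # uniform outlier weight in [0, 1]

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must lie in [0, 1]")


def _as_tensor(x) -> Tensor:
    if isinstance(x, PointSet):
        return Tensor(x.coords)
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != _D or arr.shape[0] == 0:
        raise ValueError(f"expected a non-empty (N, 3) point array, got {arr.shape}")
    return Tensor(arr)


def pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    """(Na, Nb) matrix of squared Euclidean distances, differentiable."""
    aa = a.square().sum(axis=1, keepdims=True)          # (Na, 1)
    bb = b.square().sum(axis=1, keepdims=True)          # (Nb, 1)
    cross = a @ b.swapaxes(0, 1)                        # (Na, Nb)
    d2 = aa - 2.0 * cross + bb.swapaxes(0, 1)
    return d2.relu()  # clamp tiny negatives from cancellation


def chamfer_loss(A, B) -> Tensor:
    """Two-way squared-distance Chamfer loss.

    (1/Nb) sum_b min_a ||b - a||^2  +  (1/Na) sum_a min_b ||b - a||^2.
    Symmetric in its arguments; zero iff the supports coincide.
    """
    a, b = _as_tensor(A), _as_tensor(B)
    d2 = pairwise_sq_dists(a, b)                        # (Na, Nb)
    return d2.min(axis=0).mean() + d2.min(axis=1).mean()


def gmm_nll_loss(A, B, cfg: GMMLossConfig | None = None) -> Tensor:
    """Negative log-likelihood of the targets under a source-centred GMM.

    A provides the Na Gaussian cluster centres (equal weights, isotropic
    covariance ``cfg.sigma2``); an extra uniform cluster of probability
    1/Nb, weighted by ``cfg.u``, absorbs outliers.  Evaluated with
    log-sum-exp stabilization.
    """
    cfg = cfg or GMMLossConfig()
    a, b = _as_tensor(A), _as_tensor(B)
    na, nb = a.shape[0], b.shape[0]

    if cfg.u == 1.0:  # pure uniform component: coordinates drop out
        return a.sum() * 0.0 + nb * np.log(nb)

    log_gauss_norm = (np.log((1.0 - cfg.u) / na)
                      - 0.5 * _D * np.log(2.0 * np.pi * cfg.sigma2))
    d2 = pairwise_sq_dists(a, b)                        # (Na, Nb)
    exponents = d2 * (-1.0 / (2.0 * cfg.sigma2))
    per_target = logsumexp(exponents.swapaxes(0, 1), axis=1) + log_gauss_norm  # (Nb,)

    if cfg.u > 0.0:
        uniform_col = Tensor(np.full((nb, 1), np.log(cfg.u / nb),
                                     dtype=per_target.data.dtype))
        stacked = concat([per_target.reshape(nb, 1), uniform_col], axis=1)
        per_target = logsumexp(stacked, axis=1)
    elif not np.isfinite(per_target.data).all():
        raise FloatingPointError(
            "GMM likelihood underflowed with u=0: every target point is far "
            "from all cluster centres; set u > 0 or increase sigma2")

    return -per_target.sum()
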