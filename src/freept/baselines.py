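"""Classical iterative registration baselines: rigid ICP and non-rigid CPD.

ICP alternates nearest-neighbour correspondence (k-d tree) with the
closed-form least-squares rigid update (SVD Procrustes, det +1 enforced),
starting from centroid alignment.  CPD is the Myronenko-Song non-rigid
formulation: an EM fit of a Gaussian mixture centred on the moving set,
with motion coherence imposed through a Gaussian kernel on the
displacement field.  Both are deterministic given their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pointset import PointSet

__all__ = ["RigidTransform", "CPDConfig", "icp_register", "cpd_register",
           "cpd_responsibilities"]


@dataclass
class RigidTransform:
    rotation: np.ndarray      # (3, 3), proper orthogonal
    translation: np.ndarray   # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation


def _procrustes(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of corresponded point lists."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    # collinear/degenerate clouds cannot pin down a rotation
    if np.linalg.matrix_rank(H, tol=1e-10 * max(1.0, abs(H).max())) < 2:
        warnings.warn("degenerate point configuration: translation-only ICP update")
        R = np.eye(3)
    else:
        U, _, Vt = np.linalg.svd(H)
        R = Vt.T @ U.T
        if np.linalg.det(R) < 0:              # reflection guard
            Vt[-1] *= -1.0
            R = Vt.T @ U.T
    return RigidTransform(rotation=R, translation=ct - R @ cs)


def icp_register(source: PointSet, target: PointSet, max_iter: int = 25,
                 tol: float = 1e-6) -> tuple[RigidTransform, PointSet, list]:
    """Rigid ICP with centroid-alignment initialization.

    Returns the absolute transform, the moved source set, and the
    per-iteration RMS correspondence distance (non-increasing).
    """
    src, tgt = source.coords, target.coords
    tree = cKDTree(tgt)
    tf = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    history: list[float] = []
    for _ in range(max_iter):
        moved = tf.apply(src)
        d, idx = tree.query(moved, k=1)
        rms = float(np.sqrt(np.mean(d ** 2)))
        history.append(rms)
        tf = _procrustes(src, tgt[idx])
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol:
            break
    moved = tf.apply(src)
    return tf, source.with_coords(moved), history


# ---------------------------------------------------------------------------
# coherent point drift


@dataclass
class CPDConfig:
    w: float = 0.0            # assumed outlier fraction
    max_iter: int = 250
    beta: float = 2.0         # Gaussian kernel width of the coherence prior
    lam: float = 2.0          # regularization weight
    tol: float = 1e-5

    def __post_init__(self):
        if not 0.0 <= self.w < 1.0:
            raise ValueError("w must lie in [0, 1)")
        if self.beta <= 0 or self.lam <= 0:
            raise ValueError("beta and lambda must be positive")


def cpd_responsibilities(moved: np.ndarray, x: np.ndarray, sigma2: float,
                         w: float) -> tuple[np.ndarray, float]:
    """E-step: posterior P (M x N) that target n was drawn from centre m,
    and the total negative log-likelihood of the mixture."""
    m, n = moved.shape[0], x.shape[0]
    d2 = ((moved[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    num = np.exp(-d2 / (2.0 * sigma2))
    c = 0.0
    if w > 0.0:
        c = (w / (1.0 - w)) * (2.0 * np.pi * sigma2) ** 1.5 * m / n
    denom = num.sum(axis=0) + c
    denom = np.where(denom > 0, denom, np.finfo(float).tiny)
    P = num / denom
    log_norm = (np.log(1.0 - w) - np.log(m) - 1.5 * np.log(2.0 * np.pi * sigma2))
    nll = -float(np.sum(np.log(denom)) + n * log_norm)
    return P, nll


def cpd_register(source: PointSet, target: PointSet,
                 cfg: CPDConfig | None = None) -> tuple[PointSet, list]:
    """Non-rigid CPD: move the source (GMM centres) onto the target.

    Both sets are standardized internally (zero mean, unit scale) and the
    result is mapped back.  History records the penalized EM objective
    (negative log-likelihood + coherence penalty), which is non-increasing
    up to the sigma^2 re-estimation.
    """
    cfg = cfg or CPDConfig()
    y0, x0 = source.coords, target.coords
    mu = np.concatenate([y0, x0]).mean(axis=0)
    scale = np.sqrt(((np.concatenate([y0, x0]) - mu) ** 2).sum(axis=1).mean())
    scale = scale if scale > 0 else 1.0
    Y = (y0 - mu) / scale
    X = (x0 - mu) / scale
    M, N = Y.shape[0], X.shape[0]

    G = np.exp(-((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
               / (2.0 * cfg.beta ** 2))
    W = np.zeros((M, 3))
    sigma2 = ((Y[:, None, :] - X[None, :, :]) ** 2).sum() / (3.0 * M * N)
    history: list[float] = []
    moved = Y.copy()
    for _ in range(cfg.max_iter):
        P, nll = cpd_responsibilities(moved, X, sigma2, cfg.w)
        objective = nll + 0.5 * cfg.lam * float(np.trace(W.T @ G @ W))
        history.append(objective)
        if len(history) >= 2 and abs(history[-2] - history[-1]) \
                < cfg.tol * max(1.0, abs(history[-1])):
            break
        p1 = P.sum(axis=1)                      # (M,)
        pt1 = P.sum(axis=0)                     # (N,)
        Np = p1.sum()
        A = G * p1[:, None] + cfg.lam * sigma2 * np.eye(M)
        B = P @ X - p1[:, None] * Y
        W = np.linalg.solve(A, B)
        moved = Y + G @ W
        xPx = float(np.sum(pt1 * np.sum(X * X, axis=1)))
        trPXT = float(np.sum((P @ X) * moved))
        tPt = float(np.sum(p1 * np.sum(moved * moved, axis=1)))
        sigma2 = (xPx - 2.0 * trPXT + tPt) / (3.0 * Np)
        if sigma2 < 10 * np.finfo(float).eps:   # converged onto the target
            break
    out = moved * scale + mu
    return source.with_coords(out), history
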