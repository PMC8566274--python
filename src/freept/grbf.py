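"""Parametric comparator: Gaussian radial-basis-function transformation head.

Shares the FPT global feature extractor, but instead of predicting a free
displacement per point, an MLP head maps the global feature g to Nc control
points and a 3 x Nc coefficient matrix alpha; each query point p is moved by

    p' = p + alpha . k(p),   k_c(p) = exp(-||p_c - p||^2 / (2 sigma^2)).

The resulting displacement field is a smooth spline by construction —
the deformation family is constrained, unlike the model-free head.
Control-point outputs pass through tanh so they stay inside the normalized
cube.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .fpt import (ArchitectureConfig, GlobalFeature, _linear,
                  extract_global_feature)
from .pointset import PointSet, RegistrationResult
from .preprocessing import normalize_unit_cube, subsample

__all__ = ["GRBFConfig", "GRBFParams", "grbf_transform", "grbf_register",
           "make_grbf_transform"]


@dataclass
class GRBFConfig:
    """Encoder sizes plus the RBF head's shape parameters."""

    feature: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    n_control_points: int = 27
    kernel_sigma: float = 1.0
    head_widths: tuple = (512, 256)

    def __post_init__(self):
        if self.n_control_points < 1:
            raise ValueError("need at least one control point")
        if self.kernel_sigma <= 0:
            raise ValueError("kernel sigma must be positive")

    @classmethod
    def desk(cls, seed: int = 0) -> "GRBFConfig":
        return cls(feature=ArchitectureConfig.desk(seed=seed),
                   head_widths=(128, 64))

    @property
    def K(self) -> int:
        return self.feature.K

    def to_dict(self) -> dict:
        return {"feature": self.feature.to_dict(),
                "n_control_points": self.n_control_points,
                "kernel_sigma": self.kernel_sigma,
                "head_widths": list(self.head_widths)}

    @classmethod
    def from_dict(cls, d: dict) -> "GRBFConfig":
        f = d["feature"]
        return cls(feature=ArchitectureConfig(K=f["K"], U=tuple(f["U"]),
                                              feature_tnet=f["feature_tnet"],
                                              seed=f["seed"]),
                   n_control_points=d["n_control_points"],
                   kernel_sigma=d["kernel_sigma"],
                   head_widths=tuple(d["head_widths"]))


@dataclass
class GRBFParams:
    config: GRBFConfig
    params: dict = field(default_factory=dict)

    @classmethod
    def init(cls, config: GRBFConfig) -> "GRBFParams":
        from .fpt import FPTParams
        feat = FPTParams.init(config.feature)
        store = {k: v for k, v in feat.params.items() if k.startswith("feat.")}
        rng = np.random.default_rng(config.feature.seed + 1)
        prev = 2 * config.K
        for i, w in enumerate(config.head_widths):
            store[f"head.{i}.W"], store[f"head.{i}.b"] = _linear(rng, prev, w)
            prev = w
        n_out = 6 * config.n_control_points      # Nc*3 control pts + Nc*3 coeffs
        store["head.out.W"], store["head.out.b"] = _linear(rng, prev, n_out)
        return cls(config=config, params=store)

    def tensors(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # the encoder forward passes expect an FPTParams-shaped object; this
    # store is a superset, so expose the same attributes.
    @property
    def feature_view(self):
        from .fpt import FPTParams
        return FPTParams(config=self.config.feature, params=self.params)


def predict_head(grbf: GRBFParams, g: Tensor) -> tuple[Tensor, Tensor]:
    """g (B, 2K) -> control points (B, Nc, 3), coefficients (B, 3, Nc)."""
    p = grbf.params
    h = g
    for i in range(len(grbf.config.head_widths)):
        h = (h @ p[f"head.{i}.W"] + p[f"head.{i}.b"]).relu()
    out = h @ p["head.out.W"] + p["head.out.b"]
    nc = grbf.config.n_control_points
    B = out.shape[0]
    control = out[:, :3 * nc].reshape(B, nc, 3).tanh()
    alpha = out[:, 3 * nc:].reshape(B, 3, nc)
    return control, alpha


def rbf_displace(control: Tensor, alpha: Tensor, pts: Tensor,
                 sigma: float) -> Tensor:
    """Batched spline displacement: (B, N, 3) from control/alpha tensors."""
    pp = pts.square().sum(axis=2, keepdims=True)              # (B, N, 1)
    cc = control.square().sum(axis=2, keepdims=True)          # (B, Nc, 1)
    cross = pts @ control.swapaxes(1, 2)                      # (B, N, Nc)
    d2 = (pp - 2.0 * cross + cc.swapaxes(1, 2)).relu()
    k = (d2 * (-1.0 / (2.0 * sigma ** 2))).exp()              # (B, N, Nc)
    return k @ alpha.swapaxes(1, 2)                           # (B, N, 3)


def grbf_forward(grbf: GRBFParams, g: Tensor, pts: Tensor) -> Tensor:
    """Displacements for (B, N, 3) normalized points conditioned on g."""
    control, alpha = predict_head(grbf, g)
    return rbf_displace(control, alpha, pts, grbf.config.kernel_sigma)


def grbf_transform(grbf: GRBFParams, g: GlobalFeature,
                   points: PointSet) -> tuple[PointSet, np.ndarray]:
    """Apply the predicted spline field to a normalized point-set."""
    if g.g.shape[0] != 2 * grbf.config.K:
        raise ValueError("global feature length does not match configured K")
    d = grbf_forward(grbf, Tensor(g.g[None]), Tensor(points.coords[None])).data[0]
    if not np.isfinite(d).all():
        raise FloatingPointError("G-RBF head produced non-finite displacements")
    return points.with_coords(points.coords + d), d


def make_grbf_transform(grbf: GRBFParams, source: PointSet, target: PointSet,
                        n_input_points: int | None = None, seed: int = 0):
    """mm-space transform from one pair, mirroring fpt.make_transform."""
    src_n, src_np = normalize_unit_cube(source)
    tgt_n, tgt_np = normalize_unit_cube(target)
    if n_input_points is not None:
        src_n = subsample(src_n, n_input_points, seed)
        tgt_n = subsample(tgt_n, n_input_points, seed + 1)
    g = extract_global_feature(grbf.feature_view, src_n, tgt_n)

    def apply(coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        pn = PointSet(src_np.apply(coords), space_tag="unit_cube")
        moved, _ = grbf_transform(grbf, g, pn)
        return tgt_np.invert(moved.coords)

    return apply


def grbf_register(grbf: GRBFParams, source: PointSet, target: PointSet,
                  points_to_transform: PointSet | None = None,
                  n_input_points: int | None = None,
                  seed: int = 0) -> RegistrationResult:
    t0 = time.perf_counter()
    pts = points_to_transform if points_to_transform is not None else source
    fn = make_grbf_transform(grbf, source, target,
                             n_input_points=n_input_points, seed=seed)
    moved = fn(pts.coords)
    dt = time.perf_counter() - t0
    return RegistrationResult(
        transformed=PointSet(moved, id=pts.id, space_tag="mm"),
        displacements=moved - pts.coords, method="grbf", seconds=dt,
        extras={"n_input_points": n_input_points})
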