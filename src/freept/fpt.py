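"""The registration network: global feature extraction + model-free
per-point displacement prediction.

A single weight-sharing encoder (a PointNet-style per-point MLP with
max-aggregation, WITHOUT batch normalization so that translational offsets
between the two sets survive into the features) maps each input set to a
K-vector.  Points are first lifted to homogeneous coordinates and multiplied
by a learned 4x4 transform so translations are representable; an optional
learned 64x64 feature transform follows the early shared layers.  The
source-then-target concatenation g = [gs; gt] is order sensitive — swapping
the sets reverses the registration direction.

The displacement head is an L-layer MLP shared across points: input
[g; p] of width 2K+3, ReLU on all but the last layer, 3 outputs added to
the point.  Because the weights are shared across points it is exactly a
width-1 convolution over the point axis; both realizations are provided.
"""

from __future__ import annotations

import io as _io
import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .pointset import PointSet, RegistrationResult
from .preprocessing import denormalize, normalize_unit_cube, subsample

__all__ = ["ArchitectureConfig", "GlobalFeature", "FPTParams",
           "extract_global_feature", "transform_points",
           "transform_points_looped", "register", "save_params", "load_params"]


@dataclass
class ArchitectureConfig:
    """Network sizes.  ``full_scale()`` is the GPU-class preset; ``desk()``
    is a CPU-friendly reduction used throughout the test suite and examples."""

    K: int = 1024                                   # per-set feature length
    U: tuple = (1024, 512, 256, 128, 64, 3)         # displacement MLP widths
    feature_tnet: bool = True                       # learned 64x64 feature transform
    seed: int = 0

    @property
    def L(self) -> int:
        return len(self.U)

    def __post_init__(self):
        self.U = tuple(int(u) for u in self.U)
        if self.U[-1] != 3:
            raise ValueError("the displacement MLP must end in 3 outputs")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "ArchitectureConfig":
        return cls(seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "ArchitectureConfig":
        return cls(K=128, U=(256, 128, 64, 32, 16, 3), seed=seed)

    def to_dict(self) -> dict:
        return {"K": self.K, "U": list(self.U),
                "feature_tnet": self.feature_tnet, "seed": self.seed}


@dataclass
class GlobalFeature:
    """g = [gs; gt]: source-then-target per-set features (length 2K)."""

    g: np.ndarray
    K: int

    def swapped(self) -> "GlobalFeature":
        return GlobalFeature(np.concatenate([self.g[self.K:], self.g[:self.K]]), self.K)


# ---------------------------------------------------------------------------
# parameter store

# encoder per-point widths follow the original PointNet scheme (64, 64),
# then (64, 128, K); T-net trunks are kept small and K-independent.
_TNET_POINT = (32, 64, 128)
_TNET_FC = (64,)


def _linear(rng, fan_in: int, fan_out: int,
            zero: bool = False, bias: np.ndarray | None = None):
    if zero:
        w = np.zeros((fan_in, fan_out))
    else:
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out) if bias is None else bias.astype(np.float64)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


def _build_tnet(rng, store: dict, prefix: str, d_in: int, d_out_side: int):
    """Shared-MLP + max-pool + FC regression head for a d_out x d_out transform.

    The head is zero-weight / identity-bias initialized so training starts
    from the identity transform.
    """
    widths = list(_TNET_POINT)
    prev = d_in
    for i, w in enumerate(widths):
        store[f"{prefix}.pt{i}.W"], store[f"{prefix}.pt{i}.b"] = _linear(rng, prev, w)
        prev = w
    for i, w in enumerate(_TNET_FC):
        store[f"{prefix}.fc{i}.W"], store[f"{prefix}.fc{i}.b"] = _linear(rng, prev, w)
        prev = w
    ident = np.eye(d_out_side).ravel()
    store[f"{prefix}.out.W"], store[f"{prefix}.out.b"] = _linear(
        rng, prev, d_out_side * d_out_side, zero=True, bias=ident)


@dataclass
class FPTParams:
    """All learnable weights; the twin encoder branches share this store."""

    config: ArchitectureConfig
    params: dict = field(default_factory=dict)

    @classmethod
    def init(cls, config: ArchitectureConfig) -> "FPTParams":
        rng = np.random.default_rng(config.seed)
        store: dict = {}
        _build_tnet(rng, store, "feat.tnet_in", 4, 4)
        prev = 3
        for i, w in enumerate((64, 64)):
            store[f"feat.mlp1.{i}.W"], store[f"feat.mlp1.{i}.b"] = _linear(rng, prev, w)
            prev = w
        if config.feature_tnet:
            _build_tnet(rng, store, "feat.tnet_feat", prev, prev)
        for i, w in enumerate((64, 128, config.K)):
            store[f"feat.mlp2.{i}.W"], store[f"feat.mlp2.{i}.b"] = _linear(rng, prev, w)
            prev = w
        prev = 2 * config.K + 3
        for i, w in enumerate(config.U):
            store[f"trans.{i}.W"], store[f"trans.{i}.b"] = _linear(rng, prev, w)
            prev = w
        return cls(config=config, params=store)

    def tensors(self) -> list:
        return [self.params[k] for k in sorted(self.params)]


# ---------------------------------------------------------------------------
# forward passes (Tensor in, Tensor out; batched over a leading axis)


def _apply_tnet(params: dict, prefix: str, x: Tensor) -> Tensor:
    """x: (B, N, d) -> (B, d_out, d_out) learned transforms."""
    h = x
    for i in range(len(_TNET_POINT)):
        h = (h @ params[f"{prefix}.pt{i}.W"] + params[f"{prefix}.pt{i}.b"]).relu()
    h = h.max(axis=1)                               # (B, width)
    for i in range(len(_TNET_FC)):
        h = (h @ params[f"{prefix}.fc{i}.W"] + params[f"{prefix}.fc{i}.b"]).relu()
    out = h @ params[f"{prefix}.out.W"] + params[f"{prefix}.out.b"]
    side = int(np.sqrt(out.shape[-1]))
    return out.reshape(out.shape[0], side, side)


def encode_set(fpt: FPTParams, pts: Tensor) -> Tensor:
    """One encoder branch: (B, N, 3) points -> (B, K) features.

    No batch normalization anywhere — translational differences between the
    branches must survive max-aggregation.
    """
    p = fpt.params
    B, N, _ = pts.shape
    ones = Tensor(np.ones((B, N, 1), dtype=pts.data.dtype))
    homo = concat([pts, ones], axis=2)              # (B, N, 4)
    T = _apply_tnet(p, "feat.tnet_in", homo)        # (B, 4, 4)
    h = (homo @ T)[:, :, :3]                        # homogeneous transform, drop w
    for i in range(2):
        h = (h @ p[f"feat.mlp1.{i}.W"] + p[f"feat.mlp1.{i}.b"]).relu()
    if fpt.config.feature_tnet:
        F = _apply_tnet(p, "feat.tnet_feat", h)     # (B, 64, 64)
        h = h @ F
    for i in range(3):
        h = (h @ p[f"feat.mlp2.{i}.W"] + p[f"feat.mlp2.{i}.b"]).relu()
    return h.max(axis=1)                            # (B, K)


def global_feature(fpt: FPTParams, src: Tensor, tgt: Tensor) -> Tensor:
    """(B, Ns, 3) x (B, Nt, 3) -> (B, 2K), source features first."""
    return concat([encode_set(fpt, src), encode_set(fpt, tgt)], axis=1)


def displace(fpt: FPTParams, g: Tensor, pts: Tensor) -> Tensor:
    """Displacement MLP over (B, N, 3) points conditioned on g (B, 2K)."""
    p = fpt.params
    B, N, _ = pts.shape
    g_tiled = g.reshape(B, 1, g.shape[-1]) + Tensor(np.zeros((B, N, 1), dtype=g.data.dtype))
    x = concat([g_tiled, pts], axis=2)              # (B, N, 2K+3)
    L = fpt.config.L
    for i in range(L):
        x = x @ p[f"trans.{i}.W"] + p[f"trans.{i}.b"]
        if i < L - 1:
            x = x.relu()
    return x                                        # (B, N, 3)


# ---------------------------------------------------------------------------
# public (numpy / PointSet) operations


def _check_normalized(ps: PointSet, what: str, tol: float = 1e-6):
    if np.abs(ps.coords).max() > 1.0 + tol:
        warnings.warn(f"{what} looks unnormalized (coords outside [-1, 1]); "
                      "the encoder expects unit-cube inputs", stacklevel=3)


def extract_global_feature(fpt: FPTParams, source: PointSet,
                           target: PointSet) -> GlobalFeature:
    """Set-order-sensitive global feature: permutation invariant within each
    set, but swapping source and target swaps the two halves of g."""
    _check_normalized(source, "source")
    _check_normalized(target, "target")
    g = global_feature(fpt, Tensor(source.coords[None]), Tensor(target.coords[None]))
    return GlobalFeature(g.data[0].copy(), K=fpt.config.K)


def transform_points(fpt: FPTParams, g: GlobalFeature,
                     points: PointSet) -> tuple[PointSet, np.ndarray]:
    """Move each point by its predicted displacement (normalized space)."""
    if g.g.shape[0] != 2 * fpt.config.K:
        raise ValueError(f"global feature length {g.g.shape[0]} does not match "
                         f"configured 2K = {2 * fpt.config.K}")
    d = displace(fpt, Tensor(g.g[None]), Tensor(points.coords[None])).data[0]
    return points.with_coords(points.coords + d), d


def transform_points_looped(fpt: FPTParams, g: GlobalFeature,
                            points: PointSet) -> np.ndarray:
    """Reference realization: the same MLP applied one point at a time.

    Mathematically identical to the batched (width-1 convolution) form in
    :func:`transform_points`; kept as an executable statement of that fact.
    """
    p = fpt.params
    L = fpt.config.L
    out = np.empty_like(points.coords)
    for i, pt in enumerate(points.coords):
        x = np.concatenate([g.g, pt])
        for l in range(L):
            x = x @ p[f"trans.{l}.W"].data + p[f"trans.{l}.b"].data
            if l < L - 1:
                x = np.maximum(x, 0.0)
        out[i] = pt + x
    return out


def make_transform(fpt: FPTParams, source: PointSet, target: PointSet,
                   n_input_points: int | None = None, seed: int = 0):
    """Build the mm-space point transform defined by one source/target pair.

    Network inputs may be subsampled to ``n_input_points``; the returned
    callable maps arbitrary mm-space points through source-normalization,
    the predicted displacement field, and target-denormalization.
    """
    src_n, src_np = normalize_unit_cube(source)
    tgt_n, tgt_np = normalize_unit_cube(target)
    if n_input_points is not None:
        src_n = subsample(src_n, n_input_points, seed)
        tgt_n = subsample(tgt_n, n_input_points, seed + 1)
    g = extract_global_feature(fpt, src_n, tgt_n)

    def apply(coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        pn = PointSet(src_np.apply(coords), space_tag="unit_cube")
        moved, _ = transform_points(fpt, g, pn)
        return tgt_np.invert(moved.coords)

    return apply


def register(fpt: FPTParams, source: PointSet, target: PointSet,
             points_to_transform: PointSet | None = None,
             n_input_points: int | None = None, seed: int = 0) -> RegistrationResult:
    """Register source onto target (mm in, mm out).

    ``points_to_transform`` defaults to the full source set but may be any
    point-set in the source frame (e.g. landmarks, or a denser cloud than
    the network inputs).
    """
    t0 = time.perf_counter()
    pts = points_to_transform if points_to_transform is not None else source
    fn = make_transform(fpt, source, target,
                        n_input_points=n_input_points, seed=seed)
    moved = fn(pts.coords)
    dt = time.perf_counter() - t0
    return RegistrationResult(
        transformed=PointSet(moved, id=pts.id, space_tag="mm"),
        displacements=moved - pts.coords, method="fpt", seconds=dt,
        extras={"n_input_points": n_input_points})


# ---------------------------------------------------------------------------
# checkpointing


def save_params(obj, path: str) -> None:
    """Single-file .npz checkpoint with a JSON architecture header."""
    arrays = {k: v.data for k, v in obj.params.items()}
    header = {"class": type(obj).__name__, "config": obj.config.to_dict()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_params(path: str):
    from .grbf import GRBFConfig, GRBFParams  # local import to avoid a cycle
    with np.load(path) as zf:
        header = json.loads(bytes(zf["__header__"]).decode())
        arrays = {k: zf[k] for k in zf.files if k != "__header__"}
    if header["class"] == "FPTParams":
        cfg = ArchitectureConfig(K=header["config"]["K"],
                                 U=tuple(header["config"]["U"]),
                                 feature_tnet=header["config"]["feature_tnet"],
                                 seed=header["config"]["seed"])
        obj = FPTParams(config=cfg)
    elif header["class"] == "GRBFParams":
        obj = GRBFParams(config=GRBFConfig.from_dict(header["config"]))
    else:
        raise ValueError(f"unknown checkpoint class {header['class']!r}")
    obj.params = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    return obj
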