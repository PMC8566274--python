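"""Unsupervised end-to-end training and experiment drivers.

Training minimizes the configured point-set distance (Chamfer or GMM
negative log-likelihood) between the transformed source and the target over
a cohort of pairs, with on-the-fly per-step normalization, shuffling,
subsampling to a fixed cardinality, and source augmentation.  In the
partial-data protocols the network's target INPUT is the slice-extracted
subset (normalized by its own bounding box, as it would be at inference)
while the loss is computed against the FULL target mapped into that same
frame — stronger supervision than the partial observation alone.

The full-scale preset (2000 epochs, lr 1e-5, K=1024) is retained for
completeness; the desk preset is sized so a full train/evaluate cycle runs
in minutes on one CPU core.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import fpt as fpt_mod
from . import grbf as grbf_mod
from .autodiff import Adam, Tensor
from .baselines import CPDConfig, cpd_register, icp_register
from .fpt import ArchitectureConfig, FPTParams
from .grbf import GRBFConfig, GRBFParams
from .losses import GMMLossConfig, chamfer_loss, gmm_nll_loss
from .metrics import MetricsReport, chamfer_distance_mm, hausdorff_mm, tre_mm
from .pointset import LandmarkSet, PointSet
from .preprocessing import AugmentParams, augment_source, normalize_unit_cube, subsample
from .synthetic import SliceScenario, extract_slices

__all__ = ["TrainConfig", "RunLog", "train", "evaluate", "aggregate",
           "run_partial_experiment", "split_cohort", "disjoint_subsets"]


@dataclass
class TrainConfig:
    loss: str = "chamfer"            # "chamfer" | "gmm"
    epochs: int = 2000
    lr: float = 1e-5
    batch_size: int = 8              # the GMM loss default is 2
    n_points: int = 1024
    scenario: str = "full"           # "full" | "1" | "2" | "3"
    seed: int = 0
    test_fraction: float = 0.3
    model: str = "fpt"               # "fpt" | "grbf"
    slab_thickness: float = 2.5      # mm, partial-data slab width
    augment: AugmentParams = field(default_factory=AugmentParams)
    gmm: GMMLossConfig = field(default_factory=GMMLossConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.loss not in ("chamfer", "gmm"):
            raise ValueError("loss must be 'chamfer' or 'gmm'")
        if str(self.scenario) not in ("full", "1", "2", "3"):
            raise ValueError("scenario must be full, 1, 2 or 3")
        self.scenario = str(self.scenario)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "TrainConfig":
        """CPU-scale study conditions: small cohort, small network."""
        kw.setdefault("epochs", 150)
        kw.setdefault("lr", 1e-3)
        kw.setdefault("n_points", 256)
        return cls(seed=seed, **kw)


@dataclass
class RunLog:
    epoch_losses: list = field(default_factory=list)
    seconds: float = 0.0
    config: dict = field(default_factory=dict)


def _init_model(cfg: TrainConfig, arch=None):
    if cfg.model == "fpt":
        arch = arch or (ArchitectureConfig.desk(seed=cfg.seed)
                        if cfg.n_points <= 512 else ArchitectureConfig(seed=cfg.seed))
        return FPTParams.init(arch)
    arch = arch or (GRBFConfig.desk(seed=cfg.seed)
                    if cfg.n_points <= 512 else GRBFConfig())
    return GRBFParams.init(arch)


def _feature_view(model):
    return model.feature_view if isinstance(model, GRBFParams) else model


def _forward_displacements(model, g: Tensor, pts: Tensor) -> Tensor:
    if isinstance(model, GRBFParams):
        return grbf_mod.grbf_forward(model, g, pts)
    return fpt_mod.displace(model, g, pts)


def _prepare_pair(source: PointSet, target: PointSet, cfg: TrainConfig,
                  pair_seed: int):
    """Normalize once per pair; returns (src_n, net_tgt_n, loss_tgt_n)."""
    src_n, _ = normalize_unit_cube(source)
    if cfg.scenario == "full":
        tgt_n, _ = normalize_unit_cube(target)
        return src_n.coords, tgt_n.coords, tgt_n.coords
    scen = SliceScenario.preset(int(cfg.scenario), slab_thickness=cfg.slab_thickness)
    slices = extract_slices(target, scen, seed=pair_seed)
    _, slice_np = normalize_unit_cube(slices)
    # network sees the partial set in its own frame; the loss sees the full
    # target mapped into that SAME frame so supervision stays consistent
    return (src_n.coords, slice_np.apply(slices.coords),
            slice_np.apply(target.coords))


def _draw(coords: np.ndarray, n: int, rng) -> np.ndarray:
    """Raw-array uniform subsample (with replacement only when n > N)."""
    idx = rng.choice(coords.shape[0], size=n, replace=n > coords.shape[0])
    return coords[idx]


def _augment_coords(coords: np.ndarray, ap: AugmentParams, rng) -> np.ndarray:
    """Raw-array counterpart of preprocessing.augment_source (same model)."""
    from .preprocessing import _rotation_matrix
    angles = rng.uniform(-ap.rotation_deg, ap.rotation_deg, size=3)
    shift = rng.uniform(-ap.translation, ap.translation, size=3)
    scale = rng.uniform(ap.scale_min, ap.scale_max)
    R = _rotation_matrix(angles).astype(coords.dtype)
    c = coords.mean(axis=0)
    return ((coords - c) @ R.T * coords.dtype.type(scale) + c
            + shift.astype(coords.dtype))


def train(cfg: TrainConfig, dataset: list, arch=None):
    """Fit an FPT or G-RBF model on (source, target[, truth]) pairs.

    Deterministic under ``cfg.seed``.  Returns (params, RunLog).
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    model = _init_model(cfg, arch)
    if cfg.epochs == 0:
        return model, RunLog(config={"note": "epochs=0, initialized only"})

    rng = np.random.default_rng(cfg.seed)
    prepared = [_prepare_pair(p[0], p[1], cfg, int(rng.integers(2 ** 31)))
                for p in dataset]
    # single precision is ample for SGD and roughly halves step time
    prepared = [tuple(c.astype(np.float32) for c in rec) for rec in prepared]
    for p in model.tensors():
        p.data = p.data.astype(np.float32)
    opt = Adam(model.tensors(), lr=cfg.lr)
    loss_cfg = cfg.gmm
    log = RunLog(config={"loss": cfg.loss, "epochs": cfg.epochs, "lr": cfg.lr,
                         "n_points": cfg.n_points, "scenario": cfg.scenario,
                         "model": cfg.model, "seed": cfg.seed})
    t0 = time.perf_counter()
    snapshot = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            srcs, tgts, loss_tgts = [], [], []
            for bi in batch:
                src_c, net_tgt_c, loss_tgt_c = prepared[bi]
                s = _draw(src_c, cfg.n_points, rng)
                t = _draw(net_tgt_c, cfg.n_points, rng)
                lt = _draw(loss_tgt_c, cfg.n_points, rng)
                s = _augment_coords(s, cfg.augment, rng)
                srcs.append(s)
                tgts.append(t)
                loss_tgts.append(lt)
            src_b = Tensor(np.stack(srcs))
            tgt_b = Tensor(np.stack(tgts))
            g = fpt_mod.global_feature(_feature_view(model), src_b, tgt_b)
            moved = src_b + _forward_displacements(model, g, src_b)
            total = None
            for b in range(len(batch)):
                if cfg.loss == "chamfer":
                    li = chamfer_loss(moved[b], loss_tgts[b])
                else:
                    li = gmm_nll_loss(moved[b], loss_tgts[b], loss_cfg)
                total = li if total is None else total + li
            total = total / float(len(batch))
            if not np.isfinite(total.data):
                if snapshot is not None:
                    for k, v in snapshot.items():
                        model.params[k].data = v
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; restored last-good "
                    "parameters")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
        log.epoch_losses.append(float(np.mean(epoch_losses)))
        snapshot = {k: v.data.copy() for k, v in model.params.items()}
    log.seconds = time.perf_counter() - t0
    return model, log


# ---------------------------------------------------------------------------
# cohort handling


def split_cohort(pairs: list, test_fraction: float = 0.3, seed: int = 0,
                 subject_ids: list | None = None):
    """Train/test split; any subject with multiple pairs goes to training."""
    rng = np.random.default_rng(seed)
    n = len(pairs)
    idx = np.arange(n)
    forced_train = set()
    if subject_ids is not None:
        counts = pd.Series(subject_ids).value_counts()
        multi = set(counts[counts > 1].index)
        forced_train = {i for i in idx if subject_ids[i] in multi}
    free = [i for i in idx if i not in forced_train]
    rng.shuffle(free)
    n_test = max(1, int(round(test_fraction * n)))
    n_test = min(n_test, len(free))
    test = sorted(free[:n_test])
    train_idx = sorted(set(idx) - set(test))
    return [pairs[i] for i in train_idx], [pairs[i] for i in test]


def disjoint_subsets(ps: PointSet, n_subsets: int, size: int,
                     seed: int = 0) -> list[PointSet]:
    """Pairwise-disjoint random subsets (grouped-registration protocol)."""
    if n_subsets * size > len(ps):
        raise ValueError("not enough points for disjoint subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ps))
    return [ps.with_coords(ps.coords[perm[i * size:(i + 1) * size]])
            for i in range(n_subsets)]


# ---------------------------------------------------------------------------
# evaluation


def _transform_for_method(method: str, model, source: PointSet,
                          observed_target: PointSet, n_points, seed: int):
    """Return a mm-space callable mapping source-frame points to the target
    frame for one case."""
    if method == "fpt":
        return fpt_mod.make_transform(model, source, observed_target,
                                      n_input_points=n_points, seed=seed)
    if method == "grbf":
        return grbf_mod.make_grbf_transform(model, source, observed_target,
                                            n_input_points=n_points, seed=seed)
    if method == "icp":
        src_in = subsample(source, n_points, seed) if n_points else source
        tf, _, _ = icp_register(src_in, observed_target)
        return lambda c: tf.apply(np.atleast_2d(c))
    if method == "cpd":
        src_in = subsample(source, n_points, seed) if n_points else source
        moved, _ = cpd_register(src_in, observed_target)
        # extend the fitted displacement field to arbitrary points by
        # nearest-fitted-point displacement lookup
        from scipy.spatial import cKDTree
        tree = cKDTree(src_in.coords)
        disp = moved.coords - src_in.coords

        def apply(c):
            c = np.atleast_2d(c)
            _, idx = tree.query(c, k=1)
            return c + disp[idx]

        return apply
    if method == "unregistered":
        return lambda c: np.atleast_2d(np.asarray(c, dtype=np.float64))
    raise ValueError(f"unknown method {method!r}")


def evaluate(model, test_pairs: list, methods=("fpt",), n_points: int | None = 256,
             scenario: str = "full", slab_thickness: float = 2.5,
             seed: int = 0) -> list[MetricsReport]:
    """Register each held-out pair with each method and measure mm metrics.

    ``test_pairs`` entries are (source, target, truth) with truth carrying
    landmark pairs (may be None: TRE is then reported as NaN).  Cloud
    metrics compare the transformed source against the FULL target; in a
    partial scenario the methods only see the slice-extracted target.
    """
    reports = []
    rng = np.random.default_rng(seed)
    for case_idx, pair in enumerate(test_pairs):
        source, target = pair[0], pair[1]
        truth = pair[2] if len(pair) > 2 else None
        case_seed = int(rng.integers(2 ** 31))
        if scenario == "full":
            observed = target
        else:
            scen = SliceScenario.preset(int(scenario), slab_thickness=slab_thickness)
            observed = extract_slices(target, scen, seed=case_seed)
        cloud = subsample(source, n_points, case_seed) if n_points else source
        for method in methods:
            t0 = time.perf_counter()
            fn = _transform_for_method(method, model, source, observed,
                                       n_points, case_seed)
            moved_cloud = fn(cloud.coords)
            dt = time.perf_counter() - t0
            rep = MetricsReport(
                case_id=source.id or f"case{case_idx}", method=method,
                scenario=scenario, n_points=n_points or len(source),
                chamfer_mm=chamfer_distance_mm(moved_cloud, target.coords),
                hausdorff_mm=hausdorff_mm(moved_cloud, target.coords),
                seconds=dt)
            if truth is not None and truth.landmark_pairs is not None:
                moved_lm = truth.landmark_pairs.map_source(fn)
                rep.tre_mm, rep.per_landmark_mm = tre_mm(moved_lm,
                                                         return_per_pair=True)
            reports.append(rep)
    return reports


def aggregate(reports: list) -> pd.DataFrame:
    """Mean +/- std per method/scenario, Tables-style."""
    df = pd.DataFrame([asdict(r) for r in reports])
    df = df.drop(columns=["per_landmark_mm"])
    return (df.groupby(["scenario", "method"])
              [["chamfer_mm", "hausdorff_mm", "tre_mm", "seconds"]]
              .agg(["mean", "std"]))


def run_partial_experiment(cfg: TrainConfig, cohort: list,
                           scenarios=("1", "2", "3"),
                           methods=("fpt", "icp", "cpd"),
                           arch=None) -> pd.DataFrame:
    """Per-scenario training of the network methods plus untrained baseline
    evaluation on slice inputs; returns the aggregated comparison table."""
    train_pairs, test_pairs = split_cohort(cohort, cfg.test_fraction, cfg.seed)
    all_reports = []
    for scen in scenarios:
        scen = str(scen)
        net_methods = [m for m in methods if m in ("fpt", "grbf")]
        base_methods = [m for m in methods if m not in ("fpt", "grbf")]
        if scen == "full":
            scen_cfg = cfg
        else:
            kw = {k: v for k, v in asdict(cfg).items()
                  if k not in ("augment", "gmm", "scenario")}
            scen_cfg = TrainConfig(scenario=scen, **kw)
            scen_cfg.augment, scen_cfg.gmm = cfg.augment, cfg.gmm
        model = None
        if net_methods:
            model, _ = train(scen_cfg, train_pairs, arch=arch)
            all_reports += evaluate(model, test_pairs, methods=net_methods,
                                    n_points=cfg.n_points, scenario=scen,
                                    slab_thickness=cfg.slab_thickness,
                                    seed=cfg.seed)
        if base_methods:
            all_reports += evaluate(model, test_pairs, methods=base_methods,
                                    n_points=cfg.n_points, scenario=scen,
                                    slab_thickness=cfg.slab_thickness,
                                    seed=cfg.seed)
    return aggregate(all_reports)
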