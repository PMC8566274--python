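"""Synthetic paired gland-like point-sets with known ground truth.

Real MR/TRUS prostate cohorts are not redistributable, so this module
produces a statistical stand-in: a bumpy-ellipsoid "gland" volume is grid
sampled into a source point-set; the target is the same volume pushed
through a smooth Gaussian-RBF displacement field plus a rigid perturbation
and then re-grid-sampled in the deformed frame, so source and target share
no point-to-point correspondence (as independent segmentations would not).
Interior landmark pairs carry the exact ground-truth mapping.

Partial-data "slice" extraction mimics acquiring only two or three parallel
ultrasound slices of the gland: scenario 1 is evenly spread, scenario 2 is
biased toward one lateral side, scenario 3 is two closely spaced slices with
poor coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pointset import LandmarkSet, PointSet
from .preprocessing import _rotation_matrix

__all__ = ["SyntheticPairConfig", "GroundTruth", "SliceScenario",
           "generate_pair", "extract_slices", "extract_slice_list"]

# lateral (slicing-axis) slab centers as fractions of the gland extent.
# Chosen so that BOTH descriptor orderings hold simultaneously:
# slice centroid distance 1 < 2 < 3 and slice span 1 > 2 > 3.
_SCENARIO_FRACTIONS = {
    1: (0.10, 0.50, 0.90),
    2: (0.40, 0.65, 0.90),
    3: (0.64, 0.76),
}


@dataclass
class SyntheticPairConfig:
    """Generation parameters (mm unless noted).

    Defaults emulate a prostate-scale gland (~40-50 mm across) with an
    intraoperative perturbation large enough that unregistered landmark
    errors are in the tens of millimetres.
    """

    semi_axes_range: tuple = (18.0, 25.0)
    bump_count: int = 4
    bump_amplitude: float = 2.0
    rigid_rotation_range: float = 20.0     # degrees, per axis
    rigid_translation_range: float = 20.0  # mm, per axis
    deform_rbf_count: int = 6
    deform_amplitude: float = 3.0          # mm, max |alpha_i|
    deform_lengthscale: float = 15.0       # mm
    n_landmarks: int = 8
    voxel_spacing: float = 2.5             # mm
    seed: int = 0

    def __post_init__(self):
        if min(self.semi_axes_range) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.bump_amplitude < 0 or self.deform_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.deform_lengthscale <= 0:
            raise ValueError("lengthscale must be positive")
        if self.n_landmarks < 0:
            raise ValueError("n_landmarks must be >= 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")


@dataclass
class GroundTruth:
    """Exact generative transform: y -> R (y + rbf(y)) + t."""

    rotation_deg: np.ndarray         # (3,) x,y,z Euler angles
    translation: np.ndarray          # (3,) mm
    deform: list                     # of (center (3,), coefficient (3,), lengthscale)
    landmark_pairs: LandmarkSet | None = None
    rotation_matrix: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.rotation_matrix is None:
            self.rotation_matrix = _rotation_matrix(np.asarray(self.rotation_deg))

    def displacement_field(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        disp = np.zeros_like(pts)
        for center, coeff, ls in self.deform:
            w = np.exp(-np.sum((pts - center) ** 2, axis=1) / (2.0 * ls ** 2))
            disp += w[:, None] * coeff
        return disp

    def transform(self, pts: np.ndarray) -> np.ndarray:
        """Apply the exact non-rigid + rigid ground-truth map."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        return (pts + self.displacement_field(pts)) @ self.rotation_matrix.T + self.translation

    def inverse_transform(self, pts: np.ndarray, n_iter: int = 40) -> np.ndarray:
        """Fixed-point inversion (valid while the field is a contraction)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        base = (pts - self.translation) @ self.rotation_matrix
        y = base.copy()
        for _ in range(n_iter):
            y = base - self.displacement_field(y)
        return y


@dataclass
class SliceScenario:
    """Which parallel slabs of the target to keep (partial-data protocols)."""

    scenario_id: int
    n_slices: int
    slab_thickness: float            # mm
    placement: tuple                 # slab centers, fractions of lateral extent
    jitter: float = 0.02             # per-slab fractional placement noise

    @classmethod
    def preset(cls, scenario_id: int, slab_thickness: float = 2.5) -> "SliceScenario":
        if scenario_id not in _SCENARIO_FRACTIONS:
            raise ValueError("scenario_id must be 1, 2 or 3")
        frac = _SCENARIO_FRACTIONS[scenario_id]
        return cls(scenario_id=scenario_id, n_slices=len(frac),
                   slab_thickness=slab_thickness, placement=frac)

    def __post_init__(self):
        if self.n_slices != len(self.placement):
            raise ValueError("n_slices must match placement length")
        if self.scenario_id == 1 and self.n_slices != 3:
            raise ValueError("scenario 1 uses three slices")
        if self.scenario_id in (2, 3) and self.n_slices not in (2, 3):
            raise ValueError("scenarios 2-3 use two or three slices")
        # scenario_id 0 is a free-form custom scenario: any n_slices >= 1
        if self.n_slices < 1:
            raise ValueError("need at least one slice")


# ---------------------------------------------------------------------------
# gland shape


def _inside_gland(pts: np.ndarray, semi_axes: np.ndarray,
                  bump_dirs: np.ndarray, bump_coeffs: np.ndarray) -> np.ndarray:
    """Implicit bumpy-ellipsoid membership test.

    The base ellipsoid radius is modulated by smooth directional bumps so
    glands are organ-like rather than perfectly symmetric.
    """
    u = pts / semi_axes
    r = np.linalg.norm(u, axis=1)
    safe_r = np.where(r > 0, r, 1.0)
    direction = u / safe_r[:, None]
    radius = np.ones(len(pts))
    if len(bump_coeffs):
        # von-Mises-like lobes on the unit sphere, width ~0.3
        dots = direction @ bump_dirs.T           # (N, n_bumps)
        radius = radius + (bump_coeffs[None, :] * np.exp((dots - 1.0) / 0.3)).sum(axis=1)
    return r <= radius


def _grid_points(lo: np.ndarray, hi: np.ndarray, spacing: float) -> np.ndarray:
    axes = [np.arange(lo[d], hi[d] + spacing / 2, spacing) for d in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def generate_pair(config: SyntheticPairConfig
                  ) -> tuple[PointSet, PointSet, GroundTruth]:
    """Generate one (source, target, ground-truth) triple.

    Deterministic under ``config.seed``; identical configs give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)

    a_lo, a_hi = config.semi_axes_range
    semi_axes = rng.uniform(a_lo, a_hi, size=3)
    bump_dirs = rng.normal(size=(config.bump_count, 3))
    if config.bump_count:
        bump_dirs /= np.linalg.norm(bump_dirs, axis=1, keepdims=True)
    rel_amp = config.bump_amplitude / semi_axes.mean()
    bump_coeffs = rng.uniform(-rel_amp, rel_amp, size=config.bump_count)

    margin = 1.0 + 2.0 * rel_amp
    lo = -semi_axes * margin
    hi = semi_axes * margin
    grid = _grid_points(lo, hi, config.voxel_spacing)
    inside = _inside_gland(grid, semi_axes, bump_dirs, bump_coeffs)
    src_coords = grid[inside]
    if src_coords.shape[0] < 8:
        raise ValueError("degenerate config: gland volume too small for the "
                         "requested voxel spacing")

    # smooth non-rigid field: Gaussian RBFs centered inside the gland
    centers, coeffs = [], []
    while len(centers) < config.deform_rbf_count:
        cand = rng.uniform(-0.8, 0.8, size=3) * semi_axes
        if _inside_gland(cand[None], semi_axes, bump_dirs, bump_coeffs)[0]:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mag = rng.uniform(0.5, 1.0) * config.deform_amplitude
            centers.append(cand)
            coeffs.append(mag * direction)
    deform = [(c, a, config.deform_lengthscale) for c, a in zip(centers, coeffs)]

    angles = rng.uniform(-config.rigid_rotation_range, config.rigid_rotation_range, size=3)
    trans = rng.uniform(-config.rigid_translation_range, config.rigid_translation_range, size=3)
    truth = GroundTruth(rotation_deg=angles, translation=trans, deform=deform)

    # target: re-grid-sample the deformed volume so correspondence is broken
    fwd_corners = truth.transform(_grid_points(lo, hi, (hi - lo).max() / 2.0))
    pad = config.deform_amplitude * config.deform_rbf_count + config.voxel_spacing
    t_lo = fwd_corners.min(axis=0) - pad
    t_hi = fwd_corners.max(axis=0) + pad
    t_grid = _grid_points(t_lo, t_hi, config.voxel_spacing)
    back = truth.inverse_transform(t_grid)
    t_inside = _inside_gland(back, semi_axes, bump_dirs, bump_coeffs)
    tgt_coords = t_grid[t_inside]
    if tgt_coords.shape[0] < 8:
        raise ValueError("degenerate config: deformed gland vanished")

    # interior landmarks and their exact images
    if config.n_landmarks > 0:
        interior = src_coords[
            np.linalg.norm(src_coords / semi_axes, axis=1) <= 0.75]
        pool = interior if len(interior) >= config.n_landmarks else src_coords
        pick = rng.choice(len(pool), size=min(config.n_landmarks, len(pool)),
                          replace=False)
        lm_src = pool[pick]
        lm_tgt = truth.transform(lm_src)
        truth.landmark_pairs = LandmarkSet(
            [(s[None], t[None], f"lm{i}") for i, (s, t) in enumerate(zip(lm_src, lm_tgt))])

    tag = f"case{config.seed}"
    source = PointSet(src_coords, id=f"{tag}_source", space_tag="mm")
    target = PointSet(tgt_coords, id=f"{tag}_target", space_tag="mm")
    return source, target, truth


# ---------------------------------------------------------------------------
# partial-data slice extraction


def _slab_masks(target: PointSet, scenario: SliceScenario,
                rng: np.random.Generator, axis: int = 0) -> list[np.ndarray]:
    x = target.coords[:, axis]
    lo, hi = x.min(), x.max()
    extent = hi - lo
    if extent < scenario.n_slices * scenario.slab_thickness:
        raise ValueError("target too thin for the requested slices")
    fractions = np.asarray(scenario.placement, dtype=np.float64)
    if rng.random() < 0.5:                      # skew left or right at random
        fractions = 1.0 - fractions
    fractions = fractions + rng.uniform(-scenario.jitter, scenario.jitter,
                                        size=len(fractions))
    masks = []
    for f in np.clip(fractions, 0.0, 1.0):
        center = lo + f * extent
        masks.append(np.abs(x - center) <= scenario.slab_thickness / 2.0)
    return masks


def extract_slice_list(target: PointSet, scenario: SliceScenario, seed: int = 0,
                       axis: int = 0) -> list[PointSet]:
    """Per-slab point-sets (used by the slice-span descriptor)."""
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        masks = _slab_masks(target, scenario, rng, axis=axis)
        if all(m.any() for m in masks):
            return [target.with_coords(target.coords[m]) for m in masks]
    raise ValueError("a slice slab contained no points after one retry")


def extract_slices(target: PointSet, scenario: SliceScenario, seed: int = 0,
                   axis: int = 0) -> PointSet:
    """Union of the scenario's slabs, as a single partial point-set."""
    slabs = extract_slice_list(target, scenario, seed=seed, axis=axis)
    coords = np.concatenate([s.coords for s in slabs], axis=0)
    out = target.with_coords(coords)
    out.id = f"{target.id}_scn{scenario.scenario_id}"
    return out
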