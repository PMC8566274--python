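"""Per-sample normalization, fixed-cardinality subsampling, augmentation.

Each point-set is scaled independently to the cube [-1, 1]^3 by an affine
map of its own bounding box; this implicit coarse pre-alignment is part of
the method.  Training augmentation applies a random rotation (about each
axis in turn), displacement and mild scaling to the normalized source set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .pointset import PointSet

__all__ = ["NormParams", "AugmentParams", "normalize_unit_cube", "denormalize",
           "subsample", "augment_source"]


@dataclass
class NormParams:
    """Invertible per-axis affine map mm -> [-1, 1] (x_norm = (x - offset) * scale)."""

    scale: np.ndarray      # (3,), 1/mm
    offset: np.ndarray     # (3,), mm (maps to cube center 0)
    source_tag: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.offset) * self.scale

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return coords / self.scale + self.offset


@dataclass
class AugmentParams:
    """Ranges for on-the-fly source augmentation, in normalized units."""

    rotation_deg: float = 45.0
    translation: float = 1.0
    scale_min: float = 0.9
    scale_max: float = 1.1
    seed: int = 0


def normalize_unit_cube(ps: PointSet) -> tuple[PointSet, NormParams]:
    """Affinely map each axis's [min, max] onto [-1, 1].

    A degenerate axis (max == min) maps to 0 with unit scale.
    """
    lo = ps.coords.min(axis=0)
    hi = ps.coords.max(axis=0)
    span = hi - lo
    scale = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 1.0)
    offset = np.where(span > 0, (lo + hi) / 2.0, lo)
    np_ = NormParams(scale=scale, offset=offset, source_tag=ps.id)
    return ps.with_coords(np_.apply(ps.coords), space_tag="unit_cube"), np_


def denormalize(ps: PointSet, params: NormParams) -> PointSet:
    return ps.with_coords(params.invert(ps.coords), space_tag="mm")


def subsample(ps: PointSet, n: int, seed: int) -> PointSet:
    """Draw n points uniformly: without replacement if n <= N, else with."""
    if n <= 0:
        raise ValueError("subsample size must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ps), size=n, replace=n > len(ps))
    return ps.with_coords(ps.coords[idx])


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    # intrinsic order: rotate about x, then y, then z
    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


def augment_source(ps: PointSet, ap: AugmentParams) -> tuple[PointSet, dict]:
    """Random rotation / displacement / scaling of a normalized point-set.

    Rotation and scaling are applied about the set centroid; the sampled
    transform is returned for logging.  Deterministic under ``ap.seed``.
    """
    rng = np.random.default_rng(ap.seed)
    angles = rng.uniform(-ap.rotation_deg, ap.rotation_deg, size=3)
    shift = rng.uniform(-ap.translation, ap.translation, size=3)
    scale = rng.uniform(ap.scale_min, ap.scale_max)
    R = _rotation_matrix(angles)
    c = ps.centroid()
    coords = (ps.coords - c) @ R.T * scale + c + shift
    applied = {"rotation_deg": angles, "rotation_matrix": R,
               "translation": shift, "scale": scale}
    return ps.with_coords(coords), applied
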