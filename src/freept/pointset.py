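"""Core containers: point-sets, voxel masks, landmark pairs, results.

A :class:`PointSet` stores an N x 3 coordinate array.  Storage order is kept
stable for reproducibility, but every algorithm in this package treats the
set as unordered — no operation may depend on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["PointSet", "VoxelMask", "LandmarkSet", "RegistrationResult"]


@dataclass
class PointSet:
    """An unordered set of 3-D points.

    Parameters
    ----------
    coords : (N, 3) float array, N >= 1, all finite.
    id : free-text label used in reports.
    space_tag : ``"mm"`` for physical coordinates, ``"unit_cube"`` after
        per-sample normalization to [-1, 1]^3.
    """

    coords: np.ndarray
    id: str = ""
    space_tag: str = "mm"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("a PointSet needs at least one point")
        if not np.isfinite(self.coords).all():
            raise ValueError("all coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, space_tag: Optional[str] = None) -> "PointSet":
        return PointSet(coords, id=self.id,
                        space_tag=self.space_tag if space_tag is None else space_tag)


@dataclass
class VoxelMask:
    """Binary segmentation on an isotropic voxel grid.

    ``origin`` is the physical (mm) position of the CENTER of voxel (0,0,0);
    voxel (i,j,k) is centered at ``origin + spacing * (i,j,k)``.
    """

    grid: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)


@dataclass
class LandmarkSet:
    """Paired anatomical landmarks for target-registration-error evaluation.

    Each pair holds one or more source points and one or more target points
    (a small structure on each side); error is measured between the two
    per-pair centroids.
    """

    pairs: list  # of (source_points (Ms,3), target_points (Mt,3), label)

    def __post_init__(self):
        clean = []
        for src, tgt, label in self.pairs:
            src = np.atleast_2d(np.asarray(src, dtype=np.float64))
            tgt = np.atleast_2d(np.asarray(tgt, dtype=np.float64))
            if src.size == 0 or tgt.size == 0:
                raise ValueError(f"landmark pair {label!r} is empty on one side")
            clean.append((src, tgt, str(label)))
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)

    def source_centroids(self) -> np.ndarray:
        return np.array([s.mean(axis=0) for s, _, _ in self.pairs])

    def target_centroids(self) -> np.ndarray:
        return np.array([t.mean(axis=0) for _, t, _ in self.pairs])

    def map_source(self, fn: Callable[[np.ndarray], np.ndarray]) -> "LandmarkSet":
        """Apply a point transform to every source-side landmark point."""
        return LandmarkSet([(fn(s), t, lab) for s, t, lab in self.pairs])


@dataclass
class RegistrationResult:
    """Output of one registration: moved points plus bookkeeping."""

    transformed: PointSet
    displacements: np.ndarray          # (N, 3), in the output (mm) frame
    method: str = ""
    seconds: float = 0.0
    extras: dict = field(default_factory=dict)
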