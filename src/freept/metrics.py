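"""Evaluation metrics (mm scale) and partial-data slice descriptors.

The evaluation Chamfer distance here is the NON-squared two-way mean
nearest-neighbour distance, so values are in millimetres and directly
comparable to gland dimensions; the squared form in :mod:`freept.losses`
is the training objective.  Nearest neighbours come from a k-d tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pointset import LandmarkSet, PointSet

__all__ = ["MetricsReport", "chamfer_distance_mm", "hausdorff_mm", "tre_mm",
           "slice_centroid_distance", "slice_span"]


@dataclass
class MetricsReport:
    """Per-case metric values for one method/scenario combination."""

    case_id: str = ""
    method: str = ""
    scenario: str = "full"
    n_points: int = 0
    chamfer_mm: float = np.nan
    hausdorff_mm: float = np.nan
    tre_mm: float = np.nan
    per_landmark_mm: list = field(default_factory=list)
    seconds: float = np.nan


def _coords(x) -> np.ndarray:
    arr = x.coords if isinstance(x, PointSet) else np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 3) point array")
    return arr


def _directed_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point of a to its nearest neighbour in b."""
    d, _ = cKDTree(b).query(a, k=1)
    return d


def chamfer_distance_mm(A, B) -> float:
    """Two-way mean Euclidean nearest-neighbour distance, averaged over the
    two directions.  Zero iff the supports coincide."""
    a, b = _coords(A), _coords(B)
    return float(0.5 * (_directed_nn(a, b).mean() + _directed_nn(b, a).mean()))


def hausdorff_mm(A, B) -> float:
    """Symmetric Hausdorff distance: worst-case nearest-neighbour distance."""
    a, b = _coords(A), _coords(B)
    return float(max(_directed_nn(a, b).max(), _directed_nn(b, a).max()))


def tre_mm(registered_landmarks: LandmarkSet,
           return_per_pair: bool = False):
    """Target registration error for one case.

    Source-side landmark points must already be transformed by the
    registration under test.  Per pair, the error is the distance between
    the source and target landmark centroids; the case TRE is the
    root-mean-square of the per-pair errors.
    """
    if len(registered_landmarks) == 0:
        raise ValueError("TRE needs at least one landmark pair")
    d = np.linalg.norm(registered_landmarks.source_centroids()
                       - registered_landmarks.target_centroids(), axis=1)
    rms = float(np.sqrt(np.mean(d ** 2)))
    return (rms, d.tolist()) if return_per_pair else rms


def slice_centroid_distance(prostate, slices) -> float:
    """Distance between the gland centroid and the centroid of the selected
    slice points — how off-centre the acquired slices sit."""
    cp = _coords(prostate).mean(axis=0)
    cs = _coords(slices).mean(axis=0)
    return float(np.linalg.norm(cp - cs))


def slice_span(prostate, slice_list, rms: bool = False) -> float:
    """Mean squared distance between the gland centroid and each individual
    slice centroid — how spread out the slices are across the gland.

    As defined this is a squared (mm^2) quantity; ``rms=True`` returns its
    square root for unit-consistent (mm) reporting.
    """
    if len(slice_list) == 0:
        raise ValueError("slice_span needs at least one slice")
    cp = _coords(prostate).mean(axis=0)
    sq = [float(np.sum((cp - _coords(s).mean(axis=0)) ** 2)) for s in slice_list]
    val = float(np.mean(sq))
    return float(np.sqrt(val)) if rms else val
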