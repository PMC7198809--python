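"""Thresholding and cluster extraction on the discriminative weight map.

The averaged weight volume is thresholded per sign: positive voxels survive
at >= ``fraction`` of the positive maximum, negative voxels at <=
``fraction`` of the negative minimum. Thresholding each sign against its own
extremum keeps small-but-consistent clusters of one sign from being wiped
out by a large opposite-sign peak. Surviving voxels are partitioned into
connected components (26-connectivity by default, the common convention in
neuroimaging cluster reports) and components of at least ``min_size`` voxels
are reported with their size, signed peak weight and peak coordinate —
positive clusters are regions where the patient group's FA is lower than
the controls', negative clusters the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volumes import ScalarVolume

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ClusterRecord:
    """One suprathreshold cluster of the weight map."""

    cluster_id: int
    sign: str  # "positive" | "negative"
    size: int
    peak_weight: float
    peak_coordinate: tuple[int, int, int]
    peak_world: tuple[float, float, float] | None = None


def threshold_map(weights: ScalarVolume, fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Per-sign thresholding at a fraction of each sign's extremum.

    Returns ``(positive_mask, negative_mask)``. On an all-zero (or one-sign)
    map the corresponding mask is empty; that is a valid result, not an
    error.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    w = weights.values
    finite = np.isfinite(w)
    w = np.where(finite, w, 0.0)
    pos_max = w.max(initial=0.0)
    neg_min = w.min(initial=0.0)
    positive = w >= fraction * pos_max if pos_max > 0 else np.zeros(w.shape, dtype=bool)
    negative = w <= fraction * neg_min if neg_min < 0 else np.zeros(w.shape, dtype=bool)
    return positive, negative


def connected_clusters(mask: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Partition true voxels into maximal connected components.

    Returns one ``(size, 3)`` coordinate array per component, components
    ordered by descending size with ties broken by the first voxel in scan
    order; within a component voxels are listed in scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise GeometryError("cluster extraction needs a 3D mask")
    if connectivity not in _STRUCTURES:
        raise ParameterError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labeled == lab)  # scan order
        clusters.append(coords)
    clusters.sort(key=lambda c: (-len(c), tuple(c[0])))
    return clusters


def cluster_table(
    weights: ScalarVolume,
    fraction: float = 0.10,
    min_size: int = 20,
    connectivity: int = 26,
) -> list[ClusterRecord]:
    """Threshold the map, extract clusters and report them, largest peaks first.

    Clusters of ``min_size`` voxels or more are kept (inclusive). Within
    each sign, records are sorted by descending absolute peak weight;
    positive-sign records precede negative-sign ones.
    """
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    pos_mask, neg_mask = threshold_map(weights, fraction)
    w = weights.values
    records: list[ClusterRecord] = []
    for sign, mask in (("positive", pos_mask), ("negative", neg_mask)):
        sign_records = []
        for coords in connected_clusters(mask, connectivity):
            if len(coords) < min_size:
                continue
            vals = w[tuple(coords.T)]
            peak_idx = int(np.argmax(np.abs(vals)))  # first-in-scan-order tie-break
            peak = tuple(int(c) for c in coords[peak_idx])
            world = None
            if weights.affine is not None:
                xyz = weights.affine @ np.array([*peak, 1.0])
                world = tuple(float(v) for v in xyz[:3])
            sign_records.append(
                ClusterRecord(
                    cluster_id=0,
                    sign=sign,
                    size=int(len(coords)),
                    peak_weight=float(vals[peak_idx]),
                    peak_coordinate=peak,
                    peak_world=world,
                )
            )
        sign_records.sort(key=lambda r: (-abs(r.peak_weight), r.peak_coordinate))
        records.extend(sign_records)
    return [
        ClusterRecord(
            cluster_id=i + 1,
            sign=r.sign,
            size=r.size,
            peak_weight=r.peak_weight,
            peak_coordinate=r.peak_coordinate,
            peak_world=r.peak_world,
        )
        for i, r in enumerate(records)
    ]
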