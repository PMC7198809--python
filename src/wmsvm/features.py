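"""Analysis mask and volume <-> feature-matrix conversion.

Voxel-wise classification treats every in-mask voxel as one feature. The
mask fixes both the feature dimensionality m and the feature <-> voxel
correspondence; its index map enumerates in-mask voxels in C scan order
(ascending coordinates, last axis fastest), which is stable across runs and
platforms and is the tie-break order used by the feature ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .errors import DimensionError, GeometryError
from .volumes import ScalarVolume

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CohortDataset


@dataclass(frozen=True)
class BinaryMask:
    """Analysis mask plus the ordered list of in-mask voxel coordinates.

    ``index_map[q]`` is the voxel coordinate of feature q; it enumerates
    exactly the true voxels of ``mask`` in C scan order.
    """

    mask: np.ndarray
    index_map: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise GeometryError("mask must be 3D")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "index_map", np.asarray(self.index_map, dtype=np.intp))
        if len(self.index_map) != int(mask.sum()):
            raise GeometryError("index_map does not enumerate the mask")

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "BinaryMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, index_map=np.argwhere(mask))

    @property
    def n_voxels(self) -> int:
        """Feature dimensionality m."""
        return len(self.index_map)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FeatureMatrix:
    """n x m matrix of masked voxel values, one row per subject.

    Column q corresponds to ``mask.index_map[q]`` for every subject.
    """

    X: np.ndarray
    subject_ids: tuple[str, ...]
    mask: BinaryMask

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise DimensionError("feature matrix must be 2D")
        if X.shape != (len(self.subject_ids), self.mask.n_voxels):
            raise DimensionError(
                f"feature matrix shape {X.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.mask.n_voxels} voxels"
            )
        if not np.isfinite(X).all():
            raise DimensionError("feature matrix contains non-finite values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))


def build_mask(volumes: Sequence[ScalarVolume], fa_threshold: float = 0.2) -> BinaryMask:
    """Threshold the across-subject mean map to define the analysis mask.

    A voxel enters the mask when its mean value over subjects exceeds
    ``fa_threshold``; with FA maps and the default 0.2 this is the usual
    white-matter analysis mask. ``fa_threshold = -1`` yields a whole-grid
    mask. An empty mask is an error.
    """
    if len(volumes) == 0:
        raise GeometryError("need at least one volume to build a mask")
    first = volumes[0]
    for vol in volumes[1:]:
        if not first.same_grid(vol):
            raise GeometryError("volumes are not on a common grid")
    mean_map = np.mean([vol.values for vol in volumes], axis=0)
    mask = mean_map > fa_threshold
    if not mask.any():
        raise GeometryError(f"threshold {fa_threshold} leaves no voxels in the mask")
    return BinaryMask.from_array(mask)


def volumes_to_matrix(dataset: "CohortDataset", mask: BinaryMask) -> FeatureMatrix:
    """Extract each subject's in-mask voxel values as one row of an n x m matrix."""
    rows = []
    for vol in dataset.volumes:
        if vol.shape != mask.shape:
            raise GeometryError(f"volume grid {vol.shape} does not match mask grid {mask.shape}")
        # boolean indexing scans in C order, matching index_map
        rows.append(vol.values[mask.mask])
    return FeatureMatrix(X=np.stack(rows), subject_ids=tuple(dataset.subject_ids), mask=mask)


def matrix_to_volume(
    vector: np.ndarray,
    mask: BinaryMask,
    fill: float = 0.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> ScalarVolume:
    """Back-project a length-m feature vector into a volume.

    In-mask voxels receive the vector values in index-map order; out-of-mask
    voxels receive ``fill`` (NaN is allowed and marks them for map writers).
    """
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (mask.n_voxels,):
        raise DimensionError(
            f"vector length {vector.shape} does not match mask with m={mask.n_voxels}"
        )
    values = np.full(mask.shape, float(fill), dtype=np.float64)
    values[mask.mask] = vector
    return ScalarVolume(values, voxel_size=voxel_size, affine=affine)
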