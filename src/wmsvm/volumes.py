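"""Registered scalar volumes and spatial smoothing.

A :class:`ScalarVolume` is one subject's 3D diffusion-metric map (typically
fractional anisotropy, dimensionless in [0, 1]) on a common template grid.
Spatial preprocessing upstream of this package (tensor fitting, non-linear
registration) is assumed done; the only spatial operation implemented here is
the isotropic Gaussian smoothing conventionally applied to registered FA maps
before voxel-wise analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ScalarVolume:
    """One subject's registered 3D scalar map with grid geometry.

    Parameters
    ----------
    values
        3D array of voxel values (FA-like maps lie in [0, 1]).
    voxel_size
        Physical voxel edge lengths in mm, one per axis.
    affine
        Optional 4x4 voxel-to-world matrix. When absent, reports stay in
        0-based voxel coordinates.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={values.ndim}")
        if np.isinf(values).any():
            raise GeometryError("volume contains infinite values")
        object.__setattr__(self, "values", values)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise GeometryError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)
        if self.affine is not None:
            aff = np.asarray(self.affine, dtype=np.float64)
            if aff.shape != (4, 4):
                raise GeometryError("affine must be a 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and self.voxel_size == other.voxel_size


def fwhm_to_sigma_voxels(fwhm: float, voxel_size: tuple[float, float, float]) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxel units for an isotropic FWHM in mm."""
    return tuple(fwhm / (v * FWHM_PER_SIGMA) for v in voxel_size)


def gaussian_smooth(volume: ScalarVolume, fwhm: float) -> ScalarVolume:
    """Smooth a volume with an isotropic Gaussian kernel of the given FWHM (mm).

    The kernel width is specified as full width at half maximum in physical
    units and converted per axis to sigma in voxels. Boundaries are handled
    by reflection, which preserves the mean of the volume and avoids edge
    darkening on brain-sized grids. ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise GeometryError(f"fwhm must be non-negative, got {fwhm}")
    if fwhm == 0:
        return volume
    sigma = fwhm_to_sigma_voxels(fwhm, volume.voxel_size)
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma, mode="reflect")
    return ScalarVolume(smoothed, voxel_size=volume.voxel_size, affine=volume.affine)
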