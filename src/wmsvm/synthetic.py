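"""Synthetic cohorts of registered FA-like volumes with planted group effects.

The generator emulates the study design the pipeline targets: two groups of
a few dozen subjects each, FA-like maps in [0, 1] on a common grid with
spatially smooth noise, a handful of spherical regions where the patient
group's mean FA is reduced (or, for a few, increased), and a clinical
severity score that is higher for milder patients.

Construction, per subject:

1. baseline_mean plus i.i.d. Gaussian voxel noise (sd = noise_sd);
2. Gaussian smoothing at smooth_fwhm mm, which spatially correlates the
   noise the way smoothed real FA maps are correlated;
3. for patients only, each effect sphere adds ``multiplier * delta`` inside
   its radius, where the per-patient multiplier ~ U(0.8, 1.2) modulates
   disease severity while keeping the planted contrast close to delta;
4. values clipped to [0, 1].

The patient clinical score is ``score_intercept + score_slope * multiplier``
plus Gaussian noise. With the default negative slope, patients with stronger
FA reduction score lower (more severe disease), so the score is positively
associated with the classifier's decision value by construction.

Everything is driven by one seed; per-subject RNG streams are spawned
deterministically, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .cohort import HC, PATIENT, CohortDataset, write_cohort
from .errors import GeometryError, ParameterError
from .volumes import ScalarVolume, gaussian_smooth

__all__ = [
    "EffectSpec",
    "CohortParams",
    "generate_cohort",
    "write_cohort",
    "sphere_mask",
    "params_from_yaml",
]


@dataclass(frozen=True)
class EffectSpec:
    """A spherical group-difference plant.

    ``delta`` is signed, in FA units: negative means the patient group's
    mean is reduced inside the sphere (the common direction for white-matter
    damage), positive means it is increased.
    """

    center: tuple[int, int, int]
    radius: int
    delta: float

    def __post_init__(self) -> None:
        center = tuple(int(c) for c in self.center)
        if len(center) != 3:
            raise GeometryError("effect center must be a voxel triple")
        object.__setattr__(self, "center", center)
        if int(self.radius) < 1:
            raise GeometryError(f"effect radius must be >= 1, got {self.radius}")
        object.__setattr__(self, "radius", int(self.radius))
        if not abs(self.delta) < 1:
            raise ParameterError(f"|delta| must be < 1 FA-unit, got {self.delta}")

    def check_inside(self, grid_shape: tuple[int, int, int]) -> None:
        for c, dim in zip(self.center, grid_shape):
            if c - self.radius < 0 or c + self.radius > dim - 1:
                raise GeometryError(
                    f"effect sphere (center {self.center}, radius {self.radius}) "
                    f"does not fit inside grid {grid_shape}"
                )


@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the targeted clinical design: 22 patients vs 26 healthy
    controls, 2 mm isotropic grid, baseline FA 0.5, 6 mm FWHM smoothing, and
    a severity score centred near 40 (higher = milder).
    """

    n_patients: int = 22
    n_controls: int = 26
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    baseline_mean: float = 0.5
    noise_sd: float = 0.05
    smooth_fwhm: float = 6.0
    effects: tuple[EffectSpec, ...] = ()
    score_intercept: float = 70.0
    score_slope: float = -30.0
    score_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ParameterError("need at least 2 subjects per group")
        grid = tuple(int(g) for g in self.grid_shape)
        if len(grid) != 3 or any(g < 1 for g in grid):
            raise GeometryError(f"invalid grid shape {self.grid_shape}")
        object.__setattr__(self, "grid_shape", grid)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if not 0 < self.baseline_mean < 1:
            raise ParameterError("baseline_mean must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.smooth_fwhm < 0:
            raise ParameterError("smooth_fwhm must be non-negative")
        if self.score_noise_sd < 0:
            raise ParameterError("score_noise_sd must be non-negative")
        effects = tuple(self.effects)
        for eff in effects:
            eff.check_inside(grid)
        object.__setattr__(self, "effects", effects)


def sphere_mask(grid_shape: tuple[int, int, int], center: tuple[int, int, int], radius: int) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` of ``center`` (Euclidean, inclusive)."""
    grids = np.ogrid[tuple(slice(0, g) for g in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def generate_cohort(params: CohortParams) -> CohortDataset:
    """Generate a deterministic synthetic cohort from the given parameters.

    Controls come first (ids ``hc01`` ...), then patients (``pat01`` ...).
    """
    n = params.n_controls + params.n_patients
    streams = np.random.SeedSequence(params.seed).spawn(n)
    effect_masks = [sphere_mask(params.grid_shape, e.center, e.radius) for e in params.effects]

    subject_ids: list[str] = []
    volumes: list[ScalarVolume] = []
    labels: list[int] = []
    scores: list[float] = []

    for i in range(n):
        is_patient = i >= params.n_controls
        rng = np.random.default_rng(streams[i])
        values = params.baseline_mean + rng.normal(0.0, params.noise_sd, size=params.grid_shape)
        vol = ScalarVolume(values, voxel_size=params.voxel_size)
        vol = gaussian_smooth(vol, params.smooth_fwhm)
        values = vol.values
        if is_patient:
            multiplier = rng.uniform(0.8, 1.2)
            for eff, mask in zip(params.effects, effect_masks):
                values[mask] += multiplier * eff.delta
            score = (
                params.score_intercept
                + params.score_slope * multiplier
                + rng.normal(0.0, params.score_noise_sd)
            )
            idx = i - params.n_controls + 1
            subject_ids.append(f"pat{idx:02d}")
            labels.append(PATIENT)
            scores.append(float(score))
        else:
            subject_ids.append(f"hc{i + 1:02d}")
            labels.append(HC)
            scores.append(np.nan)
        np.clip(values, 0.0, 1.0, out=values)
        volumes.append(ScalarVolume(values, voxel_size=params.voxel_size))

    return CohortDataset(
        subject_ids=tuple(subject_ids),
        volumes=tuple(volumes),
        labels=np.array(labels, dtype=np.int64),
        clinical_scores=np.array(scores, dtype=np.float64),
    )


def params_from_yaml(path: Path | str) -> CohortParams:
    """Load :class:`CohortParams` from a YAML mapping.

    ``effects`` is a list of ``{center: [x, y, z], radius: r, delta: d}``
    mappings; all other keys map directly onto :class:`CohortParams` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError("cohort config must be a YAML mapping")
    effects = tuple(
        EffectSpec(center=tuple(e["center"]), radius=e["radius"], delta=e["delta"])
        for e in raw.pop("effects", [])
    )
    for key in ("grid_shape", "voxel_size"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortParams(effects=effects, **raw)
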