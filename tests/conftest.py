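import numpy as np
import pytest

import wmsvm as w


def make_cohort(
    n_controls: int = 8,
    n_patients: int = 8,
    grid: int = 8,
    delta: float = 0.0,
    radius: int = 2,
    noise_sd: float = 0.05,
    smooth_fwhm: float = 6.0,
    seed: int = 0,
    **kwargs,
) -> w.CohortDataset:
    """Small synthetic cohort; delta = 0 gives an effect-free (null) cohort."""
    effects = ()
    if delta != 0.0:
        center = (grid // 2,) * 3
        effects = (w.EffectSpec(center=center, radius=radius, delta=delta),)
    params = w.CohortParams(
        n_controls=n_controls,
        n_patients=n_patients,
        grid_shape=(grid, grid, grid),
        voxel_size=(2.0, 2.0, 2.0),
        noise_sd=noise_sd,
        smooth_fwhm=smooth_fwhm,
        effects=effects,
        seed=seed,
        **kwargs,
    )
    return w.generate_cohort(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_cohort() -> w.CohortDataset:
    return make_cohort(delta=0.0, seed=7)


@pytest.fixture(scope="session")
def effect_cohort() -> w.CohortDataset:
    """Strong planted effect: delta is 10x the voxel noise sd."""
    return make_cohort(n_controls=6, n_patients=6, delta=-0.2, noise_sd=0.02, seed=3)


def random_svm_instance(rng: np.random.Generator, n_max: int = 8, k_max: int = 3):
    """Tiny random two-class training set for solver checks."""
    n = int(rng.integers(4, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    n_pos = int(rng.integers(1, n))
    y = np.array([1.0] * n_pos + [-1.0] * (n - n_pos))
    rng.shuffle(y)
    X = rng.normal(size=(n, k))
    return X, y
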