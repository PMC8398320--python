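import numpy as np
import pytest

from mipool import (
    Epochs,
    MultiSubjectDataset,
    PipelineConfig,
    PopulationSpec,
    SkillMixture,
    simulate_population,
)


def make_epochs(
    rng: np.random.Generator,
    T: int = 64,
    C: int = 4,
    n_per_class: int = 8,
    fs: float = 64.0,
    scale: tuple[float, ...] | None = None,
) -> Epochs:
    """Random two-class epochs; per-channel scaling optionally differs by class."""
    N = 2 * n_per_class
    labels = np.repeat([1, 2], n_per_class)
    data = rng.standard_normal((T, C, N))
    if scale is not None:
        s = np.asarray(scale)
        data[:, :, labels == 1] *= s[None, :, None]
        data[:, :, labels == 2] *= s[::-1][None, :, None]
    channels = [f"ch{i}" for i in range(C)]
    return Epochs(data, labels, fs, channels, t0=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_epochs(rng):
    return make_epochs(rng)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six simulated subjects, small trial counts: fast shared fixture."""
    spec = PopulationSpec(
        n_subjects=6,
        skill_mixture=SkillMixture(good=1.0, poor=0.0, ipsilateral=0.0),
        n_train_per_class=15,
        n_test_per_class=15,
        seed=11,
    )
    return simulate_population(spec)


@pytest.fixture
def csp_config():
    return PipelineConfig(feature="csp")
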