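import numpy as np
import pytest

from pearspec import PipelineConfig, SpectraSet, SyntheticConfig, generate_dataset, run_pipeline


def direction_counts_for(n: int) -> dict[str, int]:
    base, rem = divmod(n, 4)
    counts = {d: base for d in ("east", "south", "west", "north")}
    for d in list(counts)[:rem]:
        counts[d] += 1
    return counts


def small_config(n_samples: int = 12, **overrides) -> SyntheticConfig:
    """A fast generator config on a short visible-range grid."""
    defaults = dict(
        n_samples=n_samples,
        direction_counts=direction_counts_for(n_samples),
        wl_start_nm=400.0,
        wl_stop_nm=720.0,
        feature_bands=((450.0, 40.0, 0.0030), (670.0, 30.0, 0.0030)),
        seed=42,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset() -> SpectraSet:
    """The study-condition dataset: 87 leaves, full 350-2500 nm grid."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return run_pipeline(default_dataset, PipelineConfig())


@pytest.fixture
def toy_dataset() -> SpectraSet:
    """Three hand-built spectra on an 8-band grid."""
    rng = np.random.default_rng(3)
    return SpectraSet(
        wavelengths_nm=np.arange(500.0, 508.0),
        reflectance=rng.uniform(0.1, 0.6, size=(3, 8)),
        sample_ids=["a", "b", "c"],
        directions=["east", "south", "west"],
        spad=np.array([40.0, 45.0, 50.0]),
    )
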