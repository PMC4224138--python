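import numpy as np
import pytest

from voxnet import BoldVolume, PhantomSpec


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """A miniature two-group phantom for fast unit tests."""
    return PhantomSpec(
        grid_shape=(8, 8, 4),
        n_sessions=2,
        images_per_session=32,
        trials_per_session=3,
        trial_len=8,
        first_trial_offset=4,
        group_sizes={"young": 2, "aged": 2},
        effect_table={
            "young": {"posterior": 1.0, "anterior": 0.35},
            "aged": {"posterior": 0.35, "anterior": 1.0},
        },
        seed=11,
    )


@pytest.fixture
def small_cohort_spec() -> PhantomSpec:
    """An 8-vs-8 phantom on a reduced grid with the full session/trial
    geometry, used for recovery-style tests."""
    return PhantomSpec(
        grid_shape=(16, 16, 6),
        group_sizes={"young": 8, "aged": 8},
        effect_table={
            "young": {"posterior": 1.0, "anterior": 0.35},
            "aged": {"posterior": 0.35, "anterior": 1.0},
        },
        seed=42,
    )


def make_volume(data, tr=2.68, **kwargs) -> BoldVolume:
    return BoldVolume(data=np.asarray(data, dtype=float), tr=tr, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
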