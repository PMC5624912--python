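import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gangliotype.models import TranscriptomeModel
from gangliotype.simulate import (
    ExpressionSimConfig,
    simulate_expression,
    simulate_traces,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_sim_config(seed: int = 11, **overrides) -> ExpressionSimConfig:
    """Scaled-down simulator settings for fast unit tests.

    Same planted cell structure as the defaults (96 cells, 37/33/6/18/2)
    with fewer genes per tier.
    """
    kwargs = dict(
        n_genes=2500,
        n_markers_per_group=60,
        n_major_markers=100,
        n_high_neutral=60,
        n_outlier_private_genes=150,
        seed=seed,
    )
    kwargs.update(overrides)
    return ExpressionSimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_expression():
    return simulate_expression(small_sim_config())


@pytest.fixture(scope="session")
def small_fit(small_expression):
    mat, truth = small_expression
    return TranscriptomeModel(mat).fit(), truth


@pytest.fixture(scope="session")
def noiseless_traces():
    return simulate_traces(n_cells_per_archetype=3, noise_sd_over_f=0.0, seed=5)


@pytest.fixture(scope="session")
def noisy_traces():
    return simulate_traces(n_cells_per_archetype=8, noise_sd_over_f=0.02, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
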