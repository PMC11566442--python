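import pytest

from cvdfusion.pipeline import RunConfig, run
from cvdfusion.recovery import bayes_conservation_errors
from cvdfusion.world import build_world

conservation_errors = bayes_conservation_errors


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale world: full default structure, reduced exposures."""
    return build_world(seed=7, pop_size=200_000)


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline artifacts at desk scale (shared across test modules)."""
    cfg = RunConfig(seed=3, pop_size=200_000, n_edu_per_cell=1000, n_prev_per_wave=1000)
    return run(cfg)
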