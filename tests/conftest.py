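import numpy as np
import pytest

from amtdr.synthetic_scene import ScenarioConfig, generate_stack


@pytest.fixture(scope="session")
def small_scene():
    """A 16x16, 5-year stationary scene with default noise and clouds."""
    cfg = ScenarioConfig(
        grid_rows=16,
        grid_cols=16,
        years=tuple(range(2001, 2006)),
        cloud_fraction=0.1,
        noise_sd=0.02,
        rng_seed=123,
    )
    stack, truth = generate_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free, cloud-free 12x12 single-year scene (exactness tests)."""
    cfg = ScenarioConfig(
        grid_rows=12,
        grid_cols=12,
        years=(2001,),
        cloud_fraction=0.0,
        noise_sd=0.0,
        rng_seed=7,
    )
    stack, truth = generate_stack(cfg)
    return cfg, stack, truth
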