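import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mrmcal import abm


@pytest.fixture(scope="session")
def tiny_config():
    """A 1-site, single-agent configuration for hand-iterable dynamics."""
    return abm.SimConfig(
        grid_width=1,
        grid_height=1,
        step_minutes=60.0,
        mediators=("M1", "M2", "M3"),
        diffusion=0.0,
        decay=1.0,
        production_scale=1.0,
        horizon_days=1.0,
        rules=(("cell", "M1"), ("cell", "M2")),
        cell_counts={"cell": 1},
        attractants={"cell": "M1"},
        mediator_toxicity={},
        toxicity_inhibitor=None,
        phagocytosis_rate=0.0,
        mediator_cap=0.0,
    )


@pytest.fixture(scope="session")
def small_config():
    """A fast 10x10 configuration with the default rule catalogue."""
    return abm.SimConfig(
        grid_width=10, grid_height=10, step_minutes=30.0, horizon_days=2.0
    )
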