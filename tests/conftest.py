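import pytest

from scentforage import SimulationConfig


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A fast, small but non-degenerate run: 20x20 torus, 40 flowers."""
    return SimulationConfig(size_map=20, flower_density=0.1, n_steps=200,
                            pollinator_ratio=0.5, seed=7)
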