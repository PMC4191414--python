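import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_config():
    """A 40-gene, 2-plate screen config small enough for per-test simulation."""
    from gemscreen import SimulationConfig

    def make(**overrides):
        base = dict(n_genes=40, genes_per_plate=20, n_replicates=3, seed=7)
        base.update(overrides)
        return SimulationConfig(**base)

    return make
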