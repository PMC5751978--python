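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


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """A fast simulation: smaller population and fewer sites, same structure."""
    from lesrmap.simulate import SimConfig

    return SimConfig(
        chrom_lengths={"chr10": 5_000_000},
        qtl_chrom="chr10",
        qtl_pos=2_500_000,
        n_f2=400,
        bulk_size=20,
        n_sites=200,
        mean_depth=24.0,
        marker_offsets=(-600_000, -200_000, 200_000, 600_000),
        seed=7,
    )
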