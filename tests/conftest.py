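import pytest
from hypothesis import HealthCheck, settings

from tseq_eval.io_formats import Amplicon, TargetPanel
from tseq_eval.synthetic_data import SimConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_panel() -> TargetPanel:
    """Three amplicons on two chromosomes, 5-base primers at each end."""
    return TargetPanel(
        [
            Amplicon("amp1", "chr1", 100, 200, 5, 5),
            Amplicon("amp2", "chr1", 300, 420, 5, 5),
            Amplicon("amp3", "chr2", 50, 150, 5, 5),
        ]
    )


@pytest.fixture
def small_sim() -> SimConfig:
    """Reduced-scale synthetic design for fast end-to-end tests."""
    return SimConfig(
        seed=11, n_amplicons=40, n_variant_sites=60, mean_depth=300.0
    )
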