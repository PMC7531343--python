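import pytest
from hypothesis import HealthCheck, settings

from editome.screen import run_screen
from editome.synthetic_cohort import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (2×100 kb genome, 20 vs 20 samples,
    100 planted edits, 20 artifact sites per category), seed 1."""
    cfg = SimConfig(seed=1)
    syn, truth, pileups = simulate_cohort(cfg)
    return cfg, syn, truth, pileups


@pytest.fixture(scope="session")
def screened(default_cohort):
    cfg, syn, truth, pileups = default_cohort
    sites, trace = run_screen(pileups, syn.annotations, syn.genome)
    return sites, trace
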