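import pytest
from hypothesis import HealthCheck, settings

from hydrocouple import pipeline, synthetic

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_system():
    """Small planted-coupling system shared across tests."""
    return synthetic.gen_toy_system(n_residues=24, n_frames=500, seed=7)


@pytest.fixture(scope="session")
def toy_result(toy_system):
    return pipeline.analyze(toy_system.frames)


@pytest.fixture(scope="session")
def multi_seed_results():
    """Pipeline results for ten independent toy-system realisations."""
    out = []
    for seed in range(10):
        toy = synthetic.gen_toy_system(n_residues=24, n_frames=1000, seed=seed)
        out.append(pipeline.analyze(toy.frames))
    return out
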