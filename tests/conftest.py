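from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amycon.pipeline import run_pipeline
from amycon.simulate import FamilySpec, simulate_family, simulate_tracks

settings.register_profile(
    "amycon",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("amycon")

N_REPLICATE_SEEDS = 20


def run_default_family(seed: int):
    """One full default-condition synthetic run: (result, truth)."""
    spec = FamilySpec(seed=seed)
    records, alignment, truth = simulate_family(spec)
    arch, dis = simulate_tracks(records, truth, seed=seed)
    return run_pipeline(records, alignment, arch, dis), truth


@pytest.fixture(scope="session")
def default_family_runs():
    """Full pipeline under default simulator conditions, 20 seeds."""
    return [run_default_family(seed) for seed in range(1, N_REPLICATE_SEEDS + 1)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20210575)
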