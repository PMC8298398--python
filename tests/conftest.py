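import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nrykit import simulate as sim

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_truth():
    """Eight-leaf genealogy with mutations at a scale where every
    branch carries several defining SNPs."""
    tree = sim.simulate_tree(8, 50_000, seed=101)
    return sim.place_mutations(tree, 8e-10, 10_000_000, seed=102)


@pytest.fixture(scope="session")
def clean_pileups(small_truth):
    """Noise-free pileups over the catalogue positions."""
    return sim.emit_pileups(
        small_truth, mean_depth=20.0, seed=103,
        positions=small_truth.variant_positions)


def brute_force_union_length(intervals):
    """Boolean-mask oracle for the total length of an interval union."""
    if not len(intervals):
        return 0
    hi = max(e for _, e in intervals)
    mask = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


@pytest.fixture
def union_oracle():
    return brute_force_union_length
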