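import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import amfassembly as A

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the simulators legitimately produce empty OTUs that get dropped with a
# warning; keep test output quiet
logging.getLogger("amfassembly").setLevel(logging.ERROR)


@pytest.fixture
def example_tree():
    """The worked 3-tip tree: d(A,B)=2, d(A,C)=d(B,C)=4."""
    return A.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    counts = np.array(
        [[10.0, 0.0, 5.0, 1.0],
         [0.0, 2.0, 5.0, 3.0],
         [4.0, 4.0, 0.0, 6.0]]
    )
    return A.OtuTable(["s1", "s2", "s3"], ["A", "B", "C", "D"], counts)


@pytest.fixture
def neutral_table_small():
    spec = A.NeutralSimSpec(n_samples=20, n_otus=60, reads_per_sample=1000,
                            migration_rate=0.05, seed=11)
    return A.simulate_neutral_table(spec).drop_empty()


def random_count_table(rng, n_samples, n_otus, max_count=20):
    counts = rng.integers(0, max_count, size=(n_samples, n_otus)).astype(float)
    # guarantee no empty samples or OTUs
    for j in range(n_samples):
        if counts[j].sum() == 0:
            counts[j, rng.integers(n_otus)] = 1.0
    for i in range(n_otus):
        if counts[:, i].sum() == 0:
            counts[rng.integers(n_samples), i] = 1.0
    return A.OtuTable([f"s{j}" for j in range(n_samples)],
                      [f"o{i}" for i in range(n_otus)], counts)
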