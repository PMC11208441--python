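import numpy as np
import pytest

from borgtools.synthetic import (IslandPlan, SyntheticSpec, TRPlan,
                                 generate_genome)


@pytest.fixture(scope="session")
def desk_spec() -> SyntheticSpec:
    """Desk-scale study conditions: one 300 kbp genome keeps every
    architecture/motif check fast while leaving all planted features
    (2 kbp ITR, 70/30 replichores, 23 TR regions, islands) at full size."""
    return SyntheticSpec(length_range=(300_000, 300_000))


@pytest.fixture(scope="session")
def genome_and_truth(desk_spec):
    return generate_genome(desk_spec, seed=11)


@pytest.fixture(scope="session")
def clean_genome_and_truth():
    """Background-only genome (no TRs, no islands) for null checks."""
    spec = SyntheticSpec(length_range=(120_000, 120_000),
                         tr_plan=TRPlan(n_regions=0),
                         high_gc_islands=IslandPlan(count=0))
    return generate_genome(spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
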