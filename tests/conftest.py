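import numpy as np
import pandas as pd
import pytest

import rbsubtyper as rb


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort shared across read-only tests."""
    cfg = rb.CohortConfig(seed=7)
    expression, methylation, segments, truth = rb.generate_cohort(cfg)
    return {"config": cfg, "expression": expression,
            "methylation": methylation, "segments": segments, "truth": truth}


@pytest.fixture(scope="session")
def organoids():
    return rb.generate_organoid_timecourse(seed=2)


def make_partition(labels, samples=None):
    samples = samples or [f"s{i}" for i in range(len(labels))]
    return rb.Partition(pd.Series(labels, index=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
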