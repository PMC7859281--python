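import numpy as np
import pytest

import dfncstates as d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """12-scan, 10-component cohort with time courses (shared, read-only)."""
    return d.generate_cohort(n_healthy=7, n_impaired=5, c=10, seed=101)


@pytest.fixture(scope="session")
def recovery_cohort():
    """52-scan, 20-component cohort for state-recovery tests (shared, read-only)."""
    return d.generate_cohort(n_healthy=32, n_impaired=20, c=20, seed=303)
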