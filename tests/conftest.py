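import numpy as np
import pytest

from oigrad import (CohortSpec, ExactBackend, GateSpec, gate_table,
                    gaussian_cohort)


@pytest.fixture
def xor3():
    return ExactBackend(gate_table(GateSpec("xor", 3)), units="bits")


@pytest.fixture
def copy3():
    return ExactBackend(gate_table(GateSpec("copy", 3)), units="bits")


@pytest.fixture
def rng():
    return np.random.default_rng(20240109)


@pytest.fixture
def independent_panel():
    """One 5-variable iid Gaussian panel, T=200."""
    spec = CohortSpec(n_records=1, n_vars=5, T=200, structure="independent",
                      seed=424242)
    return gaussian_cohort(spec)[0]
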