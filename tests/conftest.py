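import numpy as np
import pytest
from hypothesis import settings

import rarewin as rw

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (103 subjects, 10 RV clusters)."""
    cfg = rw.CohortConfig(seed=11)
    matrix, subjects, truth = rw.simulate_cohort(cfg)
    return cfg, matrix, subjects, truth


@pytest.fixture(scope="session")
def fixture_paths(default_cohort, tmp_path_factory):
    """The default cohort written out as VCF/BED/TSV files."""
    cfg, matrix, subjects, truth = default_cohort
    out = tmp_path_factory.mktemp("fixture")
    return cfg, rw.write_fixture(matrix, subjects, truth, cfg, out)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
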