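import numpy as np
import pandas as pd
import pytest

from ptprmeth import CohortConfig, generate_cohort
from ptprmeth.io import BetaMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized synthetic cohort (20/24/31 samples, 20k probes)."""
    cfg = CohortConfig(seed=0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit tests (same structure, fewer probes)."""
    cfg = CohortConfig(
        n_per_subtype={"PTPR-A": 8, "PTPR-B1": 9, "PTPR-B2": 10},
        n_probes_total=2_000, n_dmp_probes=60, n_dmp_b1b2=80,
        n_genes=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_beta(values, probes=None, samples=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))
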