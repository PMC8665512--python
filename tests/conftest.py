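import numpy as np
import pandas as pd
import pytest

from liveromics.datatypes import ClinicalTable, OmicsMatrix, PathwayDB
from liveromics.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    spec = CohortSpec(seed=7, n_genes=600, n_regions=700, n_pathways=12)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, features=None, samples=None, domain="log-abundance"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples),
                       value_domain=domain)


def make_clinical(n, rng, hazard=0.05, censor=0.02):
    t_ev = rng.exponential(1 / hazard, size=n)
    t_c = rng.exponential(1 / censor, size=n)
    rfs = np.round(np.minimum(t_ev, t_c), 1).clip(min=0.1)
    return ClinicalTable(pd.DataFrame({
        "sample": [f"S{i:03d}" for i in range(n)],
        "rfs_months": rfs,
        "rfs_event": (t_ev <= t_c).astype(int),
        "tnm_stage": rng.choice(["I", "II", "III", "IV"], size=n),
        "afp_high": rng.integers(0, 2, size=n),
        "thrombus": rng.integers(0, 2, size=n),
        "phenotype": rng.choice(["MI", "MA"], size=n),
    }))
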