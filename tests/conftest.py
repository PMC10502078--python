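import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import foodgrs as fg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel() -> fg.SNPPanel:
    return fg.load_panel()


@pytest.fixture(scope="session")
def small_study(panel) -> fg.SyntheticStudy:
    """A modest synthetic study shared by read-only tests."""
    return fg.simulate_study(n=400, seed=11, panel=panel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_genotypes(dosages, rsids=None, ids=None) -> fg.GenotypeMatrix:
    """Helper: build a GenotypeMatrix from a nested list/array."""
    arr = np.asarray(dosages, dtype=float)
    n, m = arr.shape
    rsids = rsids or [f"rs{i + 1}" for i in range(m)]
    ids = ids or [f"s{i + 1}" for i in range(n)]
    return fg.GenotypeMatrix(pd.DataFrame(arr, index=ids, columns=rsids))


def make_panel(rsids, betas_s=None, betas_f=None) -> fg.SNPPanel:
    """Helper: build a small panel with non-ambiguous alleles."""
    m = len(rsids)
    betas_s = betas_s if betas_s is not None else [0.1] * m
    betas_f = betas_f if betas_f is not None else betas_s
    return fg.SNPPanel(
        pd.DataFrame(
            {
                "rsid": rsids,
                "risk_allele": ["A"] * m,
                "other_allele": ["G"] * m,
                "beta_speliotes": betas_s,
                "beta_finhit": betas_f,
                "gene": [f"G{i}" for i in range(m)],
            }
        )
    )
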