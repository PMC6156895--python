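import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from globalp import MethylationMatrix, SampleTable

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_samples(y, covariates=None, ids=None, family=None):
    """Build a SampleTable from arrays (shared helper)."""
    n = len(y)
    ids = ids if ids is not None else [f"s{i:04d}" for i in range(n)]
    data = {"phenotype": np.asarray(y, dtype=float)}
    covariates = covariates or {}
    for name, vals in covariates.items():
        data[name] = vals
    if family is not None:
        data["family_id"] = family
    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
    return SampleTable(df, "phenotype", tuple(covariates),
                       "family_id" if family is not None else None)


def make_meth(betas, probe_ids=None, sample_ids=None):
    betas = np.asarray(betas, dtype=float)
    m, n = betas.shape
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(m)]
    sample_ids = sample_ids or [f"s{j:04d}" for j in range(n)]
    return MethylationMatrix(pd.DataFrame(betas, index=probe_ids, columns=sample_ids))


@pytest.fixture
def tiny_samples():
    rng = np.random.default_rng(7)
    y = rng.normal(size=40)
    return make_samples(y, covariates={"age": rng.normal(50, 10, 40),
                                       "sex": rng.choice(["F", "M"], 40)})
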