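import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from xcikit import SimGenome

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def genome() -> SimGenome:
    return SimGenome.default()


@pytest.fixture
def tiny_genome() -> SimGenome:
    return SimGenome(("chr1", "chrX"), (400_000, 300_000))


def make_adata(total, strain1, obs=None, chroms=None, genotype="WT"):
    """Small dense AnnData with strain1/strain2 layers for hand fixtures."""
    total = np.asarray(total, dtype=np.int64)
    strain1 = np.asarray(strain1, dtype=np.int64)
    strain2 = total - strain1
    n_obs, n_var = total.shape
    if chroms is None:
        chroms = ["chrX"] * n_var
    if obs is None:
        obs = pd.DataFrame(index=[f"cell{i}" for i in range(n_obs)])
    obs = obs.copy()
    if "genotype" not in obs:
        obs["genotype"] = genotype
    adata = ad.AnnData(
        X=total,
        obs=obs,
        var=pd.DataFrame({"chrom": chroms}, index=[f"g{i}" for i in range(n_var)]),
        layers={"strain1": strain1, "strain2": strain2},
    )
    return adata


@pytest.fixture
def adata_factory():
    return make_adata
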