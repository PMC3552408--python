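import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from adaptdiff.core import TraitTable, GenotypeTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def balanced_traits():
    """Builder for balanced trait tables from an array (pops, fams, obs)."""

    def make(values: np.ndarray, trait: str = "y") -> TraitTable:
        values = np.asarray(values, dtype=float)
        a, f, o = values.shape
        rows = {
            "individual_id": [f"i{k}" for k in range(a * f * o)],
            "population": np.repeat([f"pop{i}" for i in range(a)], f * o),
            "family": np.tile(np.repeat([f"fam{j}" for j in range(f)], o), a),
            trait: values.ravel(),
        }
        return TraitTable(pd.DataFrame(rows))

    return make


@pytest.fixture
def genotype_builder():
    """Builder for genotype tables from {pop: list of [(a,b), ...] per individual}."""

    def make(pops: dict[str, list[list[tuple[int, int]]]], loci: list[str] | None = None):
        individuals, populations, rows = [], [], []
        k = 0
        for pop, inds in pops.items():
            for geno in inds:
                individuals.append(f"ind{k}")
                populations.append(pop)
                rows.append(geno)
                k += 1
        n_loci = len(rows[0])
        return GenotypeTable(
            individuals=individuals,
            populations=np.array(populations, dtype=object),
            loci=loci or [f"L{j}" for j in range(n_loci)],
            alleles=np.array(rows, dtype=np.int64),
        )

    return make
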