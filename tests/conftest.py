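import numpy as np
import pandas as pd
import pytest

from lipidflow.extraction import IntensityMatrix


def make_matrix(values, groups=None, sample_type=None, tissue="t1",
                modes=None, species=None):
    """Build an IntensityMatrix from a plain array + minimal metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"s{i}" for i in range(n)]
    var_ids = [f"v{j}" for j in range(p)]
    groups = list(groups) if groups is not None else ["A"] * n
    sample_type = list(sample_type) if sample_type is not None else ["study"] * n
    modes = list(modes) if modes is not None else ["positive"] * p
    species = list(species) if species is not None else var_ids
    vals = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                        columns=var_ids)
    samples = pd.DataFrame(
        {"group": groups, "tissue": tissue, "sample_type": sample_type,
         "subject": [f"subj{i}" for i in range(n)]},
        index=vals.index,
    )
    variables = pd.DataFrame(
        {"variable": var_ids, "species": species,
         "lipid_class": ["X"] * p, "adduct": ["+H"] * p,
         "mode": modes, "mz_theoretical": np.linspace(400, 900, p)}
    ).set_index("variable")
    return IntensityMatrix(vals, samples, variables)


@pytest.fixture
def two_group_matrix():
    """20 vs 20 samples, 50 variables, 3 of them shifted by ~3 pooled sd."""
    rng = np.random.default_rng(7)
    n, p = 40, 50
    x = rng.lognormal(0, 0.25, size=(n, p))
    x[n // 2:, :3] *= 2.2
    return make_matrix(x, groups=["A"] * (n // 2) + ["B"] * (n // 2))
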