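import numpy as np
import pandas as pd
import pytest

from coexnet.expression import CountMatrix, NormalizedMatrix, cpm_normalize


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes × 2 samples with unequal library sizes."""
    df = pd.DataFrame(
        {"s1": [5, 15, 80], "s2": [10, 10, 30]},
        index=["g1", "g2", "g3"],
    )
    return CountMatrix(df, {"s1": "shoot", "s2": "inflorescence"})


@pytest.fixture
def toy_cpm(toy_counts) -> NormalizedMatrix:
    return cpm_normalize(toy_counts)


def random_cpm(n_genes: int, n_samples: int, seed: int) -> NormalizedMatrix:
    """Unstructured positive expression matrix for noise-only scenarios."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=4.0, sigma=1.0, size=(n_genes, n_samples))
    df = pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    groups = {f"s{j}": ("shoot" if j % 2 else "inflorescence")
              for j in range(n_samples)}
    return NormalizedMatrix(df, groups)
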