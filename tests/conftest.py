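import numpy as np
import pandas as pd
import pytest

from crossdeg.io import CountMatrix


def make_count_matrix(counts: np.ndarray, gene_ids=None, sample_ids=None,
                      conditions=None, species="A") -> CountMatrix:
    counts = np.asarray(counts)
    g, n = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    conditions = conditions or ["control"] * (n // 2) + ["treated"] * (n - n // 2)
    meta = pd.DataFrame(
        {"species": species, "condition": conditions,
         "replicate": list(range(1, n + 1))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    return CountMatrix(counts=df, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
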