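import numpy as np
import pandas as pd
import pytest

from lysoflux.io_core import ExpressionMatrix, GeneSet, SampleAnnotation


@pytest.fixture
def toy_counts():
    """3 genes × 4 samples, two groups, sample doubling structure."""
    df = pd.DataFrame(
        [[10, 20, 30, 40], [20, 40, 60, 80], [30, 60, 90, 120]],
        index=["Ctsb", "Ctss", "Acp5"],
        columns=["a1", "a2", "b1", "b2"],
    )
    matrix = ExpressionMatrix(df, "counts")
    ann = SampleAnnotation.from_groups(
        {"a1": "lean", "a2": "lean", "b1": "obese", "b2": "obese"}
    )
    return matrix, ann


@pytest.fixture
def random_log2_matrix():
    def make(n_genes=20, n_samples=10, seed=0, groups=("ctrl", "trt")):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n_genes, n_samples))
        half = n_samples // 2
        sample_ids = [f"s{j}" for j in range(n_samples)]
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(n_genes)], columns=sample_ids),
            "log2",
        )
        ann = SampleAnnotation.from_groups(
            {s: (groups[0] if j < half else groups[1]) for j, s in enumerate(sample_ids)}
        )
        return m, ann

    return make


@pytest.fixture
def lyso_set():
    return GeneSet("LYSO", "focus set", ("Ctsb", "Ctss", "Acp5", "Tfe3", "Cd68", "Slc15a3"))
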