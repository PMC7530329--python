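import numpy as np
import pandas as pd
import pytest

from cernet.datatypes import ExpressionMatrix


def make_matrix(diffs, classes=None, base=None, seed=0):
    """Build a paired ExpressionMatrix whose tumor-normal differences equal
    the given (transcripts x pairs) array exactly."""
    diffs = np.asarray(diffs, dtype=float)
    n_genes, k = diffs.shape
    rng = np.random.default_rng(seed)
    normal = rng.normal(6.0, 1.0, size=(n_genes, k)) if base is None else base
    tumor = normal + diffs
    ids = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"T{j:02d}" for j in range(k)] + [f"N{j:02d}" for j in range(k)]
    values = pd.DataFrame(
        np.concatenate([tumor, normal], axis=1), index=ids, columns=samples
    )
    design = pd.DataFrame(
        {
            "condition": ["tumor"] * k + ["normal"] * k,
            "pair": [f"P{j:02d}" for j in range(k)] * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    cls = None
    if classes is not None:
        cls = pd.Series(classes, index=ids, name="class")
    return ExpressionMatrix(values, design, cls)


@pytest.fixture
def toy_matrix():
    """3 transcripts x 3 pairs with hand-chosen differences."""
    return make_matrix(
        [[1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -3.0]],
        classes=["lncRNA", "mRNA", "mRNA"],
    )
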