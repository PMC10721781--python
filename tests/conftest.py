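import numpy as np
import pandas as pd
import pytest

from tfcollab.expression import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, groups=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    if groups is None:
        groups = {s: "all" for s in sample_ids}
        order = ["all"]
    else:
        order = list(dict.fromkeys(groups.values()))
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), groups, order)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """Session-scoped planted end-to-end fixture (2 modules, 4 triples)."""
    from tfcollab.pipeline import demo_fixture

    outdir = tmp_path_factory.mktemp("demo_fixture")
    return demo_fixture(outdir, seed=1)
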