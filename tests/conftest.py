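import numpy as np
import pandas as pd
import pytest

import tworect as tw


@pytest.fixture
def worked():
    """The deterministic hand-traceable 10-gene toy study."""
    return tw.worked_fixture()


@pytest.fixture
def worked_ranked(worked):
    return tw.rank_genes(tw.fold_change_scores(worked.expression))


@pytest.fixture
def small_study():
    """A small planted study for fast end-to-end runs."""
    return tw.generate_study(n_genes=400, n_pathways=12,
                             pathway_size_range=(10, 30),
                             n_active_pathways=3, seed=7)


def make_expression(values, control_ids, test_ids, genes=None):
    """Build an ExpressionMatrix from a plain nested list."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = list(control_ids) + list(test_ids)
    return tw.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        group_labels=pd.Series(["control"] * len(control_ids)
                               + ["test"] * len(test_ids), index=samples),
    )
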