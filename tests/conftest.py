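import numpy as np
import pandas as pd
import pytest

from ptrtools.io import ExpressionMatrix, GeneSet


def make_expr(values, gene_ids=None, cell_ids=None, patients=None, tissues=None,
              **extra_meta):
    """Build a small ExpressionMatrix from a dense array with default metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "patient_id": patients or ["P1"] * n_cells,
            "tissue": tissues or ["liver"] * n_cells,
            **extra_meta,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionMatrix(values=values, gene_ids=pd.Index(gene_ids),
                            cell_ids=pd.Index(cell_ids), cell_meta=meta)


@pytest.fixture
def toy_expr():
    # 3 genes x 4 cells, hand-set values used by arithmetic oracles
    return make_expr(
        [[1.0, 0.0, 2.0, 4.0],
         [3.0, 1.0, 0.0, 2.0],
         [0.0, 5.0, 1.0, 0.0]],
    )


@pytest.fixture
def signature50():
    return GeneSet("tumor_reactivity", [f"SIG{i:03d}" for i in range(50)])
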