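import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from blastoseq import simulate


def point_in_hull(point: np.ndarray, vertices: np.ndarray, tol: float = 1e-9) -> bool:
    """Linear-programming membership test: is the point a convex combination
    of the vertices? Independent of the geometry code under test."""
    n = len(vertices)
    a_eq = np.vstack([vertices.T, np.ones(n)])
    b_eq = np.concatenate([point, [1.0]])
    res = linprog(np.zeros(n), A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * n)
    return res.status == 0 and res.fun is not None


@pytest.fixture
def small_embryo():
    params = simulate.EmbryoSimParams(n_outer=40, n_inner=10, seed=7)
    table, truth = simulate.simulate_embryo(params)
    return table, truth


@pytest.fixture
def two_class_matrix():
    """40 cells in two classes with 50 planted signature genes."""
    params = simulate.ExpressionSimParams(
        n_genes=400, n_hvg=0, n_modules=0, pseudotime_genes=0, seed=11
    )
    return simulate.simulate_expression(params)


@pytest.fixture
def toy_matrix():
    genes = ["g1", "g2", "g3", "g4"]
    cells = ["c1", "c2", "c3", "c4"]
    vals = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
            [2.0, 4.0, 6.0, 8.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    return pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"), columns=cells)
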