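import numpy as np
import pytest

from cellsorter.containers import ExpressionMatrix, MarkerSpec, ProblemInstance


def make_instance(x, gamma, weights, type_names=None, g=None):
    """Assemble a ProblemInstance from raw arrays (markers-first rows)."""
    x = np.asarray(x, dtype=float)
    gamma = np.asarray(gamma, dtype=bool)
    g = gamma.shape[0] if g is None else g
    h = x.shape[0] - g
    K = gamma.shape[1]
    gene_ids = [f"m{i}" for i in range(g)] + [f"n{i}" for i in range(h)]
    type_names = type_names or [f"T{k}" for k in range(K)]
    expr = ExpressionMatrix(
        x, gene_ids, [f"c{j}" for j in range(x.shape[1])], is_lognorm=False
    )
    spec = MarkerSpec(type_names, gene_ids[:g], gamma, np.asarray(weights, float))
    return ProblemInstance(expr=expr, spec=spec, g=g, h=h)


def single_marker_instance(x_gene, gamma_row, w_row, extra_nonmarker=None):
    """Instance exposing one marker gene of interest (gene 0) plus a dummy
    marker covering all types, so per-gene solvers can be probed in
    isolation while the container invariants stay satisfied."""
    x_gene = np.asarray(x_gene, dtype=float)
    n = x_gene.size
    K = len(gamma_row)
    nonm = np.ones(n) if extra_nonmarker is None else np.asarray(extra_nonmarker)
    x = np.vstack([x_gene, np.zeros(n), nonm])
    gamma = np.vstack([gamma_row, [True] * K]).astype(bool)
    weights = np.vstack([w_row, np.ones(K)]).astype(float)
    return make_instance(x, gamma, weights)


@pytest.fixture
def separable_instance():
    """Two well-separated types: one exclusive marker each (5 in own type,
    0 elsewhere) and two informative non-marker genes."""
    truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    m0 = np.where(truth == 0, 5.0, 0.0)
    m1 = np.where(truth == 1, 5.0, 0.0)
    n0 = np.where(truth == 0, 1.0, 4.0) + 0.01 * np.arange(8)
    n1 = np.where(truth == 0, 3.0, 0.5) - 0.01 * np.arange(8)
    x = np.vstack([m0, m1, n0, n1])
    gamma = np.array([[True, False], [False, True]])
    weights = np.full((2, 2), 2.0)
    return make_instance(x, gamma, weights), truth
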