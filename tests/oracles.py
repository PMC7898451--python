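"""Independent brute-force oracles for the clustering objective.

These deliberately avoid the package's solver code paths: costs are
minimized by exhaustive enumeration (all assignments; elevated sets per
marker gene), so they can certify the alternating solver's solutions on
tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_gene_cost_full(x, assignment, K, gamma_row, w_row):
    """Exact per-gene minimum by enumerating ALL elevated subsets.

    Exponential in cluster sizes; only for validating the top-m reduction.
    """
    members = [np.flatnonzero(assignment == k) for k in range(K)]
    best = np.inf
    subset_choices = [
        list(itertools.chain.from_iterable(
            itertools.combinations(members[k], m)
            for m in range(len(members[k]) + 1)
        )) if gamma_row[k] else [()]
        for k in range(K)
    ]
    for combo in itertools.product(*subset_choices):
        best = min(best, _cost_given_sets(x, assignment, K, w_row, combo))
    return best


def exact_gene_cost(x, assignment, K, gamma_row, w_row):
    """Exact per-gene minimum enumerating elevated sets as top-m subsets.

    For each marking cluster the elevated set of a given size can be taken
    as the largest values in the cluster (validated against the full
    enumeration in the test suite), which makes the search polynomial.
    """
    members = [np.flatnonzero(assignment == k) for k in range(K)]
    tops = []
    for k in range(K):
        if gamma_row[k]:
            order = members[k][np.argsort(-x[members[k]])]
            tops.append([tuple(order[:m]) for m in range(len(order) + 1)])
        else:
            tops.append([()])
    best = np.inf
    for combo in itertools.product(*tops):
        best = min(best, _cost_given_sets(x, assignment, K, w_row, combo))
    return best


def _cost_given_sets(x, assignment, K, w_row, elevated_sets):
    """Exact minimum over (mu, delta >= 0) with the elevated sets fixed."""
    n = x.size
    elevated = np.zeros(n, dtype=bool)
    for cells in elevated_sets:
        elevated[list(cells)] = True
    w_cell = w_row[assignment]
    base = ~elevated
    cost = 0.0
    if base.any():
        mu = float(w_cell[base] @ x[base] / w_cell[base].sum())
    else:
        mu = -np.inf  # any mu below all elevated means is optimal
    means = []
    for k, cells in enumerate(elevated_sets):
        if len(cells):
            means.append(x[list(cells)].mean())
    if means and base.any() and min(means) < mu:
        return np.inf  # delta >= 0 infeasible for this configuration
    if base.any():
        cost += float(w_cell[base] @ (x[base] - mu) ** 2)
    for k, cells in enumerate(elevated_sets):
        if len(cells):
            xv = x[list(cells)]
            cost += float(w_row[k] * ((xv - xv.mean()) ** 2).sum())
    return cost


def exact_assignment_cost(instance, assignment):
    """Exact minimum of the full objective for a FIXED assignment."""
    total = 0.0
    for i in range(instance.g):
        total += exact_gene_cost(
            instance.x_marker[i],
            assignment,
            instance.K,
            instance.spec.gamma[i],
            instance.spec.weights[i],
        )
    for k in range(instance.K):
        cells = np.flatnonzero(assignment == k)
        if cells.size:
            xh = instance.x_nonmarker[:, cells]
            total += float(((xh - xh.mean(axis=1, keepdims=True)) ** 2).sum())
    return total


def global_optimum(instance):
    """Global minimum of the objective over all K^N assignments."""
    best_cost, best_assign = np.inf, None
    for combo in itertools.product(range(instance.K), repeat=instance.N):
        a = np.array(combo)
        c = exact_assignment_cost(instance, a)
        if c < best_cost:
            best_cost, best_assign = c, a
    return best_cost, best_assign


def lloyd_kmeans(x, assignment, max_iter=100):
    """Plain Lloyd iterations from an initial assignment; returns cost trace.

    ``x`` is features x points. Ties go to the smallest cluster index and
    empty clusters keep their previous centroid, mirroring the documented
    conventions so trajectories are directly comparable.
    """
    K = int(assignment.max()) + 1
    a = assignment.copy()
    centroids = np.empty((x.shape[0], K))
    centroids[:] = x.mean(axis=1, keepdims=True)
    trace = []
    for _ in range(max_iter):
        for k in range(K):
            cells = np.flatnonzero(a == k)
            if cells.size:
                centroids[:, k] = x[:, cells].mean(axis=1)
        d = ((x[:, :, None] - centroids[:, None, :]) ** 2).sum(axis=0)
        trace.append(float(d[np.arange(x.shape[1]), a].sum()))
        new_a = np.argmin(d, axis=1)
        trace.append(float(d[np.arange(x.shape[1]), new_a].sum()))
        if np.array_equal(new_a, a):
            return a, trace
        a = new_a
    return a, trace


def random_tiny_instance(rng, N=8, K=2, g=2, h=3, w0=2.0, separation=3.0):
    """A random small problem with planted structure, for oracle tests."""
    from cellsorter.containers import (
        ExpressionMatrix,
        MarkerSpec,
        ProblemInstance,
    )

    truth = rng.integers(0, K, size=N)
    x = rng.normal(0.0, 1.0, size=(g + h, N))
    if g < K:
        raise ValueError("need g >= K so every type has a marker")
    gamma = np.zeros((g, K), dtype=bool)
    for i in range(g):
        gamma[i, i % K if i < K else rng.integers(0, K)] = True
    for i in range(g):
        k = int(np.flatnonzero(gamma[i])[0])
        own = truth == k
        on = own & (rng.random(N) < 0.8)
        x[i, on] += separation
    for i in range(h):
        shift = rng.normal(0.0, separation / 2.0, size=K)
        x[g + i] += shift[truth]
    x = x - x.min() + 0.1
    gene_ids = [f"m{i}" for i in range(g)] + [f"n{i}" for i in range(h)]
    expr = ExpressionMatrix(x, gene_ids, [f"c{j}" for j in range(N)], True)
    weights = np.full((g, K), w0 * h / g)
    spec = MarkerSpec(
        [f"T{k}" for k in range(K)], gene_ids[:g], gamma, weights
    )
    return ProblemInstance(expr=expr, spec=spec, g=g, h=h, w0=w0), truth
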