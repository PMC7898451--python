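"""Step I: constrained clustering with per-marker base/elevated levels.

The objective generalizes K-means.  Each non-marker gene contributes the
usual within-cluster sum of squares around per-cluster centroids mu_ik.
Each marker gene i has a single base level mu_i shared by all clusters plus
a non-negative elevation delta_ik for every type k it marks; a cell of type
k pays the cheaper of sitting at the base level or at the elevated level
mu_i + delta_ik, so a marker is allowed to stay un-elevated in any fraction
of its own type's cells:

    sum_i<=g sum_k sum_{j in C_k} w_ik [ (x_ij-mu_i)^2           if gamma_ik=0
                                         min((x_ij-mu_i-delta_ik)^2,
                                             (x_ij-mu_i)^2)      if gamma_ik=1 ]
  + sum_i>g  sum_k sum_{j in C_k} (x_ij-mu_ik)^2,   s.t. delta_ik >= 0.

The solver alternates K-means-style: fit all parameters given the
assignment, then reassign each cell to its cheapest cluster.  Marker
parameters have no closed form; an inner fixed point alternates the exact
conditional updates

    delta_ik = mean over {j in C_k : x_ij > mu_i + delta_ik/2} of (x_ij - mu_i)
    mu_i     = (sum w x  -  sum over elevated cells of w delta) / sum w

until the elevated sets stabilize.  Every individual update is an exact
conditional minimizer after an optimal branch re-choice, so the objective
is non-increasing throughout; this is asserted at runtime.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ProblemInstance

logger = logging.getLogger(__name__)

__all__ = [
    "StepOneState",
    "assignment_cost",
    "cost_matrix",
    "update_assignments",
    "update_nonmarker_centroids",
    "fit_marker_params",
    "step1_total_cost",
    "run_step1",
]

_INNER_TOL = 1e-8
_MAX_INNER_ITER = 100
# slack for the runtime monotone-descent assertion (floating-point only)
_DESCENT_RTOL = 1e-7


@dataclass
class StepOneState:
    """Solution state of the Step I optimization.

    ``assignment`` holds 0-based cluster indices; ``delta`` is zero wherever
    ``gamma`` is zero (those entries are not model parameters).
    """

    assignment: np.ndarray          # (N,) int
    mu_base: np.ndarray             # (g,)
    delta: np.ndarray               # (g, K), >= 0
    mu_nonmarker: np.ndarray        # (h, K)
    cost: float = np.inf
    n_iter: int = 0
    converged: bool = False
    cost_trace: list = field(default_factory=list)

    def copy(self) -> "StepOneState":
        return StepOneState(
            self.assignment.copy(), self.mu_base.copy(), self.delta.copy(),
            self.mu_nonmarker.copy(), self.cost, self.n_iter, self.converged,
            list(self.cost_trace),
        )


def cost_matrix(
    instance: ProblemInstance,
    mu_base: np.ndarray,
    delta: np.ndarray,
    mu_nonmarker: np.ndarray,
) -> np.ndarray:
    """(N, K) matrix of per-cell assignment costs under the given parameters."""
    N, K, g = instance.N, instance.K, instance.g
    cm = np.zeros((N, K))
    if g:
        xm = instance.x_marker                                   # (g, N)
        base = (xm - mu_base[:, None]) ** 2                      # (g, N)
        elev = (xm[:, :, None] - mu_base[:, None, None] - delta[:, None, :]) ** 2
        per = np.where(
            instance.spec.gamma[:, None, :],
            np.minimum(elev, base[:, :, None]),
            base[:, :, None],
        )                                                        # (g, N, K)
        cm += np.einsum("gnk,gk->nk", per, instance.spec.weights)
    xh = instance.x_nonmarker                                    # (h, N)
    sq = (
        (xh ** 2).sum(axis=0)[:, None]
        + (mu_nonmarker ** 2).sum(axis=0)[None, :]
        - 2.0 * xh.T @ mu_nonmarker
    )
    cm += np.maximum(sq, 0.0)
    return cm


def assignment_cost(
    instance: ProblemInstance, state: StepOneState, cell: int, cluster: int
) -> float:
    """Cost of assigning one cell to one cluster under the current parameters."""
    if not 0 <= cluster < instance.K:
        raise IndexError(f"cluster {cluster} outside 0..{instance.K - 1}")
    if not 0 <= cell < instance.N:
        raise IndexError(f"cell {cell} outside 0..{instance.N - 1}")
    total = 0.0
    for i in range(instance.g):
        x = instance.x_marker[i, cell]
        base = (x - state.mu_base[i]) ** 2
        if instance.spec.gamma[i, cluster]:
            elev = (x - state.mu_base[i] - state.delta[i, cluster]) ** 2
            term = min(elev, base)
        else:
            term = base
        total += instance.spec.weights[i, cluster] * term
    diff = instance.x_nonmarker[:, cell] - state.mu_nonmarker[:, cluster]
    return total + float(diff @ diff)


def step1_total_cost(instance: ProblemInstance, state: StepOneState) -> float:
    """The full objective, evaluated directly as the double sum over genes."""
    a = state.assignment
    total = 0.0
    for k in range(instance.K):
        members = np.flatnonzero(a == k)
        if members.size == 0:
            continue
        if instance.g:
            xm = instance.x_marker[:, members]                   # (g, n_k)
            base = (xm - state.mu_base[:, None]) ** 2
            elev = (xm - state.mu_base[:, None] - state.delta[:, k, None]) ** 2
            per = np.where(
                instance.spec.gamma[:, k, None], np.minimum(elev, base), base
            )
            total += float((instance.spec.weights[:, k, None] * per).sum())
        xh = instance.x_nonmarker[:, members]
        total += float(((xh - state.mu_nonmarker[:, k, None]) ** 2).sum())
    return total


def update_assignments(
    instance: ProblemInstance, state: StepOneState
) -> StepOneState:
    """Move every cell to its cheapest cluster (ties: smallest index)."""
    cm = cost_matrix(instance, state.mu_base, state.delta, state.mu_nonmarker)
    new = state.copy()
    new.assignment = np.argmin(cm, axis=1)
    return new


def update_nonmarker_centroids(
    instance: ProblemInstance, state: StepOneState
) -> StepOneState:
    """Set each cluster's non-marker centroid to its member mean.

    Empty clusters retain their previous centroids.
    """
    new = state.copy()
    for k in range(instance.K):
        members = np.flatnonzero(state.assignment == k)
        if members.size:
            new.mu_nonmarker[:, k] = instance.x_nonmarker[:, members].mean(axis=1)
    return new


def fit_marker_params(
    instance: ProblemInstance,
    assignment: np.ndarray,
    gene: int,
    init: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Base level and per-type elevations minimizing one marker's cost.

    The per-gene subproblem is solved exactly.  At any optimum the elevated
    cells of a marking cluster are a top-m-by-value subset, and with the
    elevated sets fixed the stationarity conditions (the delta/mu update
    recursion) have the closed-form limit mu = weighted mean of base-branch
    cells, delta_k = mean(E_k) - mu.  Scanning every elevated-set size per
    marking cluster with prefix sums, keeping only configurations
    satisfying delta >= 0, therefore finds the global minimizer, which is
    itself a fixed point of the update recursion.  Ties go to the smallest
    elevated sets.

    Returns ``(mu_i, delta_i)`` with ``delta_i`` a K-vector, zero for types
    the gene does not mark and for marking types with an empty elevated
    set; empty clusters retain the warm-start ``init`` value if given.
    """
    K = instance.K
    x = instance.x_marker[gene]                                  # (N,)
    gamma = instance.spec.gamma[gene]                            # (K,)
    w_row = instance.spec.weights[gene]                          # (K,)
    w_cell = w_row[assignment]                                   # (N,)
    members = [np.flatnonzero(assignment == k) for k in range(K)]

    w_tot = float(w_cell.sum())
    s_tot = float(w_cell @ x)
    q_tot = float(w_cell @ (x * x))

    marked = [k for k in range(K) if gamma[k] and members[k].size]
    pre = {}
    for k in marked:
        v = np.sort(x[members[k]])[::-1]
        pre[k] = (
            np.concatenate([[0.0], np.cumsum(v)]),
            np.concatenate([[0.0], np.cumsum(v * v)]),
            v.size,
        )

    best_cost, best = np.inf, None
    for combo in itertools.product(*(range(pre[k][2] + 1) for k in marked)):
        w_b, s_b, q_b = w_tot, s_tot, q_tot
        e_means = {}
        for k, m in zip(marked, combo):
            if m:
                p, p2, _ = pre[k]
                w_b -= w_row[k] * m
                s_b -= w_row[k] * p[m]
                q_b -= w_row[k] * p2[m]
                e_means[k] = p[m] / m
        if w_b > 1e-12:
            mu = s_b / w_b
            cost = max(q_b - s_b * s_b / w_b, 0.0)
        else:
            mu = min(e_means.values())
            cost = 0.0
        if any(m < mu - 1e-12 for m in e_means.values()):
            continue  # delta >= 0 infeasible for this configuration
        for k, m in zip(marked, combo):
            if m:
                p, p2, _ = pre[k]
                cost += w_row[k] * max(p2[m] - p[m] ** 2 / m, 0.0)
        if best is None or cost < best_cost - 1e-12 * (1.0 + best_cost):
            best_cost, best = cost, (mu, dict(e_means))

    mu, e_means = best
    delta = np.zeros(K)
    if init is not None:
        delta = np.array(init[1], dtype=float)
        delta[~gamma] = 0.0
        for k in marked:
            delta[k] = 0.0  # nonempty marking clusters are set below
    for k, m in e_means.items():
        delta[k] = max(m - mu, 0.0)
    return float(mu), delta


def _fit_all_params(
    instance: ProblemInstance, state: StepOneState
) -> StepOneState:
    """One full parameter update: centroids plus every marker fixed point."""
    new = update_nonmarker_centroids(instance, state)
    warm = state.n_iter > 0
    for i in range(instance.g):
        init = (state.mu_base[i], state.delta[i]) if warm else None
        mu, delta = fit_marker_params(instance, state.assignment, i, init=init)
        new.mu_base[i] = mu
        new.delta[i] = delta
    return new


def _check_descent(prev: float, cur: float, where: str) -> None:
    if cur > prev + _DESCENT_RTOL * (1.0 + abs(prev)):
        raise AssertionError(
            f"objective increased during {where}: {prev:.12g} -> {cur:.12g}"
        )


def run_step1(
    instance: ProblemInstance,
    seed: int,
    max_iter: int = 100,
    init_assignment: np.ndarray | None = None,
) -> StepOneState:
    """Alternating minimization from a random assignment.

    Cells are initially assigned to clusters uniformly at random (seeded);
    parameter fits and reassignments alternate until the assignment stops
    changing or ``max_iter`` outer iterations elapse.  The objective value
    after each phase is recorded in ``cost_trace`` and verified to be
    non-increasing.
    """
    N, K = instance.N, instance.K
    if K < 1:
        raise ValueError("need at least one cell type")
    if N < K:
        raise ValueError(f"fewer cells ({N}) than cell types ({K})")

    if init_assignment is not None:
        assignment = np.asarray(init_assignment, dtype=int).copy()
    else:
        rng = np.random.default_rng(seed)
        assignment = rng.integers(0, K, size=N)

    grand = instance.x_nonmarker.mean(axis=1)
    state = StepOneState(
        assignment=assignment,
        mu_base=np.zeros(instance.g),
        delta=np.zeros((instance.g, K)),
        mu_nonmarker=np.tile(grand[:, None], (1, K)),
    )

    prev_cost = np.inf
    for it in range(max_iter):
        state = _fit_all_params(instance, state)
        cost = step1_total_cost(instance, state)
        if it > 0:
            _check_descent(prev_cost, cost, "parameter update")
        state.cost_trace.append(cost)
        prev_cost = cost

        new_state = update_assignments(instance, state)
        new_state.n_iter = it + 1
        cost = step1_total_cost(instance, new_state)
        _check_descent(prev_cost, cost, "assignment update")
        new_state.cost_trace.append(cost)
        prev_cost = cost

        if np.array_equal(new_state.assignment, state.assignment):
            new_state.converged = True
            new_state.cost = cost
            return new_state
        state = new_state

    logger.warning("assignment did not stabilize within %d iterations", max_iter)
    state.cost = prev_cost
    return state
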