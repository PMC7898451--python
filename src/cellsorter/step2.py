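"""Step II: calling cells that resemble none of the known types.

Step I forces every cell into one of the K known clusters.  Within each
cluster k the cells split on alpha_kj, the fraction of type k's markers a
cell expresses at the elevated level: cells with alpha > alpha0 are
"decided" (set D_k, kept as type k), the rest are "undecided" (set U_k)
and are screened one by one against the decided cells on the non-marker
genes.  Each undecided cell gets a squared z-score distance

    d_jk = sum_i z_ij^2,   z_ij = (x_ij - nu_ik) / sigma_ik,

with nu/sigma the per-gene mean and sd over D_k, and beta_jk = the
chi-square(h) CDF of d_jk.  Under the null (the cell is a bona fide type-k
cell) beta is uniform on [0, 1]; alien cells pile up near 1.  The cutoff
theta_k is picked automatically by minimizing the two-group within-sum-of-
squares S_k over the range [F_chi2h(h + sqrt(2h)), 1]; cells with
beta > theta_k become "Unknown".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .containers import ProblemInstance
from .step1 import StepOneState

logger = logging.getLogger(__name__)

__all__ = [
    "UNKNOWN_LABEL",
    "StepTwoResult",
    "compute_alpha",
    "partition_decided",
    "compute_beta",
    "select_theta",
    "call_unknowns",
]

UNKNOWN_LABEL = "Unknown"
_SIGMA_FLOOR = 1e-6


@dataclass
class StepTwoResult:
    """Per-cell diagnostics and final labels from the unknown-calling stage.

    ``beta`` is NaN for decided cells (no test is performed on them) and for
    cells of clusters where the test was skipped. ``theta`` and ``s_k`` are
    per-cluster; ``theta`` is NaN for skipped clusters.
    """

    alpha: np.ndarray               # (N,)
    decided_mask: np.ndarray        # (N,) bool
    beta: np.ndarray                # (N,), NaN where undefined
    theta: np.ndarray               # (K,)
    s_k: np.ndarray                 # (K,)
    labels: list = field(default_factory=list)   # type names or UNKNOWN_LABEL
    unknown_mask: np.ndarray | None = None       # (N,) bool


def compute_alpha(
    instance: ProblemInstance, state: StepOneState, cell: int
) -> float:
    """Fraction of the cell's cluster's markers at the elevated level.

    A marker is elevated in the cell when x > mu_i + delta_ik/2, i.e. when
    the elevated branch of the objective is the cheaper one (the boundary
    point counts as base level).
    """
    k = int(state.assignment[cell])
    idx = np.flatnonzero(instance.spec.gamma[:, k])
    if idx.size == 0:
        raise ValueError(f"cluster {k} has no marker genes")
    x = instance.x_marker[idx, cell]
    thresh = state.mu_base[idx] + state.delta[idx, k] / 2.0
    return float((x > thresh).sum() / idx.size)


def _all_alphas(instance: ProblemInstance, state: StepOneState) -> np.ndarray:
    """Vectorized alpha for every cell against its own cluster."""
    a = state.assignment
    thresh = state.mu_base[:, None] + state.delta[:, a] / 2.0      # (g, N)
    elevated = (instance.x_marker > thresh) & instance.spec.gamma[:, a]
    n_markers = instance.spec.gamma.sum(axis=0)[a].astype(float)   # (N,)
    return elevated.sum(axis=0) / n_markers


def partition_decided(
    alphas: np.ndarray, assignment: np.ndarray, alpha0: float = 0.5
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split every cluster into decided (alpha > alpha0) and undecided cells."""
    if not 0.0 <= alpha0 < 1.0:
        raise ValueError("alpha0 must lie in [0, 1)")
    K = int(assignment.max(initial=-1)) + 1
    decided, undecided = [], []
    for k in range(K):
        members = np.flatnonzero(assignment == k)
        inside = alphas[members] > alpha0
        decided.append(members[inside])
        undecided.append(members[~inside])
    return decided, undecided


def _dk_profile(
    instance: ProblemInstance, d_k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    xh = instance.x_nonmarker[:, d_k]
    nu = xh.mean(axis=1)
    sigma = np.maximum(xh.std(axis=1, ddof=1), _SIGMA_FLOOR)
    return nu, sigma


def compute_beta(
    instance: ProblemInstance, d_k: np.ndarray, cell: int
) -> float:
    """Chi-square CDF of the cell's squared z-distance to the D_k profile."""
    if d_k.size < 2:
        raise ValueError("need at least two decided cells to estimate nu, sigma")
    nu, sigma = _dk_profile(instance, d_k)
    z = (instance.x_nonmarker[:, cell] - nu) / sigma
    return float(chi2.cdf(z @ z, df=instance.h))


def select_theta(
    instance: ProblemInstance,
    d_k: np.ndarray,
    u_k: np.ndarray,
    betas: np.ndarray,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Pick the cutoff theta_k minimizing the two-group within-SS (S_k).

    ``betas`` aligns with ``u_k``.  S_k is piecewise constant between
    observed beta values, so evaluating it at the lower range endpoint, at
    every admissible observed beta, and at 1 is an exact search.  Ties go
    to the smallest theta.  Returns ``(theta, S_k, decided_star,
    undecided_star)`` with the final index sets.
    """
    h = instance.h
    lower = float(chi2.cdf(h + np.sqrt(2.0 * h), df=h))
    candidates = np.unique(
        np.concatenate(
            [[lower], betas[(betas >= lower) & (betas <= 1.0)], [1.0]]
        )
    )

    order = np.argsort(betas, kind="stable")
    sorted_b = betas[order]
    xh_d = instance.x_nonmarker[:, d_k]                           # (h, |D|)
    xh_u = instance.x_nonmarker[:, u_k[order]]                    # (h, |U|)

    # prefix sums over U sorted by beta: for a cutoff keeping the first m
    # cells in D*, group SS per gene follows from sum, sum of squares, count
    m_u = xh_u.shape[1]
    cs = np.concatenate([np.zeros((h, 1)), np.cumsum(xh_u, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((h, 1)), np.cumsum(xh_u**2, axis=1)], axis=1)
    sum_d, sum2_d, n_d = xh_d.sum(axis=1), (xh_d**2).sum(axis=1), d_k.size

    def s_at(m: int) -> float:
        nd = n_d + m
        s1 = sum_d + cs[:, m]
        s2 = sum2_d + cs2[:, m]
        ss_d = s2 - s1**2 / nd if nd else np.zeros(h)
        nu_ = m_u - m
        if nu_:
            s1u = cs[:, m_u] - cs[:, m]
            s2u = cs2[:, m_u] - cs2[:, m]
            ss_u = s2u - s1u**2 / nu_
        else:
            ss_u = np.zeros(h)
        return float(np.maximum(ss_d, 0).sum() + np.maximum(ss_u, 0).sum())

    best_theta, best_s = None, np.inf
    for theta in candidates:
        m = int(np.searchsorted(sorted_b, theta, side="right"))
        s = s_at(m)
        if best_theta is None or s < best_s - 1e-12 * (1.0 + abs(best_s)):
            best_theta, best_s = float(theta), s
    keep = int(np.searchsorted(sorted_b, best_theta, side="right"))
    decided_star = np.concatenate([d_k, u_k[order[:keep]]])
    undecided_star = u_k[order[keep:]]
    return best_theta, best_s, decided_star, undecided_star


def call_unknowns(
    instance: ProblemInstance,
    state: StepOneState,
    alpha0: float = 0.5,
) -> StepTwoResult:
    """Run the full unknown-calling stage on a converged clustering.

    Clusters with fewer than two decided cells skip the test (their cells
    keep the Step I label, with a logged warning); for them S_k falls back
    to the plain within-cluster sum of squares so the final cost remains
    comparable across restarts.
    """
    N, K = instance.N, instance.K
    alphas = _all_alphas(instance, state)
    decided, undecided = partition_decided(alphas, state.assignment, alpha0)
    while len(decided) < K:  # trailing empty clusters
        decided.append(np.array([], dtype=int))
        undecided.append(np.array([], dtype=int))

    beta = np.full(N, np.nan)
    theta = np.full(K, np.nan)
    s_k = np.zeros(K)
    unknown = np.zeros(N, dtype=bool)
    decided_mask = np.zeros(N, dtype=bool)

    for k in range(K):
        d_k, u_k = decided[k], undecided[k]
        decided_mask[d_k] = True
        members = np.concatenate([d_k, u_k])
        if members.size == 0:
            continue
        if d_k.size < 2:
            logger.warning(
                "cluster %d: only %d decided cells; skipping unknown-calling",
                k, d_k.size,
            )
            xh = instance.x_nonmarker[:, members]
            s_k[k] = float(((xh - xh.mean(axis=1, keepdims=True)) ** 2).sum())
            continue
        if u_k.size == 0:
            xh = instance.x_nonmarker[:, d_k]
            s_k[k] = float(((xh - xh.mean(axis=1, keepdims=True)) ** 2).sum())
            theta[k] = 1.0
            continue
        nu, sigma = _dk_profile(instance, d_k)
        z = (instance.x_nonmarker[:, u_k] - nu[:, None]) / sigma[:, None]
        d_stat = (z**2).sum(axis=0)
        betas = chi2.cdf(d_stat, df=instance.h)
        beta[u_k] = betas
        theta[k], s_k[k], _, u_star = select_theta(instance, d_k, u_k, betas)
        unknown[u_star] = True

    labels = [
        UNKNOWN_LABEL if unknown[j] else instance.spec.type_names[state.assignment[j]]
        for j in range(N)
    ]
    return StepTwoResult(
        alpha=alphas,
        decided_mask=decided_mask,
        beta=beta,
        theta=theta,
        s_k=s_k,
        labels=labels,
        unknown_mask=unknown,
    )
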