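"""Scikit-learn-style estimator wrapping the full two-step procedure.

``CellSorter`` follows the clusterer protocol: ``fit(X)`` on a cells x
genes frame learns the marker base/elevated levels, cluster centroids and
unknown-calling thresholds; ``labels_`` holds the final per-cell call
(a declared type name or ``"Unknown"``).  ``predict(X_new)`` types new
cells against the fitted model.  The estimator composes with sklearn
``clone``/``get_params``/``set_params`` and pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, ProblemInstance
from .pipeline import SortResult, run_pipeline
from .preprocess import build_design
from .step1 import cost_matrix
from .step2 import UNKNOWN_LABEL

__all__ = ["CellSorter"]


class CellSorter(ClusterMixin, BaseEstimator):
    """Semi-supervised cell-type assignment from marker genes.

    Parameters
    ----------
    markers : dict[str, list[str]] or DataFrame
        Known cell types and their marker genes; a DataFrame needs columns
        ``type, gene`` and may carry per-marker ``weight``.
    w0 : float, default 2.0
        Overall marker weight: with the constant rule every marker weight
        is ``w0 * h / g``, so the marker panel contributes ``w0`` times
        the non-marker panel to the clustering objective.
    alpha0 : float, default 0.5
        Decided/undecided split: a cell is decided for its cluster when
        more than ``alpha0`` of the cluster's markers are elevated in it.
    n_restarts : int, default 10
        Random initializations; the restart with the lowest final cost wins.
    max_iter : int, default 100
        Cap on outer alternating iterations per restart.
    hvg : list of str, optional
        Non-marker gene panel. If None, all non-marker columns of X are used
        (callers typically pass a pre-selected highly-variable panel).
    random_state : int, default 0
        Base seed; restart r uses ``random_state + r``.

    Attributes
    ----------
    labels_ : list of str
        Final label per fitted cell (type name or ``"Unknown"``).
    mu_base_ : ndarray of shape (g,)
        Marker base levels.
    delta_ : ndarray of shape (g, K)
        Marker elevations (0 where a gene does not mark a type).
    nonmarker_centroids_ : ndarray of shape (h, K)
        Per-cluster centroids of the non-marker genes.
    theta_ : ndarray of shape (K,)
        Per-cluster unknown-calling cutoffs on the chi-square CDF scale.
    restart_costs_ : list of float
        Final cost of every restart; ``chosen_restart_`` indexes the winner.

    Examples
    --------
    >>> sorter = CellSorter(markers={"B": ["CD79A"], "T": ["CD3D"]})
    >>> labels = sorter.fit_predict(logexpr_cells_by_genes)   # doctest: +SKIP
    """

    def __init__(
        self,
        markers=None,
        w0: float = 2.0,
        alpha0: float = 0.5,
        n_restarts: int = 10,
        max_iter: int = 100,
        hvg=None,
        random_state: int = 0,
    ):
        self.markers = markers
        self.w0 = w0
        self.alpha0 = alpha0
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.hvg = hvg
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _as_expression(self, X) -> ExpressionMatrix:
        """Accept a cells x genes DataFrame (or array) of log expression."""
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns.astype(str))
            cells = list(X.index.astype(str))
            values = X.to_numpy(dtype=float).T
        else:
            X = np.asarray(X, dtype=float)
            genes = [f"gene{i}" for i in range(X.shape[1])]
            cells = [f"cell{j}" for j in range(X.shape[0])]
            values = X.T
        return ExpressionMatrix(values, genes, cells, is_lognorm=True)

    def _build_instance(self, X) -> ProblemInstance:
        if self.markers is None:
            raise ValueError("CellSorter requires a marker specification")
        expr = self._as_expression(X)
        hvg = self.hvg
        if hvg is None:
            marker_genes = (
                set(self.markers["gene"].astype(str))
                if isinstance(self.markers, pd.DataFrame)
                else {g for gs in self.markers.values() for g in gs}
            )
            hvg = [g for g in expr.gene_ids if g not in marker_genes]
        return build_design(expr, self.markers, hvg=hvg, w0=self.w0)

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y=None) -> "CellSorter":
        """Fit the two-step model on cells x genes log expression."""
        instance = self._build_instance(X)
        result: SortResult = run_pipeline(
            instance,
            n_restarts=self.n_restarts,
            base_seed=self.random_state,
            alpha0=self.alpha0,
            max_iter=self.max_iter,
        )
        self.instance_ = instance
        self.result_ = result
        self.labels_ = result.labels
        self.type_names_ = list(instance.spec.type_names)
        self.mu_base_ = result.step1.mu_base
        self.delta_ = result.step1.delta
        self.nonmarker_centroids_ = result.step1.mu_nonmarker
        self.theta_ = result.step2.theta
        self.alpha_ = result.step2.alpha
        self.beta_ = result.step2.beta
        self.restart_costs_ = result.restart_costs
        self.chosen_restart_ = result.chosen_restart
        self.n_iter_ = result.step1.n_iter
        self.cost_ = result.step1.cost
        # frozen D_k profiles for predict()
        self._dk_profiles = {}
        assignment = result.step1.assignment
        for k in range(instance.K):
            d_k = np.flatnonzero(
                (assignment == k) & result.step2.decided_mask
            )
            if d_k.size >= 2:
                xh = instance.x_nonmarker[:, d_k]
                self._dk_profiles[k] = (
                    xh.mean(axis=1),
                    np.maximum(xh.std(axis=1, ddof=1), 1e-6),
                )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    def predict(self, X):
        """Type new cells against the fitted parameters.

        Each cell goes to its cheapest cluster under the fitted levels and
        centroids; it is then screened exactly as in fitting, using the
        frozen decided-cell profiles and per-cluster cutoffs.
        """
        check_is_fitted(self, "labels_")
        expr = self._as_expression(X).subset_genes(self.instance_.expr.gene_ids)
        inst = ProblemInstance(
            expr=expr,
            spec=self.instance_.spec,
            g=self.instance_.g,
            h=self.instance_.h,
            w0=self.instance_.w0,
        )
        s1 = self.result_.step1
        cm = cost_matrix(inst, s1.mu_base, s1.delta, s1.mu_nonmarker)
        assignment = np.argmin(cm, axis=1)
        labels = []
        gamma = inst.spec.gamma
        for j, k in enumerate(assignment):
            idx = np.flatnonzero(gamma[:, k])
            x = inst.x_marker[idx, j]
            alpha = float(
                (x > s1.mu_base[idx] + s1.delta[idx, k] / 2.0).mean()
            )
            if alpha > self.alpha0 or k not in self._dk_profiles:
                labels.append(self.type_names_[k])
                continue
            nu, sigma = self._dk_profiles[k]
            z = (inst.x_nonmarker[:, j] - nu) / sigma
            beta = float(chi2.cdf(z @ z, df=inst.h))
            theta = self.theta_[k]
            if np.isnan(theta) or beta <= theta:
                labels.append(self.type_names_[k])
            else:
                labels.append(UNKNOWN_LABEL)
        return labels
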