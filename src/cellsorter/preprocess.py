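"""Normalization, highly-variable-gene selection, and design construction.

``log_normalize`` applies the standard library-size log-normalization
x' = ln(1 + x / libsize * scale).  ``select_hvg`` ranks genes by the
variance of their standardized expression (values standardized per gene and
clipped at sqrt(N), a common dispersion-stabilizing practice); a
user-supplied HVG list is always the more faithful path and takes
precedence in :func:`build_design`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MarkerSpec, ProblemInstance

logger = logging.getLogger(__name__)

__all__ = ["log_normalize", "select_hvg", "build_design"]


def log_normalize(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize raw counts and log-transform.

    Each count is divided by the cell's total count, multiplied by
    ``scale`` (default 1e4) and passed through ln(1 + .).  Output is
    invariant to per-cell count scaling.
    """
    if expr.is_lognorm:
        raise ValueError("expression is already log-normalized")
    colsums = expr.values.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        names = [expr.cell_ids[j] for j in zero[:10]]
        raise ValueError(f"cells with zero total count: {names}")
    out = np.log1p(expr.values / colsums * scale)
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.cell_ids), True)


def select_hvg(
    expr: ExpressionMatrix,
    n_hvg: int = 2000,
    exclude: set[str] | None = None,
) -> list[str]:
    """Rank genes by standardized variance and return the top ``n_hvg``.

    Per gene, values are standardized (z-scores against the gene's own mean
    and sd) and clipped at sqrt(N); the ranking statistic is the variance of
    the clipped values. Constant genes score 0.  Deterministic: ties are
    broken by lexicographic gene id.
    """
    exclude = set() if exclude is None else set(exclude)
    x = expr.values
    n = expr.n_cells
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    z = np.clip(z, -np.sqrt(n), np.sqrt(n))
    stat = z.var(axis=1, ddof=1)
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    order = sorted(
        (g for g in expr.gene_ids if g not in exclude),
        key=lambda g: (-stat[idx[g]], g),
    )
    if not order:
        raise ValueError("no genes remain after exclusion")
    return order[:n_hvg]


def build_design(
    expr: ExpressionMatrix,
    markers: pd.DataFrame | dict[str, list[str]],
    hvg: list[str] | None = None,
    w0: float = 2.0,
    n_hvg: int = 2000,
) -> ProblemInstance:
    """Assemble the ordered marker-first problem the solver consumes.

    Marker genes absent from the matrix are dropped with a warning; a type
    whose markers are all absent is an error.  When ``hvg`` is None the
    non-marker panel is chosen by :func:`select_hvg`.  Per-marker weights
    may be given via a ``weight`` column in a marker table; otherwise every
    weight is the constant ``w0 * h / g``, so the marker panel contributes
    ``w0`` times the non-marker panel to the objective.
    """
    if not expr.is_lognorm:
        raise ValueError("build_design expects log-normalized expression")
    if isinstance(markers, dict):
        table = pd.DataFrame(
            [{"type": t, "gene": g} for t, gs in markers.items() for g in gs]
        )
    else:
        table = markers.copy()
        table.columns = [c.lower() for c in table.columns]

    present = set(expr.gene_ids)
    missing = sorted(set(table["gene"].astype(str)) - present)
    if missing:
        logger.warning("dropping %d marker genes absent from matrix: %s",
                       len(missing), missing)
        kept = table[table["gene"].astype(str).isin(present)]
        lost_types = sorted(
            set(table["type"].astype(str)) - set(kept["type"].astype(str))
        )
        if lost_types:
            raise ValueError(
                f"cell types with no marker gene present in the matrix: {lost_types}"
            )
        table = kept
    marker_ids = list(dict.fromkeys(table["gene"].astype(str)))

    if hvg is None:
        hvg = select_hvg(expr, n_hvg=n_hvg, exclude=set(marker_ids))
    else:
        hvg = [g for g in hvg if g in present and g not in set(marker_ids)]
    if len(hvg) < 1:
        raise ValueError("no non-marker (HVG) genes available; h must be >= 1")

    spec = MarkerSpec.from_table(table, h=len(hvg), w0=w0)
    ordered = expr.subset_genes(marker_ids + list(hvg))
    return ProblemInstance(
        expr=ordered, spec=spec, g=len(marker_ids), h=len(hvg), w0=w0
    )
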