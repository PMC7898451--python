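"""Core data containers shared by every stage of the pipeline.

The method works on a genes x cells expression matrix together with a
marker-gene specification: for each of the K known cell types, a short list
of genes believed to be over-expressed in that type.  Internally the gene
panel is reordered so the g marker genes come first and the h non-marker
(highly variable) genes follow; that ordered view, together with the
per-(gene, type) weights, is a :class:`ProblemInstance`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "MarkerSpec", "ProblemInstance"]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` float array; rows are genes.
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    is_lognorm
        Whether ``values`` are already log-normalized (non-negative log
        expression) rather than raw counts.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_lognorm: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.is_lognorm and np.any(self.values < 0):
            raise ValueError("log-normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Restrict and reorder to the given genes (all must be present)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [lookup[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows], list(gene_ids), list(self.cell_ids), self.is_lognorm
        )


@dataclass
class MarkerSpec:
    """Marker-gene membership and weights: which gene marks which type.

    ``gamma`` is the g x K binary indicator (gene i is a marker of type k);
    a gene may mark several types.  ``weights`` is the positive g x K weight
    matrix applied to the marker-gene cost terms; :meth:`constant_weights`
    builds the standard choice ``w0 * h / g`` for every entry, under which
    the g marker genes jointly carry ``w0`` times the weight of the h
    non-marker genes.
    """

    type_names: list[str]
    marker_gene_ids: list[str]
    gamma: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.type_names = [str(t) for t in self.type_names]
        self.marker_gene_ids = [str(g) for g in self.marker_gene_ids]
        self.gamma = np.asarray(self.gamma, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        _check_unique(self.type_names, "type names")
        _check_unique(self.marker_gene_ids, "marker gene ids")
        g, k = len(self.marker_gene_ids), len(self.type_names)
        if self.gamma.shape != (g, k):
            raise ValueError(f"gamma must be {g}x{k}, got {self.gamma.shape}")
        if self.weights.shape != (g, k):
            raise ValueError(f"weights must be {g}x{k}, got {self.weights.shape}")
        if np.any(self.weights <= 0):
            raise ValueError("all marker weights must be strictly positive")
        if g > 0:
            if not np.all(self.gamma.sum(axis=1) >= 1):
                orphans = [
                    self.marker_gene_ids[i]
                    for i in np.flatnonzero(self.gamma.sum(axis=1) == 0)
                ]
                raise ValueError(f"marker genes marking no type: {orphans}")
            if not np.all(self.gamma.sum(axis=0) >= 1):
                empty = [
                    self.type_names[j]
                    for j in np.flatnonzero(self.gamma.sum(axis=0) == 0)
                ]
                raise ValueError(f"cell types with no marker gene: {empty}")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        h: int,
        w0: float = 2.0,
    ) -> "MarkerSpec":
        """Build from a long table with columns ``type, gene[, weight]``.

        Rows without an explicit weight get the constant rule ``w0 * h / g``.
        """
        table = table.copy()
        table.columns = [c.lower() for c in table.columns]
        if not {"type", "gene"}.issubset(table.columns):
            raise ValueError("marker table needs 'type' and 'gene' columns")
        types = list(dict.fromkeys(table["type"].astype(str)))
        genes = list(dict.fromkeys(table["gene"].astype(str)))
        g = len(genes)
        gamma = np.zeros((g, len(types)), dtype=bool)
        const = w0 * h / g if g else 0.0
        weights = np.full((g, len(types)), const if g else 1.0)
        gi = {x: i for i, x in enumerate(genes)}
        ti = {x: i for i, x in enumerate(types)}
        for _, row in table.iterrows():
            i, k = gi[str(row["gene"])], ti[str(row["type"])]
            gamma[i, k] = True
            if "weight" in table.columns and pd.notna(row.get("weight")):
                weights[i, k] = float(row["weight"])
        return cls(types, genes, gamma, weights)

    @classmethod
    def constant_weights(
        cls,
        markers: dict[str, list[str]],
        h: int,
        w0: float = 2.0,
    ) -> "MarkerSpec":
        """Build from a ``{type: [genes]}`` dict with the w0*h/g weight rule."""
        rows = [
            {"type": t, "gene": g} for t, gs in markers.items() for g in gs
        ]
        return cls.from_table(pd.DataFrame(rows), h=h, w0=w0)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def n_markers(self) -> int:
        return len(self.marker_gene_ids)


@dataclass
class ProblemInstance:
    """The ordered problem the solver consumes.

    The expression matrix is restricted to the g marker genes (first) and
    h non-marker genes (after), matching the convention that x[:g] carries
    the marker panel and x[g:g+h] the highly variable genes.
    """

    expr: ExpressionMatrix
    spec: MarkerSpec
    g: int
    h: int
    w0: float | None = 2.0

    def __post_init__(self) -> None:
        if self.g + self.h != self.expr.n_genes:
            raise ValueError("g + h must equal the number of genes in expr")
        if self.h < 1:
            raise ValueError(
                "at least one non-marker gene is required (h >= 1): the "
                "unknown-cell chi-square test has h degrees of freedom"
            )
        if self.expr.gene_ids[: self.g] != self.spec.marker_gene_ids:
            raise ValueError("first g genes must be the marker genes, in order")
        overlap = set(self.expr.gene_ids[self.g :]) & set(self.spec.marker_gene_ids)
        if overlap:
            raise ValueError(f"non-marker rows contain marker genes: {sorted(overlap)}")

    @property
    def N(self) -> int:
        return self.expr.n_cells

    @property
    def K(self) -> int:
        return self.spec.n_types

    @property
    def x_marker(self) -> np.ndarray:
        """(g, N) view of marker-gene expression."""
        return self.expr.values[: self.g]

    @property
    def x_nonmarker(self) -> np.ndarray:
        """(h, N) view of non-marker-gene expression."""
        return self.expr.values[self.g :]
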