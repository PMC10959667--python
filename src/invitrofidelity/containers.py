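"""Core in-memory containers shared across the pipeline.

All expression matrices are stored gene-major (genes x cells), matching the
orientation of 10x-style Matrix-Market triplets. Cell-major views needed by
scikit-learn are produced by transposition at call sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ParameterError(ValueError):
    """Out-of-range or inconsistent parameter values."""


@dataclass
class CountMatrix:
    """Sparse raw-count matrix with gene/cell identifiers.

    Parameters
    ----------
    genes : ordered unique gene identifiers (rows).
    cells : ordered unique cell barcodes (columns).
    counts : sparse non-negative integer matrix, shape (n_genes, n_cells).
    sample_of_cell : mapping cell -> sample name (one sample per cell).
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    sample_of_cell: pd.Series

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise DataError("duplicate cell identifiers")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("negative counts")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise DataError("non-integral counts")
        if not isinstance(self.sample_of_cell, pd.Series):
            self.sample_of_cell = pd.Series(dict(self.sample_of_cell))
        missing = set(self.cells) - set(self.sample_of_cell.index)
        if missing:
            raise DataError(f"{len(missing)} cells lack a sample assignment")
        self.sample_of_cell = self.sample_of_cell.loc[self.cells]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_of_cell.unique())

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted by boolean masks or id lists."""
        gidx = _as_index(gene_mask, self.genes)
        cidx = _as_index(cell_mask, self.cells)
        counts = self.counts
        if gidx is not None:
            counts = counts[gidx, :]
        if cidx is not None:
            counts = counts[:, cidx]
        genes = [self.genes[i] for i in gidx] if gidx is not None else list(self.genes)
        cells = [self.cells[i] for i in cidx] if cidx is not None else list(self.cells)
        return CountMatrix(genes, cells, counts, self.sample_of_cell.loc[cells])


def _as_index(mask, ids: Sequence[str]):
    if mask is None:
        return None
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape[0] != len(ids):
            raise DataError("mask length mismatch")
        return np.flatnonzero(mask)
    if mask.dtype.kind in "iu":
        return mask
    lookup = {g: i for i, g in enumerate(ids)}
    return np.array([lookup[m] for m in mask], dtype=int)


@dataclass
class ResidualMatrix:
    """Dense matrix of clipped, covariate-regressed Pearson residuals."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # (n_genes, n_cells), float64
    clip_bound: float
    sample_of_cell: pd.Series

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DataError("residual matrix shape mismatch")
        if self.clip_bound <= 0:
            raise ParameterError("clip bound must be positive")
        if np.abs(self.values).max(initial=0.0) > self.clip_bound + 1e-12:
            raise DataError("residuals exceed the declared clip bound")
        if not isinstance(self.sample_of_cell, pd.Series):
            self.sample_of_cell = pd.Series(dict(self.sample_of_cell))
        self.sample_of_cell = self.sample_of_cell.loc[self.cells]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ResidualMatrix":
        idx = _as_index(list(cell_ids), self.cells)
        return ResidualMatrix(
            list(self.genes),
            [self.cells[i] for i in idx],
            self.values[:, idx],
            self.clip_bound,
            self.sample_of_cell.iloc[idx],
        )


@dataclass(frozen=True)
class GeneSignature:
    """Named, directed gene set with provenance."""

    name: str
    genes: frozenset[str]
    direction: str = "up"
    source: str = "query-cluster"
    thresholds: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClusterAssignment:
    """Cell -> cluster label mapping for one clustering level."""

    labels: pd.Series  # index: cell ids, values: str labels
    resolution: float
    seed: int
    parent_cluster: str | None = None

    def __post_init__(self):
        self.labels = self.labels.astype(str)

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.labels.unique())

    def cells_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class SimilarityTable:
    """Query-group x reference-group score matrix with its metric tag."""

    scores: pd.DataFrame  # rows: query labels, cols: reference labels
    metric: str
    gene_basis: list[str] = field(default_factory=list)

    VALID_METRICS = ("jaccard", "overlap_vs_reference", "cosine")

    def __post_init__(self):
        if self.metric not in self.VALID_METRICS:
            raise ParameterError(f"unknown metric {self.metric!r}")

    def best_match(self, tie_label: str = "ambiguous") -> pd.Series:
        """Per-query argmax over references; exact ties -> tie_label."""
        out = {}
        for q, row in self.scores.iterrows():
            top = row.max()
            winners = row.index[row == top]
            out[q] = winners[0] if len(winners) == 1 else tie_label
        return pd.Series(out, name="best_match")
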