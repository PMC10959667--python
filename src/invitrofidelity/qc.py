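"""Per-sample cell and gene quality control on raw counts.

Boundary semantics: cells pass at equality of the UMI and detected-gene
minima and at equality of the mitochondrial-fraction maximum; genes are kept
when expressed in at least ``min_cells_per_gene`` cells (strictly fewer are
dropped). Gene filtering is evaluated per sample and the kept sets are
intersected so the merged matrix has a common gene universe.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, DataError, ParameterError


@dataclass
class QCThresholds:
    """Cell/gene QC thresholds; ``min_umi``/``min_genes`` may vary by sample.

    Scalars apply to every sample; a mapping must cover every sample present.
    """

    min_umi: int | Mapping[str, int] = 2250
    min_genes: int | Mapping[str, int] = 770
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 5

    def __post_init__(self):
        if not 0 <= self.max_mito_fraction <= 1:
            raise ParameterError("max_mito_fraction must lie in [0, 1]")
        if self.min_cells_per_gene < 1:
            raise ParameterError("min_cells_per_gene must be >= 1")
        for name, v in [("min_umi", self.min_umi), ("min_genes", self.min_genes)]:
            vals = v.values() if isinstance(v, Mapping) else [v]
            if any(x < 0 for x in vals):
                raise ParameterError(f"{name} must be non-negative")

    def umi_for(self, sample: str) -> int:
        return _per_sample(self.min_umi, sample, "min_umi")

    def genes_for(self, sample: str) -> int:
        return _per_sample(self.min_genes, sample, "min_genes")


def _per_sample(value, sample: str, name: str) -> int:
    if isinstance(value, Mapping):
        if sample not in value:
            raise ParameterError(f"no {name} threshold configured for sample {sample!r}")
        return value[sample]
    return value


def compute_qc_metrics(cm: CountMatrix, mito_genes: set[str]) -> pd.DataFrame:
    """Per-cell UMI total, detected genes and mitochondrial fraction.

    ``mito_fraction`` is 0 for all-zero cells. Returns a DataFrame indexed by
    cell id with columns umi_total, genes_detected, mito_fraction.
    """
    if cm.n_genes == 0 or cm.n_cells == 0:
        raise DataError("empty count matrix")
    missing = set(mito_genes) - set(cm.genes)
    if missing:
        warnings.warn(f"{len(missing)} mito genes absent from the gene universe")
    csc = cm.counts.tocsc()
    umi = np.asarray(csc.sum(axis=0)).ravel()
    detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    mito_mask = np.array([g in mito_genes for g in cm.genes])
    mito_umi = (
        np.asarray(csc[mito_mask, :].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros(cm.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito_umi / np.where(umi > 0, umi, 1), 0.0)
    return pd.DataFrame(
        {
            "umi_total": umi.astype(int),
            "genes_detected": detected.astype(int),
            "mito_fraction": mito_frac,
        },
        index=cm.cells,
    )


def filter_cells(
    records: pd.DataFrame, thresholds: QCThresholds, sample_of_cell: pd.Series
) -> pd.Series:
    """Boolean pass mask per cell (index-aligned with ``records``)."""
    samples = sample_of_cell.loc[records.index]
    min_umi = samples.map(lambda s: thresholds.umi_for(s))
    min_genes = samples.map(lambda s: thresholds.genes_for(s))
    passed = (
        (records["umi_total"] >= min_umi)
        & (records["genes_detected"] >= min_genes)
        & (records["mito_fraction"] <= thresholds.max_mito_fraction)
    )
    return passed.rename("pass")


def filter_genes(cm: CountMatrix, min_cells_per_gene: int = 5) -> np.ndarray:
    """Boolean keep mask per gene: expressed in >= ``min_cells_per_gene``
    cells within every sample (per-sample evaluation, intersected)."""
    if min_cells_per_gene < 1:
        raise ParameterError("min_cells_per_gene must be >= 1")
    csr = cm.counts.tocsr()
    keep = np.ones(cm.n_genes, dtype=bool)
    sample_arr = cm.sample_of_cell.loc[cm.cells].values
    for s in np.unique(sample_arr):
        cols = np.flatnonzero(sample_arr == s)
        n_expr = np.asarray((csr[:, cols] > 0).sum(axis=1)).ravel()
        keep &= n_expr >= min_cells_per_gene
    return keep


def apply_qc(
    cm: CountMatrix,
    thresholds: QCThresholds,
    mito_genes: set[str],
    doublet_flags: pd.Series | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Full QC pass: metrics -> drop flagged doublets -> cell filter ->
    per-sample gene filter. Returns the filtered matrix and the QC report
    (all input cells, with a ``pass`` column)."""
    records = compute_qc_metrics(cm, mito_genes)
    passed = filter_cells(records, thresholds, cm.sample_of_cell)
    if doublet_flags is not None:
        passed &= ~doublet_flags.reindex(passed.index, fill_value=False).astype(bool)
    report = records.assign(**{"pass": passed})
    kept = cm.subset(cell_mask=passed.values)
    gene_keep = filter_genes(kept, thresholds.min_cells_per_gene)
    return kept.subset(gene_mask=gene_keep), report
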