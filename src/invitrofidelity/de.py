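"""Marker extraction: one-vs-rest Wilcoxon rank-sum tests, BH correction,
signature thresholding and marker-dictionary cluster annotation.

The rank-sum statistic is computed on the corrected (residual) layer; the
fold change is computed on library-size-normalized counts (counts per 10k)
with a 1e-9 pseudocount, since residuals can be negative. Adjusted p-values
are Benjamini-Hochberg within each cluster's gene scan.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    ClusterAssignment,
    CountMatrix,
    GeneSignature,
    ParameterError,
    ResidualMatrix,
)
from .normalize import log_normalize

LOG2FC_EPS = 1e-9


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_de(
    cm: CountMatrix,
    res: ResidualMatrix,
    assignment: ClusterAssignment,
) -> pd.DataFrame:
    """One-vs-rest rank-sum DE for every cluster.

    Returns a long DataFrame with columns gene, cluster, log2fc, u_statistic,
    p_value, p_adjusted, frac_expr_in, frac_expr_out. Clusters with fewer
    than 2 cells are skipped with a warning. Genes with identical values in
    both groups (e.g. all-zero genes) get p = 1 and log2fc from the means.
    """
    cells = list(res.cells)
    labels = assignment.labels.loc[cells].values
    stat_layer = res.values  # genes x cells
    cm_aligned = cm.subset(gene_mask=list(res.genes), cell_mask=cells)
    norm_layer = log_normalize(cm_aligned)  # genes x cells, CP10K
    raw = cm_aligned.counts.toarray()
    out_frames = []
    for cl in sorted(pd.unique(labels)):
        in_mask = labels == cl
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 2 or n_out < 2:
            warnings.warn(f"cluster {cl!r} has fewer than 2 cells on a side; skipped")
            continue
        x_in = stat_layer[:, in_mask]
        x_out = stat_layer[:, ~in_mask]
        degenerate = np.all(x_in == x_in[:, :1], axis=1) & np.all(
            x_out == x_in[:, :1], axis=1
        )
        # exact null distribution for small tie-free groups, tie-corrected
        # normal approximation otherwise (scipy's "auto" policy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            u, p = stats.mannwhitneyu(
                x_in, x_out, axis=1, alternative="two-sided", method="auto"
            )
        p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
        mean_in = norm_layer[:, in_mask].mean(axis=1)
        mean_out = norm_layer[:, ~in_mask].mean(axis=1)
        log2fc = np.where(
            degenerate & (mean_in == mean_out),
            0.0,
            np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS)),
        )
        frac_in = (raw[:, in_mask] > 0).mean(axis=1)
        frac_out = (raw[:, ~in_mask] > 0).mean(axis=1)
        out_frames.append(
            pd.DataFrame(
                {
                    "gene": res.genes,
                    "cluster": cl,
                    "log2fc": log2fc,
                    "u_statistic": u,
                    "p_value": p,
                    "p_adjusted": bh_adjust(p),
                    "frac_expr_in": frac_in,
                    "frac_expr_out": frac_out,
                }
            )
        )
    if not out_frames:
        raise ParameterError("no cluster had enough cells for DE")
    return pd.concat(out_frames, ignore_index=True)


def extract_signature(
    de: pd.DataFrame,
    cluster: str,
    lfc_min: float = 2.0,
    padj_max: float = 0.01,
    source: str = "query-cluster",
) -> GeneSignature:
    """Up-regulated signature: log2fc strictly > lfc_min and adjusted p
    strictly < padj_max. May be empty."""
    sub = de[de["cluster"] == cluster]
    if sub.empty:
        raise ParameterError(f"cluster {cluster!r} absent from the DE table")
    hits = sub[(sub["log2fc"] > lfc_min) & (sub["p_adjusted"] < padj_max)]
    return GeneSignature(
        name=str(cluster),
        genes=frozenset(hits["gene"]),
        direction="up",
        source=source,
        thresholds=(lfc_min, padj_max),
    )


def annotate_clusters(
    cm: CountMatrix,
    values: np.ndarray,
    genes: list[str],
    assignment: ClusterAssignment,
    markers: dict[str, list[str]],
    floor: float = 0.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign a cell-type label to each cluster from a marker dictionary.

    Score(cluster, type) = mean over the type's markers of the per-gene
    z-scored cluster-mean expression. The label is the argmax; ties are broken
    by the higher mean fraction of cells expressing the markers, then by
    lexicographic type name. Clusters whose top score is below ``floor`` are
    labeled "unassigned". Returns (labels, full score table).
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    marker_idx = {}
    for t, ms in markers.items():
        present = [gene_index[g] for g in ms if g in gene_index]
        if not ms:
            raise ParameterError(f"cell type {t!r} has no markers")
        marker_idx[t] = present
    if not any(marker_idx.values()):
        raise ParameterError("no marker gene found in the gene universe")
    dup = {}
    for t, ms in markers.items():
        key = frozenset(ms)
        dup.setdefault(key, []).append(t)
    if any(len(v) > 1 for v in dup.values()):
        warnings.warn("identical marker lists for multiple cell types; ties broken lexicographically")

    clusters = assignment.cluster_names
    cells = list(cm.cells)
    labels_arr = assignment.labels.loc[cells].values
    # cluster-mean expression per gene, z-scored across clusters
    means = np.stack(
        [values[:, labels_arr == cl].mean(axis=1) for cl in clusters], axis=1
    )  # genes x clusters
    sd = means.std(axis=1, keepdims=True)
    center = means.mean(axis=1, keepdims=True)
    z = np.where(sd > 0, (means - center) / np.where(sd > 0, sd, 1.0), 0.0)

    raw = cm.counts.toarray()
    score_rows, frac_rows = [], []
    for ci, cl in enumerate(clusters):
        in_mask = labels_arr == cl
        srow, frow = {}, {}
        for t in sorted(markers):
            idx = marker_idx[t]
            if idx:
                srow[t] = float(z[idx, ci].mean())
                frow[t] = float((raw[np.ix_(idx, np.flatnonzero(in_mask))] > 0).mean())
            else:
                srow[t] = -np.inf
                frow[t] = 0.0
        score_rows.append(srow)
        frac_rows.append(frow)
    score_table = pd.DataFrame(score_rows, index=clusters)
    frac_table = pd.DataFrame(frac_rows, index=clusters)

    out = {}
    for cl in clusters:
        row = score_table.loc[cl]
        top = row.max()
        if top < floor:
            out[cl] = "unassigned"
            continue
        winners = sorted(row.index[row == top])
        if len(winners) > 1:
            fr = frac_table.loc[cl, winners]
            winners = sorted(fr.index[fr == fr.max()])
        out[cl] = winners[0]
    return pd.Series(out, name="cell_type"), score_table
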