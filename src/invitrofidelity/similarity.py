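"""Comparison statistics: gene-set overlap attribution, centroid cosine
similarity against labeled references, and prevalence-threshold overlaps."""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    DataError,
    GeneSignature,
    ParameterError,
    ResidualMatrix,
    SimilarityTable,
)


def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty (convention)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_vs_reference(query_set, reference_set) -> float:
    """|query ∩ reference| / |reference| (size-normalized overlap)."""
    ref = set(reference_set)
    if not ref:
        raise ParameterError("reference set must be non-empty")
    return len(set(query_set) & ref) / len(ref)


def cosine(u, v) -> float:
    """Cosine similarity of two non-zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataError("cosine similarity is undefined for zero vectors")
    return float(u @ v / (nu * nv))


def origin_attribution(
    cluster_signatures: list[GeneSignature],
    line_signatures: tuple[GeneSignature, GeneSignature],
    metric: str = "overlap_vs_reference",
) -> tuple[SimilarityTable, pd.Series]:
    """Score each cluster signature against the two line signatures and call the
    conjectured line of origin per cluster (exact ties -> "ambiguous")."""
    if metric not in ("jaccard", "overlap_vs_reference"):
        raise ParameterError(f"unsupported origin metric {metric!r}")
    fn = jaccard if metric == "jaccard" else overlap_vs_reference
    rows = {}
    for sig in cluster_signatures:
        rows[sig.name] = {
            line.name: fn(sig.genes, line.genes) for line in line_signatures
        }
    table = SimilarityTable(pd.DataFrame(rows).T, metric=metric)
    return table, table.best_match()


def subset_centroids(
    res: ResidualMatrix, labels: pd.Series, gene_basis: list[str]
) -> pd.DataFrame:
    """Per-label mean residual vectors restricted to ``gene_basis``.

    Labels with fewer than 3 cells are kept but flagged with a warning.
    """
    if not gene_basis:
        raise ParameterError("gene_basis must be non-empty")
    gene_index = {g: i for i, g in enumerate(res.genes)}
    missing = [g for g in gene_basis if g not in gene_index]
    if missing:
        raise ParameterError(f"{len(missing)} basis genes absent from the matrix")
    idx = [gene_index[g] for g in gene_basis]
    lab = labels.loc[res.cells]
    out = {}
    for label in sorted(lab.unique()):
        cols = np.flatnonzero((lab == label).values)
        if len(cols) < 3:
            warnings.warn(f"label {label!r} has only {len(cols)} cells")
        out[label] = res.values[np.ix_(idx, cols)].mean(axis=1)
    return pd.DataFrame(out, index=gene_basis).T


def crc_similarity(
    query_centroids: pd.DataFrame,
    ref_centroids: pd.DataFrame,
    deg_union: list[str],
) -> SimilarityTable:
    """Cosine similarity of every (query, reference) centroid pair on the
    union-of-reference-DEGs basis. Genes missing from either centroid table
    are dropped from the basis with a warning, never imputed."""
    if not deg_union:
        raise ParameterError("deg_union must be non-empty")
    basis = [g for g in deg_union if g in query_centroids.columns and g in ref_centroids.columns]
    dropped = len(deg_union) - len(basis)
    if dropped:
        warnings.warn(f"dropped {dropped} basis genes missing from one universe")
    if not basis:
        raise ParameterError("no shared basis genes between query and reference")
    scores = pd.DataFrame(
        {
            r: {
                q: cosine(query_centroids.loc[q, basis], ref_centroids.loc[r, basis])
                for q in query_centroids.index
            }
            for r in ref_centroids.index
        }
    )
    return SimilarityTable(scores, metric="cosine", gene_basis=basis)


def prevalence_set(
    cm: CountMatrix, group_cells: list[str], tau: float = 0.30, label: str = "group"
) -> GeneSignature:
    """Genes with raw count > 0 in strictly more than ``tau`` of the group."""
    if not group_cells:
        raise ParameterError("group must be non-empty")
    if not 0 < tau < 1:
        raise ParameterError("tau must lie in (0, 1)")
    sub = cm.subset(cell_mask=list(group_cells))
    frac = np.asarray((sub.counts > 0).sum(axis=1)).ravel() / sub.n_cells
    genes = frozenset(g for g, f in zip(sub.genes, frac) if f > tau)
    return GeneSignature(
        name=label, genes=genes, direction="up", source="prevalence", thresholds=(tau,)
    )


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 named sets.

    Region keys join the member names with "&" (e.g. "A", "A&B", "A&B&C");
    each element is counted in exactly one region, so the region counts sum
    to the size of the union.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ParameterError("venn_counts supports exactly 2 or 3 sets")
    sets = {k: set(v) for k, v in sets.items()}
    out = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            out["&".join(combo)] = len(inside - outside)
    return out
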