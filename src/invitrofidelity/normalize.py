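"""Variance-stabilizing normalization and related per-cell scores.

The normalization produces analytic Pearson residuals under a negative
binomial null with expectation mu_gc = (gene total x cell total) / grand
total and a per-gene dispersion estimated by method of moments. Residuals are
clipped to +/- sqrt(n_cells) by default, then per-gene ordinary least squares
removes the stated cell-level covariates (mitochondrial fraction and the
S-minus-G2M cell-cycle score difference), and the result is re-clipped so the
clip bound holds unconditionally.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, DataError, ParameterError, ResidualMatrix

THETA_FLOOR = 1e-2
THETA_CAP = 1e6


class PearsonResidualNormalizer(TransformerMixin, BaseEstimator):
    """Analytic Pearson-residual normalization (cells x genes orientation).

    Parameters
    ----------
    theta : "mom" for per-gene method-of-moments dispersion (floored at 1e-2,
        capped at 1e6), or a positive float shared by all genes.
    clip : residual clip bound; None means sqrt(n_cells) of the fitted data.

    Attributes (after fit)
    ----------------------
    theta_ : per-gene dispersion, shape (n_genes,).
    gene_frac_ : per-gene share of the grand total, shape (n_genes,).
    clip_ : the effective clip bound.
    """

    def __init__(self, theta="mom", clip=None):
        self.theta = theta
        self.clip = clip

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise DataError("expected a non-empty 2-D cells x genes matrix")
        grand = X.sum()
        if grand <= 0:
            raise DataError("zero grand total")
        self.gene_frac_ = X.sum(axis=0) / grand
        if isinstance(self.theta, str):
            if self.theta != "mom":
                raise ParameterError(f"unknown theta mode {self.theta!r}")
            m = X.mean(axis=0)
            v = X.var(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                th = np.where(v > m, m**2 / np.maximum(v - m, 1e-300), THETA_CAP)
            self.theta_ = np.clip(th, THETA_FLOOR, THETA_CAP)
        else:
            if self.theta <= 0:
                raise ParameterError("theta must be strictly positive")
            self.theta_ = np.full(X.shape[1], float(self.theta))
        self.clip_ = float(self.clip) if self.clip is not None else float(np.sqrt(X.shape[0]))
        if self.clip_ <= 0:
            raise ParameterError("clip bound must be positive")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cell_tot = X.sum(axis=1, keepdims=True)
        mu = cell_tot * self.gene_frac_[None, :]
        denom = np.sqrt(mu + mu**2 / self.theta_[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (X - mu) / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(r, -self.clip_, self.clip_)


def regress_out(values: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-gene OLS of residuals (genes x cells) on cell covariates; returns
    the regression residuals (intercept included in the design)."""
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not np.isfinite(C).all():
        raise DataError("covariates must be finite")
    X = np.column_stack([np.ones(C.shape[0]), C])
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    return values - (X @ beta).T


def pearson_residual_normalize(
    cm: CountMatrix,
    covariates: pd.DataFrame | None = None,
    theta="mom",
    clip: float | None = None,
) -> ResidualMatrix:
    """Normalize a QC-filtered CountMatrix to covariate-regressed residuals."""
    norm = PearsonResidualNormalizer(theta=theta, clip=clip)
    dense = cm.counts.toarray().T.astype(float)  # cells x genes
    values = norm.fit(dense).transform(dense).T  # back to genes x cells
    if covariates is not None:
        cov = covariates.loc[cm.cells]
        values = regress_out(values, cov)
        values = np.clip(values, -norm.clip_, norm.clip_)
    return ResidualMatrix(list(cm.genes), list(cm.cells), values, norm.clip_, cm.sample_of_cell)


def center_by_sample(res: ResidualMatrix) -> ResidualMatrix:
    """Subtract the per-gene per-sample mean (batch-shift removal stand-in).

    Idempotent projection; clip bound is inherited (centered values are
    re-clipped in the rare case centering pushes one past the bound).
    """
    values = res.values.copy()
    sample_arr = res.sample_of_cell.loc[res.cells].values
    for s in np.unique(sample_arr):
        cols = np.flatnonzero(sample_arr == s)
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    values = np.clip(values, -res.clip_bound, res.clip_bound)
    return ResidualMatrix(list(res.genes), list(res.cells), values, res.clip_bound, res.sample_of_cell)


def log_normalize(cm: CountMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Library-size-normalized counts-per-``target_sum`` (genes x cells),
    without log transform; the DE fold change uses this layer."""
    dense = cm.counts.toarray().astype(float)
    tot = dense.sum(axis=0, keepdims=True)
    tot[tot == 0] = 1.0
    return dense / tot * target_sum


def module_score(
    values: np.ndarray,
    genes: list[str],
    gene_set: set[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    ctrl_genes: list[str] | None = None,
) -> np.ndarray:
    """Mean expression over ``gene_set`` minus mean over bin-matched controls.

    Genes are ranked by mean expression (log1p of the mean of the provided
    layer) and cut into ``n_bins`` equal-size bins; for each target gene,
    ``n_ctrl`` control genes are sampled with replacement (seeded) from its
    bin. ``ctrl_genes`` overrides the control pool entirely (used for
    self-control checks).
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    targets = sorted(g for g in gene_set if g in gene_index)
    if not targets:
        raise ParameterError("gene_set is disjoint from the gene universe")
    t_idx = np.array([gene_index[g] for g in targets])
    if ctrl_genes is not None:
        c_idx = np.array([gene_index[g] for g in ctrl_genes if g in gene_index])
    else:
        rng = np.random.default_rng(seed)
        mean_expr = np.log1p(np.maximum(values.mean(axis=1), 0))
        order = np.argsort(mean_expr, kind="stable")
        bin_of = np.empty(len(genes), dtype=int)
        bin_of[order] = np.arange(len(genes)) * n_bins // len(genes)
        picks = []
        for i in t_idx:
            pool = np.flatnonzero(bin_of == bin_of[i])
            picks.append(rng.choice(pool, size=n_ctrl, replace=True))
        c_idx = np.concatenate(picks)
    return values[t_idx].mean(axis=0) - values[c_idx].mean(axis=0)


def _set_seed(seed: int, gene_set: set[str]) -> int:
    import zlib

    return (seed ^ zlib.crc32(",".join(sorted(gene_set)).encode())) % (2**31)


def cell_cycle_scores(
    values: np.ndarray,
    genes: list[str],
    cells: list[str],
    s_genes: set[str],
    g2m_genes: set[str],
    seed: int = 0,
) -> pd.DataFrame:
    """S and G2M module scores and their difference per cell.

    ``cc_difference = s_score - g2m_score`` is the cell-cycle covariate
    regressed out during normalization. The control-draw seed for each set is
    derived from the set's content, so identical sets give identical scores
    and swapping the two sets negates the difference exactly.
    """
    s = module_score(values, genes, s_genes, seed=_set_seed(seed, s_genes))
    g2m = module_score(values, genes, g2m_genes, seed=_set_seed(seed, g2m_genes))
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "cc_difference": s - g2m}, index=cells
    )
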