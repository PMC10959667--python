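"""Synthetic data with known ground truth.

The generator emulates the data regime of a 10x-style co-culture experiment:
negative-binomial counts with gene-specific baseline abundances, lognormal
library sizes, population-specific marker up-regulation at known fold change,
a dedicated mitochondrial mass fraction per cell, additive per-sample batch
shifts on the log-mean, doublets formed by summing two parent cells, and a
replicate-free bulk expression pair with planted line-specific signatures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, DataError, ParameterError


@dataclass(frozen=True)
class Population:
    name: str
    n_cells: int
    marker_genes: frozenset[str]
    marker_log2fc: float

    def __post_init__(self):
        object.__setattr__(self, "marker_genes", frozenset(self.marker_genes))
        if self.n_cells <= 0:
            raise ParameterError(f"population {self.name}: n_cells must be positive")
        if self.marker_log2fc <= 0:
            raise ParameterError(f"population {self.name}: marker_log2fc must be positive")


@dataclass
class SimConfig:
    """Parameters of the single-cell count simulator.

    ``gene_ids`` is the full universe (regular genes plus ``mito_genes``);
    marker sets must be disjoint subsets of the non-mitochondrial genes.
    """

    n_genes: int
    populations: list[Population]
    gene_ids: list[str] = field(default_factory=list)
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion_theta: float = 10.0
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.35
    mito_genes: frozenset[str] = frozenset()
    mito_fraction_beta: tuple[float, float] = (2.0, 38.0)
    n_samples: int = 1
    batch_log_shift_sd: float = 0.0
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.populations:
            raise ParameterError("at least one population is required")
        self.populations = [
            p if isinstance(p, Population) else Population(*p) for p in self.populations
        ]
        self.mito_genes = frozenset(self.mito_genes)
        if not self.gene_ids:
            n_reg = self.n_genes - len(self.mito_genes)
            if n_reg < 0:
                raise ParameterError("more mito genes than genes")
            self.gene_ids = [f"G{i:05d}" for i in range(n_reg)] + sorted(self.mito_genes)
        if len(self.gene_ids) != self.n_genes:
            raise ParameterError("gene_ids length must equal n_genes")
        universe = set(self.gene_ids)
        if not self.mito_genes <= universe:
            raise ParameterError("mito_genes not in the gene universe")
        seen: set[str] = set()
        for p in self.populations:
            if not p.marker_genes <= universe - self.mito_genes:
                raise ParameterError(f"markers of {p.name} outside the non-mito universe")
            if p.marker_genes & seen:
                raise ParameterError("population marker sets must be pairwise disjoint")
            seen |= p.marker_genes
        for name, v in [
            ("baseline_log_sd", self.baseline_log_sd),
            ("dispersion_theta", self.dispersion_theta),
            ("libsize_log_sd", self.libsize_log_sd),
        ]:
            if v <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ParameterError("mito_fraction_beta shapes must be positive")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.batch_log_shift_sd < 0:
            raise ParameterError("batch_log_shift_sd must be non-negative")
        if not 0 <= self.doublet_rate <= 1:
            raise ParameterError("doublet_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    cell_labels: pd.Series  # cell -> population name
    doublet_flags: pd.Series  # cell -> bool
    batch_of_cell: pd.Series  # cell -> sample name
    true_bulk_signatures: tuple[frozenset[str], frozenset[str]] = (frozenset(), frozenset())

    def to_dict(self) -> dict:
        return {
            "cell_labels": self.cell_labels.to_dict(),
            "doublet_flags": {k: bool(v) for k, v in self.doublet_flags.items()},
            "batch_of_cell": self.batch_of_cell.to_dict(),
            "true_bulk_signatures": [sorted(s) for s in self.true_bulk_signatures],
        }


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB draws with mean ``mean`` and variance mean + mean^2/theta."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_bulk_pair(
    n_genes: int,
    n_sig_per_line: int,
    fold_log2: float,
    base_mean: float,
    theta: float,
    seed: int,
    gene_ids: list[str] | None = None,
):
    """Simulate a replicate-free bulk pair with planted line signatures.

    Signature genes of line A have mean ``base_mean * 2**fold_log2`` in A and
    ``base_mean * 2**-fold_log2`` in B (and symmetrically for line B); all
    other genes share ``base_mean`` in both profiles. ``fold_log2 = 0`` is the
    no-effect case: both signature sets are empty and the profiles are
    exchangeable draws from the same law.

    Returns (profile_A, profile_B, (sig_A_up, sig_B_up)) where profiles are
    pandas Series indexed by gene id.
    """
    if fold_log2 < 0:
        raise ParameterError("fold_log2 must be non-negative")
    if base_mean <= 0 or theta <= 0:
        raise ParameterError("base_mean and theta must be strictly positive")
    if n_sig_per_line < 0 or 2 * n_sig_per_line > n_genes:
        raise ParameterError("need 2 * n_sig_per_line <= n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")
    order = rng.permutation(n_genes)
    if fold_log2 > 0:
        sig_a_idx = order[:n_sig_per_line]
        sig_b_idx = order[n_sig_per_line : 2 * n_sig_per_line]
    else:
        sig_a_idx = np.array([], dtype=int)
        sig_b_idx = np.array([], dtype=int)
    mean_a = np.full(n_genes, float(base_mean))
    mean_b = np.full(n_genes, float(base_mean))
    mean_a[sig_a_idx] *= 2.0**fold_log2
    mean_b[sig_a_idx] *= 2.0**-fold_log2
    mean_b[sig_b_idx] *= 2.0**fold_log2
    mean_a[sig_b_idx] *= 2.0**-fold_log2
    prof_a = pd.Series(_nb_draws(rng, mean_a, theta), index=gene_ids)
    prof_b = pd.Series(_nb_draws(rng, mean_b, theta), index=gene_ids)
    sig_a = frozenset(gene_ids[i] for i in sig_a_idx)
    sig_b = frozenset(gene_ids[i] for i in sig_b_idx)
    return prof_a, prof_b, (sig_a, sig_b)


def simulate_sc_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a labeled single-cell count matrix.

    Per cell: library size ~ lognormal; relative gene abundance is the
    exp-normal baseline (with the per-sample batch shift applied on the
    log-mean and the population's marker genes multiplied by
    ``2**marker_log2fc``), renormalized so that non-mitochondrial genes carry
    mass ``1 - m`` and mitochondrial genes mass ``m ~ Beta(a, b)``; counts are
    NB with the configured dispersion. Doublets replace a ``doublet_rate``
    fraction of cells by the sum of two random parent cells' counts.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.gene_ids)
    gene_idx = {g: i for i, g in enumerate(genes)}
    mito_mask = np.array([g in config.mito_genes for g in genes])
    n_genes = len(genes)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    samples = [f"sample{i}" for i in range(config.n_samples)]
    batch_shift = {
        s: rng.normal(0.0, config.batch_log_shift_sd, n_genes)
        if config.batch_log_shift_sd > 0
        else np.zeros(n_genes)
        for s in samples
    }

    # per-population log2fc vector on the log scale
    pop_boost = {}
    for p in config.populations:
        boost = np.zeros(n_genes)
        for g in p.marker_genes:
            boost[gene_idx[g]] = p.marker_log2fc * np.log(2.0)
        pop_boost[p.name] = boost

    cell_ids, labels, batches = [], [], []
    for p in config.populations:
        for j in range(p.n_cells):
            cell_ids.append(f"{p.name}-c{j:04d}")
            labels.append(p.name)
    n_cells = len(cell_ids)
    batch_assign = rng.integers(0, config.n_samples, n_cells)
    batches = [samples[i] for i in batch_assign]

    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)
    a, b = config.mito_fraction_beta
    mito_frac = rng.beta(a, b, n_cells) if mito_mask.any() else np.zeros(n_cells)

    cols = np.empty((n_cells, n_genes), dtype=np.int64)
    for c in range(n_cells):
        logw = baseline + batch_shift[batches[c]] + pop_boost[labels[c]]
        w = np.exp(logw)
        p_rel = np.zeros(n_genes)
        w_non = w[~mito_mask]
        p_rel[~mito_mask] = (1.0 - mito_frac[c]) * w_non / w_non.sum()
        if mito_mask.any():
            w_mt = w[mito_mask]
            p_rel[mito_mask] = mito_frac[c] * w_mt / w_mt.sum()
        cols[c] = _nb_draws(rng, libsize[c] * p_rel, config.dispersion_theta)

    doublet = np.zeros(n_cells, dtype=bool)
    n_doub = int(round(config.doublet_rate * n_cells))
    if n_doub:
        doub_idx = rng.choice(n_cells, n_doub, replace=False)
        doublet[doub_idx] = True
        singlet_idx = np.flatnonzero(~doublet)
        for i in doub_idx:
            p1, p2 = rng.choice(singlet_idx, 2, replace=False)
            cols[i] = cols[p1] + cols[p2]

    cm = CountMatrix(
        genes,
        cell_ids,
        sp.csr_matrix(cols.T),
        pd.Series(batches, index=cell_ids),
    )
    gt = GroundTruth(
        cell_labels=pd.Series(labels, index=cell_ids),
        doublet_flags=pd.Series(doublet, index=cell_ids),
        batch_of_cell=pd.Series(batches, index=cell_ids),
    )
    return cm, gt


def simulate_reference_atlas(
    config: SimConfig, subtype_names: list[str]
) -> tuple[CountMatrix, pd.Series]:
    """Simulate a labeled reference atlas with subtype-specific markers.

    The configured populations are renamed to ``subtype_names`` one-to-one, so
    sharing a population's marker set with a query population plants a known
    best-match pair. Returns the labeled matrix and the cell -> subtype map.
    """
    if len(subtype_names) < 2:
        raise ParameterError("at least 2 subtypes are required")
    if len(subtype_names) != len(config.populations):
        raise ParameterError("need one configured population per subtype name")
    pops = [
        Population(name, p.n_cells, p.marker_genes, p.marker_log2fc)
        for name, p in zip(subtype_names, config.populations)
    ]
    ref_cfg = SimConfig(
        n_genes=config.n_genes,
        populations=pops,
        gene_ids=list(config.gene_ids),
        baseline_log_mean=config.baseline_log_mean,
        baseline_log_sd=config.baseline_log_sd,
        dispersion_theta=config.dispersion_theta,
        libsize_log_mean=config.libsize_log_mean,
        libsize_log_sd=config.libsize_log_sd,
        mito_genes=config.mito_genes,
        mito_fraction_beta=config.mito_fraction_beta,
        n_samples=1,
        batch_log_shift_sd=0.0,
        doublet_rate=0.0,
        seed=config.seed,
    )
    cm, gt = simulate_sc_counts(ref_cfg)
    return cm, gt.cell_labels


# ---------------------------------------------------------------------------
# Default study scenario: coupled bulk pair, query sample and reference atlas.
# ---------------------------------------------------------------------------

N_GENES_DEFAULT = 2000
N_MITO_DEFAULT = 13
MARKERS_PER_POP = 20
MARKER_LOG2FC = 4.0
CELLS_PER_POP = 300
BULK_SIG_PER_LINE = 100
BULK_FOLD_LOG2 = 3.0
BULK_BASE_MEAN = 50.0
BULK_THETA = 5.0
BULK_N_GENES_GENOME = 20000


def make_default_bulk_pair(seed: int = 0):
    """Genome-scale default bulk pair (100 planted signature genes per line
    out of 20000 genes), emulating a full bulk RNA-seq profile pair where
    line-specific signatures are a sub-percent fraction of the genome."""
    return simulate_bulk_pair(
        BULK_N_GENES_GENOME,
        BULK_SIG_PER_LINE,
        BULK_FOLD_LOG2,
        BULK_BASE_MEAN,
        BULK_THETA,
        seed=seed,
    )


@dataclass
class Scenario:
    """A coupled synthetic study: bulk pair + query cells + reference atlas."""

    bulk_a: pd.Series
    bulk_b: pd.Series
    bulk_signatures: tuple[frozenset[str], frozenset[str]]
    query: CountMatrix
    query_truth: GroundTruth
    atlas: CountMatrix
    atlas_labels: pd.Series
    pop_origin: dict[str, str]  # population -> "lineA"/"lineB"
    pop_subtype: dict[str, str]  # population -> planted atlas subtype
    marker_sets: dict[str, frozenset[str]]
    # stand-ins for the fixed, known cell-cycle gene lists of real data;
    # disjoint from every planted marker set by construction
    s_genes: frozenset[str] = frozenset()
    g2m_genes: frozenset[str] = frozenset()


def make_default_scenario(seed: int = 0) -> Scenario:
    """Build the default coupled scenario with known ground truth.

    Three query populations of 300 cells over 2000 genes. Populations pop0 and
    pop1 take their 20 markers from line A's planted bulk signature, pop2 from
    line B's, so origin attribution has a known answer. The 3-subtype
    reference atlas reuses the same marker sets (subtype_i <-> pop_i), so the
    cosine argmax has a known answer.
    """
    mito = frozenset(f"MT-{i}" for i in range(N_MITO_DEFAULT))
    gene_ids = [f"G{i:05d}" for i in range(N_GENES_DEFAULT - N_MITO_DEFAULT)] + sorted(mito)
    bulk_a, bulk_b, (sig_a, sig_b) = simulate_bulk_pair(
        N_GENES_DEFAULT,
        BULK_SIG_PER_LINE,
        BULK_FOLD_LOG2,
        BULK_BASE_MEAN,
        BULK_THETA,
        seed=seed,
        gene_ids=gene_ids,
    )
    sig_a_sorted = sorted(sig_a)
    sig_b_sorted = sorted(sig_b)
    marker_sets = {
        "pop0": frozenset(sig_a_sorted[:MARKERS_PER_POP]),
        "pop1": frozenset(sig_a_sorted[MARKERS_PER_POP : 2 * MARKERS_PER_POP]),
        "pop2": frozenset(sig_b_sorted[:MARKERS_PER_POP]),
    }
    pops = [
        Population(name, CELLS_PER_POP, genes, MARKER_LOG2FC)
        for name, genes in marker_sets.items()
    ]
    query_cfg = SimConfig(
        n_genes=N_GENES_DEFAULT,
        populations=pops,
        gene_ids=gene_ids,
        mito_genes=mito,
        n_samples=2,
        batch_log_shift_sd=0.1,
        doublet_rate=0.05,
        seed=seed + 1,
    )
    query, truth = simulate_sc_counts(query_cfg)
    atlas_cfg = SimConfig(
        n_genes=N_GENES_DEFAULT,
        populations=pops,
        gene_ids=gene_ids,
        mito_genes=mito,
        seed=seed + 2,
    )
    subtypes = ["normal", "iCMS2", "iCMS3"]
    atlas, atlas_labels = simulate_reference_atlas(atlas_cfg, subtypes)
    truth.true_bulk_signatures = (sig_a, sig_b)
    all_markers = set().union(*marker_sets.values())
    cc_pool = [g for g in gene_ids if g not in all_markers and g not in mito]
    s_genes = frozenset(cc_pool[:20])
    g2m_genes = frozenset(cc_pool[20:40])
    return Scenario(
        bulk_a=bulk_a,
        bulk_b=bulk_b,
        bulk_signatures=(sig_a, sig_b),
        query=query,
        query_truth=truth,
        atlas=atlas,
        atlas_labels=atlas_labels,
        pop_origin={"pop0": "lineA", "pop1": "lineA", "pop2": "lineB"},
        pop_subtype=dict(zip(marker_sets, subtypes)),
        marker_sets=marker_sets,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
    )
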