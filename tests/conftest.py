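import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from invitrofidelity.containers import ClusterAssignment, CountMatrix, ResidualMatrix
from invitrofidelity.pipeline import run_pipeline, validate_config


def make_count_matrix(X, samples=None, genes=None, cells=None):
    """Small CountMatrix from a dense array (genes x cells)."""
    X = np.asarray(X)
    n_genes, n_cells = X.shape
    genes = genes or [f"G{i:04d}" for i in range(n_genes)]
    cells = cells or [f"c{i:04d}" for i in range(n_cells)]
    samples = samples or ["sample0"] * n_cells
    return CountMatrix(genes, cells, sp.csr_matrix(X), pd.Series(samples, index=cells))


def make_residuals(values, samples=None, clip=None, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"G{i:04d}" for i in range(n_genes)]
    cells = cells or [f"c{i:04d}" for i in range(n_cells)]
    samples = samples or ["sample0"] * n_cells
    clip = clip if clip is not None else max(np.abs(values).max(), 1.0)
    return ResidualMatrix(genes, cells, values, clip, pd.Series(samples, index=cells))


def make_assignment(labels_by_cell: dict):
    return ClusterAssignment(labels=pd.Series(labels_by_cell), resolution=0.5, seed=0)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default synthetic scenario (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = validate_config({"outdir": str(outdir), "seed": 1})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
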