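"""Readers and writers for the on-disk formats.

Count matrices travel as 10x-style triplets: ``matrix.mtx`` (Matrix-Market
coordinate, 1-based, gene-major) with ``features.tsv`` and ``barcodes.tsv``
sidecars. Bulk profiles are 2-column TSV (gene_id, count). Ground truth and
fit reports are JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, DataError, GeneSignature


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    pd.Series(cm.genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(
        {"barcode": cm.cells, "sample": cm.sample_of_cell.loc[cm.cells].values}
    ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    return outdir


def read_count_matrix(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    bc = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    cells = bc[0].tolist()
    samples = bc[1] if bc.shape[1] > 1 else pd.Series(["sample0"] * len(cells))
    return CountMatrix(genes, cells, mat, pd.Series(samples.values, index=cells))


def write_bulk_profile(profile: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile.rename_axis("gene_id").rename("count").to_csv(path, sep="\t", header=False)
    return path


def read_bulk_profile(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "count"])
    if df["gene_id"].duplicated().any():
        raise DataError(f"duplicate gene ids in {path}")
    s = pd.Series(df["count"].values, index=df["gene_id"].values)
    if (s < 0).any():
        raise DataError(f"negative counts in {path}")
    return s


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_signature_csv(signatures: list[GeneSignature], path: str | Path) -> Path:
    rows = [
        {"signature": s.name, "gene": g, "direction": s.direction, "source": s.source}
        for s in signatures
        for g in sorted(s.genes)
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["signature", "gene", "direction", "source"]).to_csv(
        path, index=False
    )
    return path
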