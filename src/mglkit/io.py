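"""Readers and writers for the plain-text formats the pipeline exchanges.

Bulk matrices and metadata travel as TSV; single-cell counts as MatrixMarket
(.mtx) with features/barcodes sidecar TSVs (the 10x convention); structured
results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import ExpressionMatrix, validate_sample_table


def read_expression_tsv(path: str | Path, space: str = "TPM") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene symbol, header = samples)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, space=space)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t"))


def write_sample_table(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_cell_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path | None = None,
) -> ad.AnnData:
    """Load a 10x-style MatrixMarket trio into AnnData (cells x genes).

    The .mtx file stores genes as rows and cells as columns, as written by
    Cell Ranger; it is transposed into the AnnData convention.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)).T)
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=barcodes[0].astype(str)),
        var=pd.DataFrame(index=features[0].astype(str).str.upper()),
    )
    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = adata.obs.join(meta)
    return adata


def write_cell_counts(adata: ad.AnnData, out_dir: str | Path, prefix: str = "") -> None:
    """Write AnnData counts as matrix.mtx + features.tsv + barcodes.tsv + cells.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X).T  # genes x cells on disk
    scipy.io.mmwrite(str(out / f"{prefix}matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(out / f"{prefix}features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(out / f"{prefix}barcodes.tsv", sep="\t", header=False, index=False)
    if adata.obs.shape[1]:
        adata.obs.to_csv(out / f"{prefix}cells.tsv", sep="\t", index_label="barcode")


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
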