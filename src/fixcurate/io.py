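"""Readers and writers: bulk TSV, single-cell Matrix Market + TSV metadata,
ground truth and reports as JSON.

Single-cell counts are stored genes x cells in ``matrix.mtx`` (the common
convention) with ``genes.tsv`` and ``cells.tsv``; a ``matrix.json`` sidecar
records the orientation explicitly so a transposed matrix cannot be read
silently. Reading then writing reproduces counts and metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from ._utils import FixcurateError
from .bulk_de import BulkCounts


def write_bulk(bulk: BulkCounts, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk.counts.to_csv(outdir / "bulk_counts.tsv", sep="\t", index_label="gene")
    bulk.design.to_csv(outdir / "bulk_design.tsv", sep="\t", index_label="sample")


def read_bulk(counts_path, design_path) -> BulkCounts:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return BulkCounts(counts=counts, design=design)


def write_cells(cells: AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = cells.X if sparse.issparse(cells.X) else sparse.csr_matrix(cells.X)
    mat = sparse.coo_matrix(X.T)  # genes x cells on disk
    mat.eliminate_zeros()
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    (outdir / "matrix.json").write_text(
        json.dumps({"orientation": "genes_x_cells", "n_genes": cells.n_vars, "n_cells": cells.n_obs})
    )
    pd.Series(cells.var_names, name="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells.obs.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell")


def read_cells(indir) -> AnnData:
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (indir / name).exists():
            raise FixcurateError(f"missing {name} in {indir}")
    mat = spio.mmread(indir / "matrix.mtx").tocsr()
    mat.eliminate_zeros()
    sidecar = indir / "matrix.json"
    orientation = "genes_x_cells"
    if sidecar.exists():
        orientation = json.loads(sidecar.read_text()).get("orientation", orientation)
    if orientation == "genes_x_cells":
        mat = mat.T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    if genes.duplicated().any() or obs.index.duplicated().any():
        raise FixcurateError("duplicate gene or cell identifiers")
    if mat.shape != (len(obs), len(genes)):
        raise FixcurateError(
            f"matrix shape {mat.shape} does not match {len(obs)} cells x {len(genes)} genes"
        )
    obs.index = obs.index.astype(str)
    return AnnData(X=mat.astype(np.int64), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_truth(truth, path) -> None:
    payload = {
        "gene_labels": {g: sorted(tags) for g, tags in truth.gene_labels.items() if tags},
    }
    if truth.cell_labels is not None:
        payload["cell_labels"] = json.loads(truth.cell_labels.to_json(orient="index"))
    Path(path).write_text(json.dumps(payload))


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
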