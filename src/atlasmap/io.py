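"""Readers and writers for the plain-text interchange formats.

Count matrices travel as a 10x-style MTX triplet (``matrix.mtx`` with genes
as rows and cells as columns, ``barcodes.tsv``, ``features.tsv`` carrying a
mitochondrial flag column); per-cell metadata as CSV; per-sample directed
edge lists as 3-column TSV (source, target, sample).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as sio
from scipy import sparse

from .simulate import SampleGraph

__all__ = [
    "write_mtx_dir",
    "read_mtx_dir",
    "read_counts_csv",
    "write_edge_list",
    "read_edge_list",
]


def write_mtx_dir(adata: AnnData, out_dir) -> None:
    """Write a 10x-style triplet: genes x cells matrix, barcodes, features."""
    os.makedirs(out_dir, exist_ok=True)
    X = adata.X
    X = sparse.csc_matrix(X.T if sparse.issparse(X) else np.asarray(X).T)
    sio.mmwrite(os.path.join(out_dir, "matrix.mtx"), X)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False)
    mito = adata.var["mito"] if "mito" in adata.var else pd.Series(False, index=adata.var_names)
    features = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_name": adata.var_names,
        "mito": mito.astype(bool).to_numpy(),
    })
    features.to_csv(os.path.join(out_dir, "features.tsv"),
                    sep="\t", index=False, header=False)


def read_mtx_dir(in_dir) -> AnnData:
    """Read a triplet written by :func:`write_mtx_dir` (cells x genes out)."""
    X = sio.mmread(os.path.join(in_dir, "matrix.mtx"))
    barcodes = pd.read_csv(os.path.join(in_dir, "barcodes.tsv"),
                           sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(os.path.join(in_dir, "features.tsv"),
                           sep="\t", header=None,
                           names=["gene_id", "gene_name", "mito"])
    var = pd.DataFrame({"mito": features["mito"].astype(bool).to_numpy()},
                       index=features["gene_id"].astype(str))
    return AnnData(X=sparse.csr_matrix(X.T), var=var,
                   obs=pd.DataFrame(index=barcodes))


def read_counts_csv(path) -> AnnData:
    """Dense cells x genes CSV with cell ids in the first column."""
    df = pd.read_csv(path, index_col=0)
    return AnnData(X=sparse.csr_matrix(df.to_numpy(dtype=np.float64)),
                   obs=pd.DataFrame(index=df.index.astype(str)),
                   var=pd.DataFrame(index=df.columns.astype(str)))


def write_edge_list(samples: list[SampleGraph], path) -> None:
    rows = [
        {"source": src, "target": tgt, "sample": s.sample_id}
        for s in samples for src, tgt in s.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "sample"]).to_csv(
        path, sep="\t", index=False)


def read_edge_list(path) -> list[SampleGraph]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"source", "target", "sample"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list lacks columns: {sorted(missing)}")
    return [
        SampleGraph(sample_id=str(sid),
                    edges=list(zip(sub["source"], sub["target"])))
        for sid, sub in df.groupby("sample", sort=True)
    ]
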