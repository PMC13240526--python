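"""Readers and writers for the plain-text formats the pipeline exchanges."""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ExpressionMatrix


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    """Expression TSV (genes in rows, header = sample IDs) + metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, expr_path, meta_path) -> None:
    expr.values.to_csv(expr_path, sep="\t")
    expr.samples.to_csv(meta_path, sep="\t")


def write_string_edges(graph: nx.Graph, path, scale_1000: bool = True) -> None:
    """Write a PPI graph as a STRING-export-style TSV."""
    rows = []
    for u, v, data in graph.edges(data=True):
        score = data.get("score", 0.0)
        rows.append({"protein1": u, "protein2": v,
                     "combined_score": int(round(score * 1000)) if scale_1000 else score})
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False)


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_a", "gene_b", "homology_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return df


def write_ortholog_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_mtx_bundle(adata: ad.AnnData, outdir) -> None:
    """MatrixMarket counts + gene and cell annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    matrix = sp.csr_matrix(X) if not sp.issparse(X) else X
    scipy.io.mmwrite(str(outdir / "counts.mtx"), matrix.T)  # genes x cells triplets
    pd.DataFrame({"gene": adata.var_names,
                  "mito": adata.var.get("mito", False)}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.rename_axis("cell").to_csv(outdir / "cells.tsv", sep="\t")


def read_mtx_bundle(indir) -> ad.AnnData:
    indir = Path(indir)
    matrix = scipy.io.mmread(str(indir / "counts.mtx")).T.tocsr()  # cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.DataFrame({"mito": genes.get("mito", False).to_numpy()},
                       index=genes["gene"].astype(str))
    return ad.AnnData(X=np.asarray(matrix.todense(), dtype=float),
                      obs=cells, var=var)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None,
                index: bool = True) -> None:
    """TSV writer with an optional provenance comment line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index)
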