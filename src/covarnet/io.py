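"""Readers and writers for the package's tabular interchange formats.

Count matrices move as MatrixMarket (.mtx) plus gene/cell TSVs or as a
single dense TSV; covariation calls as an edge-list TSV (gene_a, gene_b,
sign, per-replicate rho and p); gene sets as GMT; annotations as BED-like
and contact TSVs. Everything round-trips through pandas / scipy.io /
anndata.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .covariation import CallSet

__all__ = [
    "write_matrix_dir",
    "read_matrix_dir",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_json",
]


def write_matrix_dir(adata: ad.AnnData, out_dir: str | Path) -> Path:
    """MTX + obs/var TSVs per layer under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layers = {"exon": np.asarray(adata.X), **{k: np.asarray(v) for k, v in adata.layers.items()}}
    for name, X in layers.items():
        spio.mmwrite(str(out / f"{name}.mtx"), sparse.csr_matrix(X))
    adata.obs.to_csv(out / "cells.tsv", sep="\t")
    adata.var.to_csv(out / "genes.tsv", sep="\t")
    return out


def read_matrix_dir(in_dir: str | Path) -> ad.AnnData:
    src = Path(in_dir)
    obs = pd.read_csv(src / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(src / "genes.tsv", sep="\t", index_col=0)
    layers = {}
    for mtx in sorted(src.glob("*.mtx")):
        layers[mtx.stem] = np.asarray(spio.mmread(str(mtx)).todense())
    X = layers.get("exon", next(iter(layers.values())))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    for name, mat in layers.items():
        adata.layers[name] = mat
    return adata


def write_calls_tsv(calls: CallSet, path: str | Path) -> Path:
    path = Path(path)
    calls.calls.to_csv(path, sep="\t", index=False)
    meta = {
        "alpha": calls.alpha,
        "min_replicates": calls.min_replicates,
        "layer": calls.layer,
        "condition": calls.condition,
        "genes": list(map(str, calls.genes)),
        "n_untestable": calls.n_untestable,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    return path


def read_calls_tsv(path: str | Path) -> CallSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    genes = np.asarray(meta.get("genes", sorted(set(df["gene_a"]) | set(df["gene_b"]))))
    if "is_ribo_pair" not in df:
        df["is_ribo_pair"] = False
    return CallSet(
        calls=df,
        alpha=meta.get("alpha", 0.01),
        min_replicates=meta.get("min_replicates", 2),
        layer=meta.get("layer", "rpm"),
        condition=meta.get("condition"),
        genes=genes,
        n_untestable=meta.get("n_untestable", 0),
    )


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
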