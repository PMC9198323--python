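"""Readers and writers for the plain-text interchange formats.

Panel and bulk tables travel as TSV (genes x samples, first column the
gene id); single-cell layers as MatrixMarket coordinate triplets with
genes.tsv / barcodes.tsv sidecars; metadata as CSV; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path)


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sc_dir(adata: ad.AnnData, outdir) -> None:
    """Write spliced/unspliced MTX triplets plus gene/cell lists and obs CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in ("spliced", "unspliced"):
        mat = sparse.csr_matrix(np.asarray(adata.layers[layer]))
        spio.mmwrite(outdir / f"{layer}.mtx", mat)
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(outdir / "metadata.csv")


def read_sc_dir(indir) -> ad.AnnData:
    indir = Path(indir)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    layers = {
        layer: np.asarray(spio.mmread(indir / f"{layer}.mtx").todense())
        for layer in ("spliced", "unspliced")
    }
    obs_path = indir / "metadata.csv"
    obs = (
        pd.read_csv(obs_path, index_col=0)
        if obs_path.exists()
        else pd.DataFrame(index=cells)
    )
    adata = ad.AnnData(
        X=layers["spliced"].astype(np.float32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        layers={k: v.astype(np.float32) for k, v in layers.items()},
    )
    adata.obs_names = cells
    return adata


def write_config_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
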