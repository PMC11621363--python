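"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are 0-based, half-open (BED convention). Cell×gene
matrices are stored as MatrixMarket triplets (one file per count layer) with
barcode/feature sidecars, mirroring the 10x on-disk layout but uncompressed.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 4)
    df = df.iloc[:, :ncol]
    df.columns = BED_COLUMNS[:ncol]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    if df.empty:
        raise ValueError(f"empty chrom.sizes file: {path}")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, sex, organ, replicate, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "organ", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    bad_sex = set(df["sex"]) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    return df


def read_counts_table(path) -> pd.DataFrame:
    """Long-format biallelic count table (unit_id, chrom, start, end, count_*)."""
    df = pd.read_csv(path, sep="\t")
    if not any(c.startswith("count_") for c in df.columns):
        raise ValueError("counts table needs two count_<strain> columns")
    return df


def write_counts_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Feature annotation TSV: feature_id, chrom, start, end[, strand]."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


# -- cell matrices -----------------------------------------------------------


def write_cell_matrix(adata: ad.AnnData, out_dir) -> None:
    """Write an AnnData with strain1/strain2 layers as MTX triplets + sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix_total.mtx"), sp.csr_matrix(adata.X))
    for layer in ("strain1", "strain2"):
        scipy.io.mmwrite(str(out / f"matrix_{layer}.mtx"), sp.csr_matrix(adata.layers[layer]))
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    feat = pd.DataFrame({"gene_id": adata.var_names, "chrom": adata.var["chrom"].to_numpy()})
    feat.to_csv(out / "features.tsv", sep="\t", index=False)
    meta = adata.obs.reset_index(names="barcode")
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)


def read_cell_matrix(in_dir) -> ad.AnnData:
    src = Path(in_dir)
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(src / "features.tsv", sep="\t")
    total = sp.csr_matrix(scipy.io.mmread(str(src / "matrix_total.mtx")))
    layers = {
        layer: sp.csr_matrix(scipy.io.mmread(str(src / f"matrix_{layer}.mtx")))
        for layer in ("strain1", "strain2")
    }
    obs = pd.read_csv(src / "metadata.tsv", sep="\t").set_index("barcode")
    obs.index = obs.index.astype(str)
    obs = obs.loc[barcodes]
    var = features.set_index("gene_id")
    adata = ad.AnnData(X=total, obs=obs, var=var, layers=layers)
    adata.obs_names = barcodes.to_numpy()
    return adata


# -- small JSON helpers ------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
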