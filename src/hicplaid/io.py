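"""Plain-text readers/writers: pairs TSV, COO matrix + bin BED, chrom sizes,
BED/bedGraph tracks and TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .hic_core import BinTable, ContactMatrix

__all__ = [
    "read_pairs",
    "read_chrom_sizes",
    "read_bed",
    "write_bins_bed",
    "read_bins_bed",
    "write_matrix_coo",
    "read_matrix_coo",
    "write_bedgraph",
    "write_track_bed",
    "read_expression",
    "read_genes_bed",
]


def read_pairs(path) -> pd.DataFrame:
    """4-column TSV: chrom1, pos1, chrom2, pos2 (no header)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom1", "pos1", "chrom2", "pos2"],
        dtype={"chrom1": str, "chrom2": str, "pos1": np.int64, "pos2": np.int64},
        comment="#",
    )


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": np.int64})
    return dict(zip(df["chrom"], df["size"]))


def read_bed(path, n_cols: int = 3, names=None) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    names = names or base[:n_cols]
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       usecols=range(len(names)), names=names)


def read_genes_bed(path) -> pd.DataFrame:
    """BED6 gene table: chrom, start, end, gene_id, score, strand."""
    df = read_bed(path, 6, names=["chrom", "start", "end", "gene_id", "score", "strand"])
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def read_expression(path) -> pd.DataFrame:
    """2-column TSV: gene_id, tpm (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "tpm"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "tpm"])
    return df[["gene_id", "tpm"]]


def write_bins_bed(bins: BinTable, path) -> None:
    bins.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path) -> BinTable:
    df = read_bed(path, 3)
    return BinTable(df["chrom"].to_numpy(dtype=object),
                    df["start"].to_numpy(), df["end"].to_numpy())


def write_matrix_coo(m: ContactMatrix, prefix) -> None:
    """Write <prefix>.bins.bed, <prefix>.coo.tsv (upper triangle) and mask/bias."""
    prefix = str(prefix)
    write_bins_bed(m.bins, prefix + ".bins.bed")
    upper = sparse.triu(m.values).tocoo()
    pd.DataFrame({"bin1": upper.row, "bin2": upper.col, "value": upper.data}).to_csv(
        prefix + ".coo.tsv", sep="\t", header=False, index=False
    )
    meta = pd.DataFrame({"bin": np.arange(m.n_bins), "masked": m.mask.astype(int)})
    if m.bias is not None:
        meta["bias"] = m.bias
    meta.to_csv(prefix + ".bins.tsv", sep="\t", index=False)


def read_matrix_coo(prefix) -> ContactMatrix:
    prefix = str(prefix)
    bins = read_bins_bed(prefix + ".bins.bed")
    coo = pd.read_csv(prefix + ".coo.tsv", sep="\t", header=None,
                      names=["bin1", "bin2", "value"])
    n = bins.n_bins
    upper = sparse.coo_matrix(
        (coo["value"], (coo["bin1"], coo["bin2"])), shape=(n, n)
    ).tocsr()
    diag = sparse.diags(upper.diagonal())
    values = upper + upper.T - diag
    mask = None
    bias = None
    meta_path = Path(prefix + ".bins.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        mask = meta["masked"].to_numpy(dtype=bool)
        if "bias" in meta.columns:
            bias = meta["bias"].to_numpy(dtype=float)
    return ContactMatrix(bins=bins, values=values.tocsr(), mask=mask, bias=bias)


def write_bedgraph(bins: BinTable, values: np.ndarray, path) -> None:
    df = bins.to_dataframe()
    df["value"] = values
    df = df[np.isfinite(df["value"])]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_track_bed(df: pd.DataFrame, path, columns=None) -> None:
    (df[columns] if columns else df).to_csv(path, sep="\t", header=False, index=False)
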