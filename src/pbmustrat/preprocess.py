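"""Expression-matrix container, I/O and count normalization.

The pipeline's universal currency is a genes x samples matrix carrying an
explicit scale tag (``raw_counts`` -> ``normalized_counts`` -> ``log2``).
Raw counts are normalized with the median-of-ratios size-factor estimator
(the standard RNA-seq library-composition correction) and log2-transformed
with a pseudocount before any downstream statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "median_of_ratios_normalize",
    "log2_transform",
    "filter_low_expression",
]

_SCALES = ("raw_counts", "normalized_counts", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.
    scale
        One of ``raw_counts``, ``normalized_counts`` or ``log2``.
    """

    data: pd.DataFrame
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if self.scale in ("raw_counts", "normalized_counts"):
            vals = self.data.to_numpy()
            if np.any(vals < 0):
                g, s = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative value at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r} on scale {self.scale!r}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :], self.scale)


def read_expression(path: str | os.PathLike, format: str = "tsv",
                    scale: str = "raw_counts") -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket.

    TSV layout: first column gene IDs, header row of sample IDs,
    tab-separated, '.' decimal.  MTX layout: ``<stem>.mtx`` plus
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one ID per line).
    """
    path = str(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows in {path}: {dup[:5]}")
        return ExpressionMatrix(df, scale)
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        raw = mmread(stem + ".mtx")
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        with open(stem + ".genes.txt") as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
        with open(stem + ".samples.txt") as fh:
            samples = [ln.strip() for ln in fh if ln.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX dimensions {mat.shape} do not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
        return ExpressionMatrix(df, scale)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike,
                     format: str = "tsv", float_format: str = "%.10g") -> None:
    """Write a matrix as TSV or MatrixMarket (with gene/sample sidecars)."""
    path = str(path)
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", float_format=float_format)
        return
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        sparse = coo_matrix(matrix.data.to_numpy())
        mmwrite(stem + ".mtx", sparse)
        with open(stem + ".genes.txt", "w") as fh:
            fh.write("\n".join(map(str, matrix.gene_ids)) + "\n")
        with open(stem + ".samples.txt", "w") as fh:
            fh.write("\n".join(map(str, matrix.sample_ids)) + "\n")
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def median_of_ratios_normalize(
    counts: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios count normalization.

    For each sample the size factor is the median, over genes with strictly
    positive counts in every sample, of the ratio of the sample's count to
    the gene's geometric mean across samples.  Size factors are rescaled to
    geometric mean 1 and each sample's counts divided by its factor.

    Returns the normalized matrix and the per-sample size factors.
    """
    if counts.scale != "raw_counts":
        raise ValueError(f"expected raw counts, got scale {counts.scale!r}")
    vals = counts.values()
    all_pos = np.all(vals > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "no gene has nonzero counts in every sample; filter samples or "
            "genes before normalizing"
        )
    ref = vals[all_pos]
    log_geo_mean = np.mean(np.log(ref), axis=1)  # per reference gene
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    normed = vals / factors[None, :]
    out = ExpressionMatrix(
        pd.DataFrame(normed, index=counts.gene_ids, columns=counts.sample_ids),
        "normalized_counts",
    )
    return out, pd.Series(factors, index=counts.sample_ids, name="size_factor")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return log2(value + pseudocount) with scale tag ``log2``."""
    if matrix.scale not in ("raw_counts", "normalized_counts"):
        raise ValueError(f"cannot log2-transform scale {matrix.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = matrix.values()
    if np.any(vals < 0):
        raise ValueError("negative input values")
    out = np.log2(vals + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids), "log2"
    )


def filter_low_expression(matrix: ExpressionMatrix, min_count: float,
                          min_samples: int) -> ExpressionMatrix:
    """Keep genes with at least ``min_count`` in at least ``min_samples`` samples."""
    if matrix.scale == "log2":
        raise ValueError("filter operates on raw or normalized counts")
    if min_samples > matrix.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {matrix.shape[1]} samples present"
        )
    keep = (matrix.values() >= min_count).sum(axis=1) >= min_samples
    if not np.any(keep):
        raise ValueError("no gene passes the low-expression filter")
    return ExpressionMatrix(matrix.data.loc[keep], matrix.scale)
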