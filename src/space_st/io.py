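"""Readers, writers, gene filtering and normalization.

Supported external formats (all plain text):

* MatrixMarket triplets: ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
  (10x-style layout, genes as MTX rows);
* delimited text (TSV/CSV) with gene rows and a header of spot ids;
* coordinates as delimited text with columns ``spot_id``, ``x``, ``y``.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ExpressionMatrix, RawCounts, SpatialCoords

logger = logging.getLogger(__name__)


def _read_id_column(path: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _read_expression(
    path: str,
    format: str | None,
    spots_as_rows: bool,
    features_path: str | None,
    barcodes_path: str | None,
) -> tuple[np.ndarray, list[str], list[str]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "delimited"
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        base = os.path.dirname(path)
        features_path = features_path or os.path.join(base, "features.tsv")
        barcodes_path = barcodes_path or os.path.join(base, "barcodes.tsv")
        gene_ids = _read_id_column(features_path)
        spot_ids = _read_id_column(barcodes_path)
        if len(gene_ids) != mat.shape[0] or len(spot_ids) != mat.shape[1]:
            raise ValueError(
                "feature/barcode files do not match matrix dimensions "
                f"({len(gene_ids)} x {len(spot_ids)} vs {mat.shape})"
            )
        return mat, gene_ids, spot_ids
    if format == "delimited":
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if spots_as_rows:
            df = df.T
        return df.to_numpy(dtype=float), [str(g) for g in df.index], [str(s) for s in df.columns]
    raise ValueError(f"unknown expression format: {format!r}")


def load_expression(
    path: str,
    format: str | None = None,
    spots_as_rows: bool = False,
    features_path: str | None = None,
    barcodes_path: str | None = None,
) -> RawCounts:
    """Read a raw (nonnegative) expression matrix into genes-x-spots
    orientation.

    ``format`` is one of ``mtx`` or ``delimited``; when omitted it is inferred
    from the file extension. For MTX input the companion feature/barcode files
    default to ``features.tsv`` / ``barcodes.tsv`` next to the matrix.
    With ``spots_as_rows`` a delimited file holding spots as rows is
    transposed on load.
    """
    mat, gene_ids, spot_ids = _read_expression(path, format, spots_as_rows, features_path, barcodes_path)
    return RawCounts(mat, gene_ids, spot_ids)


def load_expression_matrix(
    path: str,
    format: str | None = None,
    spots_as_rows: bool = False,
    features_path: str | None = None,
    barcodes_path: str | None = None,
    normalized: bool = True,
) -> ExpressionMatrix:
    """Read a pre-normalized expression matrix (values may be negative)."""
    mat, gene_ids, spot_ids = _read_expression(path, format, spots_as_rows, features_path, barcodes_path)
    return ExpressionMatrix(mat, gene_ids, spot_ids, normalized)


def load_coordinates(path: str) -> SpatialCoords:
    """Read a spot coordinate table (columns: spot_id, x, y[, ...])."""
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    spot_ids = df.iloc[:, 0].astype(str).tolist()
    coords = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpatialCoords(coords, spot_ids)


def write_expression(counts: RawCounts | ExpressionMatrix, path: str, format: str = "delimited") -> None:
    if format == "delimited":
        sep = "," if path.endswith(".csv") else "\t"
        pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.spot_ids).to_csv(
            path, sep=sep
        )
    elif format == "mtx":
        base = os.path.dirname(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.values))
        # mmwrite appends .mtx if missing; mirror that for the companions
        pd.Series(counts.gene_ids).to_csv(
            os.path.join(base, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(counts.spot_ids).to_csv(
            os.path.join(base, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def write_coordinates(coords: SpatialCoords, path: str) -> None:
    df = pd.DataFrame(
        {
            "spot_id": coords.spot_ids,
            "x": coords.coords[:, 0],
            "y": coords.coords[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_genes(counts: RawCounts, min_frac: float = 0.01) -> RawCounts:
    """Drop sparse genes expressed in fewer than ``min_frac`` of spots."""
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must lie in [0, 1]")
    frac = (counts.values != 0).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("sparse-gene filter removed every gene")
    return RawCounts(
        counts.values[keep],
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.spot_ids),
    )


def normalize(
    counts: RawCounts, method: str = "lognorm", assume_normalized: bool = True
) -> ExpressionMatrix:
    """Normalize counts to the analysis scale.

    ``lognorm`` scales each spot to the median library size and applies
    log(1 + x); ``none`` passes values through, marking them normalized
    according to ``assume_normalized`` (the caller's assertion about its
    pre-processed input).
    """
    if method == "none":
        return ExpressionMatrix(
            counts.values.copy(), list(counts.gene_ids), list(counts.spot_ids), assume_normalized
        )
    if method != "lognorm":
        raise ValueError(f"unknown normalization method: {method!r}")
    lib = counts.values.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("spot with zero library size under lognorm")
    scaled = counts.values * (np.median(lib) / lib)
    return ExpressionMatrix(
        np.log1p(scaled), list(counts.gene_ids), list(counts.spot_ids), True
    )


def align_spots(expr: ExpressionMatrix, coords: SpatialCoords) -> tuple[ExpressionMatrix, SpatialCoords]:
    """Align the spot axes of expression and coordinates.

    Alignment is by spot id when both sides carry ids; if the id sets differ
    entirely, positional alignment is used with a logged warning.
    """
    if expr.n_spots != coords.n_spots and set(expr.spot_ids) - set(coords.spot_ids):
        raise ValueError("expression and coordinates cover different spot sets")
    if set(expr.spot_ids) <= set(coords.spot_ids):
        index = {s: i for i, s in enumerate(coords.spot_ids)}
        order = [index[s] for s in expr.spot_ids]
        return expr, SpatialCoords(coords.coords[order], list(expr.spot_ids))
    logger.warning("spot ids do not match between expression and coordinates; aligning by position")
    if expr.n_spots != coords.n_spots:
        raise ValueError("cannot align by position: spot counts differ")
    return expr, SpatialCoords(coords.coords, list(expr.spot_ids))
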