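"""Reading and writing of matrices and pipeline artifacts.

Dense matrices travel as TSV/CSV with an optional header row and rows as
samples; sparse matrices as MatrixMarket coordinate files with optional
companion name files (``<path>.rows.txt`` / ``<path>.cols.txt``, one name
per line).  All numeric output is printed with 12 significant digits so a
write/read round trip is lossless at that precision.
"""

from __future__ import annotations

import os

import numpy as np
from scipy import io as spio
from scipy import sparse

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "write_outline",
    "write_projection",
    "write_embedding",
    "write_metrics",
]

_FMT = "%.12g"


class MatrixParseError(ValueError):
    """A matrix file could not be parsed."""


def _delimiter(path: str, fmt: str | None) -> str:
    if fmt == "csv" or (fmt is None and path.endswith(".csv")):
        return ","
    return "\t"


def _is_numeric_row(cells: list[str]) -> bool:
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def read_matrix(path: str, fmt: str | None = None):
    """Read a samples-by-features matrix.

    Parameters
    ----------
    path : str
    fmt : {"tsv", "csv", "mtx", None}
        Inferred from the extension when None.

    Returns
    -------
    (matrix, row_names, col_names)
        Dense float ndarray; names are None when absent.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = ext if ext in ("tsv", "csv", "mtx") else "tsv"
    if fmt == "mtx":
        return _read_mtx(path)
    delim = _delimiter(path, fmt)
    rows: list[list[float]] = []
    col_names = None
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(delim)
            if lineno == 1 and not _is_numeric_row(cells):
                col_names = cells
                continue
            if not _is_numeric_row(cells):
                bad = next(c for c in cells if not _is_numeric_row([c]))
                raise MatrixParseError(
                    f"{path}:{lineno}: non-numeric cell {bad!r}"
                )
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise MatrixParseError(
                    f"{path}:{lineno}: ragged row — expected {width} cells, "
                    f"got {len(cells)}"
                )
            rows.append([float(c) for c in cells])
    if not rows:
        raise MatrixParseError(f"{path}: no data rows")
    return np.array(rows, dtype=float), None, col_names


def _read_mtx(path: str):
    try:
        mat = spio.mmread(path)
    except Exception as err:  # scipy raises assorted types for bad headers
        raise MatrixParseError(f"{path}: invalid MatrixMarket file ({err})") from err
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    row_names = _read_names(path + ".rows.txt")
    col_names = _read_names(path + ".cols.txt")
    if row_names is not None and len(row_names) != mat.shape[0]:
        raise MatrixParseError(
            f"{path}.rows.txt: {len(row_names)} names for {mat.shape[0]} rows"
        )
    if col_names is not None and len(col_names) != mat.shape[1]:
        raise MatrixParseError(
            f"{path}.cols.txt: {len(col_names)} names for {mat.shape[1]} columns"
        )
    return mat, row_names, col_names


def _read_names(path: str):
    if not os.path.exists(path):
        return None
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _fmt_row(values) -> str:
    return "\t".join(_FMT % v for v in values)


def write_matrix(path: str, matrix: np.ndarray, col_names=None) -> None:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w") as fh:
        if col_names is not None:
            fh.write("\t".join(col_names) + "\n")
        for row in matrix:
            fh.write(_fmt_row(row) + "\n")


def write_outline(path: str, outline, sample_ids=None) -> None:
    """TSV: sample_id, endpoint_flag, manifold_distance, color, bin_label."""
    n = outline.dist_from_endpoint.size
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("sample_id\tendpoint_flag\tmanifold_distance\tcolor\tbin_label\n")
        for i in range(n):
            fh.write(
                f"{ids[i]}\t{int(i == outline.endpoint)}\t"
                f"{_FMT % outline.dist_from_endpoint[i]}\t"
                f"{_FMT % outline.color[i]}\t{outline.pseudo_labels[i]}\n"
            )


def write_projection(path_u: str, proj, path_mu: str | None = None) -> None:
    """U as TSV with components named u1..uR; optionally mu_Q alongside."""
    R = proj.U.shape[1]
    write_matrix(path_u, proj.U, col_names=[f"u{s + 1}" for s in range(R)])
    if path_mu is not None:
        write_matrix(path_mu, proj.mu_Q, col_names=[f"u{s + 1}" for s in range(R)])


def write_embedding(path: str, model, outline=None, sample_ids=None) -> None:
    """TSV: sample_id, x, y, manifold_distance, bin_label."""
    n = model.V.shape[0]
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("sample_id\tx\ty\tmanifold_distance\tbin_label\n")
        for i in range(n):
            md = _FMT % outline.dist_from_endpoint[i] if outline is not None else "NA"
            lab = str(outline.pseudo_labels[i]) if outline is not None else "NA"
            fh.write(
                f"{ids[i]}\t{_FMT % model.V[i, 0]}\t{_FMT % model.V[i, 1]}\t{md}\t{lab}\n"
            )


def write_metrics(path: str, report) -> None:
    """Single-row TSV of metric values plus the settings that produced them."""
    cols = [
        "pearson_geodesic", "demap", "knn_accuracy",
        "k_graph", "k_classifier", "n_splits", "seed",
    ]
    vals = []
    for c in cols:
        v = getattr(report, c)
        if v is None:
            vals.append("NA")
        elif isinstance(v, float):
            vals.append(_FMT % v)
        else:
            vals.append(str(v))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(vals) + "\n")
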