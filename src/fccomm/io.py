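"""Reading and writing the package's delimited-text formats.

All artifacts are plain text so runs stay portable and diffable:
FC/dissimilarity matrices as CSV/TSV (optional header row+column of ROI
names), partitions as two-column ``roi_id,label`` CSV, block parameters
as delimited matrices, and fit/selection/consensus summaries as JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .types import BlockParams, FCMatrix, Partition

__all__ = [
    "read_fc_matrix",
    "write_fc_matrix",
    "read_partition",
    "write_partition",
    "write_block_params",
    "read_block_params",
    "to_jsonable",
    "write_json",
]

_SYM_TOL = 1e-8


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_fc_matrix(path) -> FCMatrix:
    """Read and validate an FC matrix from delimited text.

    Accepts a square numeric block with an optional header row and/or
    leading column of ROI names. Asymmetries within 1e-8 are symmetrized
    with a warning, as is an off-unit diagonal; larger violations raise
    :class:`DataError` naming the offending cell.
    """
    path = Path(path)
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if raw.empty:
        raise DataError(f"{path}: empty file")

    def _numeric(s) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    roi_names = None
    header = None
    if not all(_numeric(v) for v in raw.iloc[0]):
        header = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
    if not all(_numeric(v) for v in raw.iloc[:, 0]):
        roi_names = [str(v) for v in raw.iloc[:, 0]]
        raw = raw.iloc[:, 1:]
    elif header is not None:
        # header only: names are the header cells (minus a placeholder)
        roi_names = header[1:] if len(header) == raw.shape[1] + 1 else header

    try:
        w = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric entry ({exc})") from exc
    if w.shape[0] != w.shape[1]:
        raise DataError(f"{path}: matrix is {w.shape[0]} x {w.shape[1]}, not square")
    bad = np.argwhere(np.isnan(w))
    if bad.size:
        i, j = bad[0]
        raise DataError(f"{path}: NaN entry at row {i + 1}, column {j + 1}")

    asym = np.abs(w - w.T)
    if asym.max() > _SYM_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise DataError(
            f"{path}: A[{i + 1}][{j + 1}]={w[i, j]} != A[{j + 1}][{i + 1}]="
            f"{w[j, i]} beyond tolerance {_SYM_TOL}"
        )
    if asym.max() > 0:
        warnings.warn(f"{path}: symmetrized asymmetries up to {asym.max():.2e}")
        w = 0.5 * (w + w.T)
    d = np.diag(w)
    if np.any(d != 1.0):
        if np.abs(d - 1.0).max() > _SYM_TOL:
            warnings.warn(
                f"{path}: diagonal forced to 1 (largest deviation "
                f"{np.abs(d - 1.0).max():.2e})"
            )
        np.fill_diagonal(w, 1.0)
    names = tuple(str(x) for x in roi_names) if roi_names is not None else None
    return FCMatrix(w, roi_names=names)


def write_fc_matrix(path, fc: FCMatrix, header: bool = False) -> None:
    """Write an FC matrix as delimited text at 17 significant digits."""
    path = Path(path)
    sep = _sep_for(path)
    names = fc.roi_names or tuple(f"ROI{i + 1}" for i in range(fc.n))
    with open(path, "w") as fh:
        if header:
            fh.write(sep.join(["", *names]) + "\n")
        for i in range(fc.n):
            row = sep.join(f"{x:.17g}" for x in fc.weights[i])
            fh.write((names[i] + sep + row if header else row) + "\n")


def read_partition(path) -> Partition:
    """Read a two-column ``roi_id,label`` partition file (ordered by roi_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (roi_id, label)")
    df = df.sort_values(df.columns[0])
    labels = df.iloc[:, 1].to_numpy(dtype=np.int64)
    return Partition.from_labels(labels)


def write_partition(path, z: Partition) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(f"roi_id{sep}label\n")
        for i, lab in enumerate(z.labels, start=1):
            fh.write(f"{i}{sep}{lab}\n")


def write_block_params(prefix, params: BlockParams) -> tuple[Path, Path]:
    """Write mu and sigma2 as ``<prefix>_mu.csv`` / ``<prefix>_sigma2.csv``."""
    prefix = Path(prefix)
    paths = (
        prefix.with_name(prefix.name + "_mu.csv"),
        prefix.with_name(prefix.name + "_sigma2.csv"),
    )
    for p, m in zip(paths, (params.mu, params.sigma2)):
        np.savetxt(p, m, delimiter=",", fmt="%.17g")
    return paths


def read_block_params(prefix) -> BlockParams:
    prefix = Path(prefix)
    mu = np.loadtxt(prefix.with_name(prefix.name + "_mu.csv"), delimiter=",", ndmin=2)
    s2 = np.loadtxt(
        prefix.with_name(prefix.name + "_sigma2.csv"), delimiter=",", ndmin=2
    )
    return BlockParams(mu=mu, sigma2=s2)


def to_jsonable(obj):
    """Recursively convert numpy containers/scalars for JSON output."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return repr(obj)
    return obj


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
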