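"""Readers/writers for count matrices, curve vectors, and JSON reports."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .matrix_sim import CountMatrix
from .rarefaction import RarefactionCurve, curve_from_vector

__all__ = [
    "SCHEMA_VERSION",
    "ReportBundle",
    "read_count_matrix",
    "write_count_matrix",
    "read_curve_vector",
    "write_curve",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise DataValidationError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataValidationError(f"{path}: empty data section")
    values = df.to_numpy()

    def _bad_cell(mask: np.ndarray, what: str) -> None:
        i, j = map(int, np.argwhere(mask)[0])
        raise DataValidationError(
            f"{path}: {what} at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )

    if not np.issubdtype(values.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(coerced)):
            _bad_cell(~np.isfinite(coerced), "non-numeric cell")
        values = coerced
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        _bad_cell(~np.isfinite(values), "non-numeric cell")
    if np.any(np.mod(values, 1) != 0):
        _bad_cell(np.mod(values, 1) != 0, "non-integer count")
    if np.any(values < 0):
        _bad_cell(values < 0, "negative count")
    return CountMatrix(
        counts=values.astype(np.int64),
        gene_ids=tuple(map(str, df.index)),
        sample_ids=tuple(map(str, df.columns)),
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, index=list(matrix.gene_ids), columns=list(matrix.sample_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_curve_vector(path: str | Path) -> RarefactionCurve:
    """Read a depth-richness TSV: two columns (depth, richness) or three
    (depth, richness, kind).  Depth must be strictly increasing."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataValidationError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected at least two columns (depth, richness)")
    depths = df.iloc[:, 0].to_numpy()
    richness = df.iloc[:, 1].to_numpy(dtype=float)
    kinds = tuple(df.iloc[:, 2].astype(str)) if df.shape[1] >= 3 else None
    return curve_from_vector(depths, richness, kinds)


def write_curve(curve: RarefactionCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"depth": curve.depths, "richness": curve.richness, "kind": list(curve.kinds)}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ReportBundle:
    """All stage outputs of one run, serializable to JSON losslessly."""

    tool_version: str
    seed: int | None = None
    inputs_digest: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    payload = _jsonable(dataclasses.asdict(bundle))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
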