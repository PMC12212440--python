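"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (feature_id [, chrom, start, end], one integer column
per sample), sample sheets as CSV, peak sets as 6-column BED (0-based,
half-open), and summaries/manifests as JSON. Write-then-read round trips
reproduce the in-memory structures exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix, CountMatrixError, SampleDesign

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "write_bed",
    "write_json",
    "read_json",
]

_COORD_COLS = ["chrom", "start", "end"]
_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps repeated runs byte-identical


def read_counts(path: str | Path, library_sizes=None) -> CountMatrix:
    """Parse a counts TSV into a :class:`CountMatrix`.

    Layout: header row; first column ``feature_id``; optional ``chrom``,
    ``start``, ``end`` coordinate columns; remaining columns integer
    counts, one per sample. Errors cite the offending row (1-based, header
    excluded) or feature id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        raise CountMatrixError(f"{path}: first column must be 'feature_id'")
    has_coords = all(c in df.columns for c in _COORD_COLS)
    meta_cols = ["feature_id"] + (_COORD_COLS if has_coords else [])
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise CountMatrixError(f"{path}: no sample columns found")
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        for col in sample_cols:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise CountMatrixError(
                    f"{path}: non-numeric count at row {row}, column {col!r}"
                )
    if np.any(counts != np.rint(counts)):
        r, c = np.argwhere(counts != np.rint(counts))[0]
        raise CountMatrixError(
            f"{path}: non-integer count at row {int(r) + 1}, column {sample_cols[int(c)]!r}"
        )
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        raise CountMatrixError(
            f"{path}: negative count at row {int(r) + 1}, column {sample_cols[int(c)]!r}"
        )
    coords = df[_COORD_COLS].reset_index(drop=True) if has_coords else None
    return CountMatrix(
        counts=counts.astype(np.int64),
        feature_ids=list(df["feature_id"].astype(str)),
        sample_ids=sample_cols,
        coords=coords,
        library_sizes=library_sizes,
    )


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"feature_id": matrix.feature_ids})
    if matrix.coords is not None:
        for c in _COORD_COLS:
            df[c] = matrix.coords[c].to_numpy()
    for j, s in enumerate(matrix.sample_ids):
        df[s] = matrix.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    """Write peaks as 6-column BED sorted by (chrom, start).

    Expects columns ``chrom``, ``start``, ``end``, ``feature_id`` and
    optionally ``l2fc``. Score encodes effect size as
    ``round(1000 * min(1, l2fc / 5))`` clipped to [0, 1000]; strand is
    ``"."`` (the assays are unstranded at the peak level). An empty
    feature set writes an empty file.
    """
    path = Path(path)
    required = {"chrom", "start", "end", "feature_id"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features table missing coordinate columns: {sorted(missing)}")
    df = features.sort_values(["chrom", "start"], kind="mergesort")
    if "l2fc" in df.columns:
        score = np.rint(1000 * np.minimum(1.0, df["l2fc"].to_numpy() / 5.0))
        score = np.clip(score, 0, 1000).astype(int)
    else:
        score = np.zeros(len(df), dtype=int)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy().astype(int),
            "end": df["end"].to_numpy().astype(int),
            "name": df["feature_id"].to_numpy(),
            "score": score,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer with fixed float formatting (deterministic bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
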