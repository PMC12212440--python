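"""Core containers: feature-by-sample count matrices and sample designs.

A :class:`CountMatrix` holds raw integer counts for genomic features (peaks
with BED-style coordinates, or genes) across sequencing libraries, together
with per-library sizes used for counts-per-million (CPM) normalization. A
:class:`SampleDesign` maps each library to its experimental condition
(stimulus, timepoint, washout treatment, replicate).

Coordinates follow the BED convention throughout: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "SampleDesign", "CountMatrixError", "DesignError"]


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


class DesignError(ValueError):
    """Raised when a sample design is inconsistent with the data."""


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with optional peak coordinates.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_features, n_samples)``.
    feature_ids
        Unique feature identifiers (peak ids or gene ids), length
        ``n_features``.
    sample_ids
        Unique library identifiers, length ``n_samples``.
    coords
        Optional DataFrame with columns ``chrom``, ``start``, ``end``
        (0-based, half-open), indexed like ``feature_ids``. Genes have no
        coordinates.
    library_sizes
        Per-sample total read counts used for CPM scaling. When omitted,
        column sums of ``counts`` are used. Explicit sizes represent the
        total aligned reads of each library, of which reads falling in the
        quantified features are typically a minority.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    coords: pd.DataFrame | None = None
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D features x samples array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise CountMatrixError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise CountMatrixError("counts must be non-negative")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != self.counts.shape[0]:
            raise CountMatrixError("feature_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise CountMatrixError("sample_ids length does not match counts columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = pd.Index(self.feature_ids)
            dupe = dupes[dupes.duplicated()][0]
            raise CountMatrixError(f"duplicated feature_id: {dupe!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountMatrixError("sample_ids must be unique")
        if self.coords is not None:
            missing = {"chrom", "start", "end"} - set(self.coords.columns)
            if missing:
                raise CountMatrixError(f"coords missing columns: {sorted(missing)}")
            if len(self.coords) != len(self.feature_ids):
                raise CountMatrixError("coords length does not match features")
            bad = self.coords["start"] >= self.coords["end"]
            if bad.any():
                fid = self.feature_ids[int(np.flatnonzero(bad.to_numpy())[0])]
                raise CountMatrixError(f"feature {fid!r} has start >= end")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if self.library_sizes.shape != (self.counts.shape[1],):
                raise CountMatrixError("library_sizes length does not match samples")
        if (self.library_sizes < 0).any():
            raise CountMatrixError("library_sizes must be non-negative")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise CountMatrixError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_features(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to a boolean/index feature mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        coords = self.coords.iloc[keep].reset_index(drop=True) if self.coords is not None else None
        return CountMatrix(
            counts=self.counts[keep],
            feature_ids=[self.feature_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            coords=coords,
            library_sizes=self.library_sizes.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (features as index, samples as columns)."""
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


#: columns a design sheet must provide; ``condition`` keys all group lookups
REQUIRED_DESIGN_COLUMNS = ("sample_id", "condition")

OPTIONAL_DESIGN_COLUMNS = (
    "assay",
    "stimulus",
    "time_h",
    "washout_treatment",
    "pretreatment",
    "replicate",
    "library_size",
)


@dataclass
class SampleDesign:
    """Per-sample metadata table defining conditions and contrasts.

    Wraps a DataFrame with at least ``sample_id`` and ``condition`` columns.
    ``condition`` is a flat label such as ``ifng_8h`` or
    ``ifng_wash_media``; all grouping in the analysis modules goes through
    it, so the generator and any external sample sheet only need to agree on
    these labels.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise DesignError(f"design is missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["sample_id"].astype(str)
        if ids.duplicated().any():
            raise DesignError(f"duplicated sample_id: {ids[ids.duplicated()].iloc[0]!r}")
        self.table["sample_id"] = ids
        self.table["condition"] = self.table["condition"].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition (possibly empty)."""
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])

    def require_samples(self, condition: str) -> list[str]:
        samples = self.samples_in(condition)
        if not samples:
            raise DesignError(f"no samples for condition {condition!r}")
        return samples

    def library_sizes_for(self, sample_ids: list[str]) -> np.ndarray | None:
        """Explicit library sizes from the sheet, or None if absent."""
        if "library_size" not in self.table.columns:
            return None
        sub = self.table.set_index("sample_id").loc[sample_ids, "library_size"]
        if sub.isna().any():
            return None
        return sub.to_numpy(dtype=float)

    def validate_against(self, matrix: CountMatrix) -> None:
        if set(self.sample_ids) != set(matrix.sample_ids):
            raise DesignError("design sample_ids do not match count matrix columns")
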