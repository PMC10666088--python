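"""Expression-sample container, CSV input/output and arcsinh preprocessing.

Mass-cytometry (CyTOF) samples arrive as cells x markers tables of raw ion
counts, one row per cell and one numeric column per cellular marker.  All
classification logic in this package operates in arcsinh space,
``arcsinh(x / cofactor)`` with cofactor 5, the standard variance-stabilising
transform for mass cytometry.  A labelled reference sample additionally
carries a per-cell cell-type column in which a reserved sentinel (default
``"ungated"``, matched case-insensitively) marks cells left unassigned by
manual gating.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_UNGATED = "ungated"
DEFAULT_COFACTOR = 5.0

__all__ = [
    "DEFAULT_UNGATED",
    "DEFAULT_COFACTOR",
    "SampleError",
    "ExpressionSample",
    "CentroidSet",
    "read_sample_csv",
    "write_sample_csv",
    "arcsinh_transform",
    "ensure_transformed",
    "compute_centroids",
]


class SampleError(ValueError):
    """Malformed sample data (parse errors, invariant violations)."""


def _canonical_labels(labels: Sequence[str], sentinel: str) -> np.ndarray:
    """Normalise any case variant of the ungated sentinel to its canonical form."""
    out = np.asarray([str(v) for v in labels], dtype=object)
    low = sentinel.lower()
    for k, v in enumerate(out):
        if v.lower() == low:
            out[k] = sentinel
    return out


@dataclass(frozen=True)
class ExpressionSample:
    """A cells x markers expression matrix with optional per-cell labels.

    Parameters
    ----------
    matrix : ndarray of shape (n_cells, n_markers)
        Expression values; raw ion counts when ``is_raw`` is true, otherwise
        arcsinh-transformed intensities.
    marker_names : tuple of str
        Unique, ordered marker (channel) identifiers, one per column.
    cell_ids : tuple
        Ordered per-cell identifiers (row order).
    labels : ndarray of str, optional
        Per-cell cell-type labels; the ungated sentinel marks unassigned cells.
    is_raw : bool
        True while values are untransformed ion counts.
    ungated_sentinel : str
        Reserved label for unassigned cells (matched case-insensitively).
    """

    matrix: np.ndarray
    marker_names: tuple[str, ...]
    cell_ids: tuple = ()
    labels: np.ndarray | None = None
    is_raw: bool = False
    ungated_sentinel: str = DEFAULT_UNGATED

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2:
            raise SampleError("expression matrix must be 2-dimensional")
        object.__setattr__(self, "matrix", matrix)
        markers = tuple(str(m) for m in self.marker_names)
        if matrix.shape[1] != len(markers):
            raise SampleError(
                f"matrix has {matrix.shape[1]} columns but "
                f"{len(markers)} marker names were given"
            )
        dupes = sorted(m for m, k in Counter(markers).items() if k > 1)
        if dupes:
            raise SampleError(f"duplicate marker names: {dupes}")
        object.__setattr__(self, "marker_names", markers)
        cell_ids = tuple(self.cell_ids) if len(self.cell_ids) else tuple(range(matrix.shape[0]))
        if len(cell_ids) != matrix.shape[0]:
            raise SampleError(
                f"{len(cell_ids)} cell ids for {matrix.shape[0]} matrix rows"
            )
        object.__setattr__(self, "cell_ids", cell_ids)
        if not np.all(np.isfinite(matrix)):
            bad = np.argwhere(~np.isfinite(matrix))[0]
            raise SampleError(
                f"missing/non-finite value at row {bad[0]}, column {markers[bad[1]]!r}"
            )
        if self.labels is not None:
            labels = _canonical_labels(np.asarray(self.labels, dtype=object), self.ungated_sentinel)
            if labels.shape[0] != matrix.shape[0]:
                raise SampleError(
                    f"{labels.shape[0]} labels for {matrix.shape[0]} cells"
                )
            object.__setattr__(self, "labels", labels)

    # -- basic geometry -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.n_cells

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise SampleError(f"marker {marker!r} not in sample") from None

    def marker_column(self, marker: str) -> np.ndarray:
        return self.matrix[:, self.marker_index(marker)]

    # -- labels ---------------------------------------------------------

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def gated_types(self) -> tuple[str, ...]:
        """Sorted gated cell types present in the labels (sentinel excluded)."""
        if self.labels is None:
            raise SampleError("sample has no labels")
        return tuple(sorted(set(self.labels) - {self.ungated_sentinel}))

    def gated_mask(self) -> np.ndarray:
        if self.labels is None:
            raise SampleError("sample has no labels")
        return self.labels != self.ungated_sentinel

    # -- derived samples ------------------------------------------------

    def subset_markers(self, markers: Sequence[str]) -> "ExpressionSample":
        """Restrict (and reorder) to the given classification markers."""
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise SampleError(f"markers not in sample: {missing}")
        idx = [self.marker_names.index(m) for m in markers]
        return replace(self, matrix=self.matrix[:, idx], marker_names=tuple(markers))

    def subset_cells(self, mask: np.ndarray) -> "ExpressionSample":
        mask = np.asarray(mask)
        labels = self.labels[mask] if self.labels is not None else None
        ids = tuple(np.asarray(self.cell_ids, dtype=object)[mask])
        return replace(self, matrix=self.matrix[mask], cell_ids=ids, labels=labels)

    def to_dataframe(self, label_column: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.marker_names))
        if label_column is not None:
            if self.labels is None:
                raise SampleError("sample has no labels to export")
            df[label_column] = self.labels
        return df


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

def read_sample_csv(
    path: str | Path,
    label_column: str | None = None,
    ungated_sentinel: str = DEFAULT_UNGATED,
    markers: Sequence[str] | None = None,
) -> ExpressionSample:
    """Read a cells x markers CSV (header row, comma-separated, UTF-8).

    All columns except ``label_column`` are treated as numeric markers unless
    an explicit ``markers`` subset is given.  Values are returned untransformed
    and the sample is flagged raw.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise SampleError(f"{path}: empty file") from None
    dupes = sorted(name for name, k in Counter(header).items() if k > 1)
    if dupes:
        raise SampleError(f"{path}: duplicate marker columns {dupes}")
    if label_column is not None and label_column not in header:
        raise SampleError(f"{path}: label column {label_column!r} not present")

    df = pd.read_csv(path, float_precision="round_trip")
    labels = None
    if label_column is not None:
        labels = df.pop(label_column).astype(str).to_numpy(dtype=object)
    if markers is not None:
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise SampleError(f"{path}: requested markers not present: {missing}")
        df = df[list(markers)]

    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna()
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SampleError(
                f"{path}: non-numeric marker value {df[col].iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise SampleError(f"{path}: missing value at row {r}, column {df.columns[c]!r}")

    return ExpressionSample(
        matrix=df.to_numpy(dtype=float),
        marker_names=tuple(df.columns),
        labels=labels,
        is_raw=True,
        ungated_sentinel=ungated_sentinel,
    )


def write_sample_csv(
    sample: ExpressionSample,
    path: str | Path,
    label_column: str | None = "cell_type",
) -> None:
    """Write a sample to CSV; labels are included when present and requested.

    Floats are written with 17 significant digits so a write/read round trip
    reproduces the matrix exactly.
    """
    col = label_column if (label_column is not None and sample.has_labels) else None
    sample.to_dataframe(label_column=col).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def arcsinh_transform(
    sample: ExpressionSample, cofactor: float = DEFAULT_COFACTOR
) -> ExpressionSample:
    """Apply ``x -> arcsinh(x / cofactor)`` to every expression value.

    The transform is strictly monotone per marker, so within-marker rankings
    are preserved.  Applying it to an already-transformed sample is an error.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    if not sample.is_raw:
        raise SampleError("sample already arcsinh-transformed")
    return replace(sample, matrix=np.arcsinh(sample.matrix / cofactor), is_raw=False)


def ensure_transformed(
    sample: ExpressionSample, cofactor: float = DEFAULT_COFACTOR
) -> ExpressionSample:
    """Transform raw samples; pass already-transformed samples through."""
    return arcsinh_transform(sample, cofactor) if sample.is_raw else sample


# ---------------------------------------------------------------------------
# Centroids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentroidSet:
    """Per-cell-type mean expression vectors in arcsinh space.

    Holds exactly the gated cell types (never the ungated sentinel), each with
    one mean per classification marker, in the shared marker ordering.
    """

    marker_names: tuple[str, ...]
    centroids: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cents = {}
        for t, v in self.centroids.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.marker_names),):
                raise SampleError(
                    f"centroid for {t!r} has {v.shape[0]} entries, "
                    f"expected {len(self.marker_names)}"
                )
            cents[str(t)] = v
        object.__setattr__(self, "centroids", cents)
        object.__setattr__(self, "marker_names", tuple(self.marker_names))

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted(self.centroids))

    def __contains__(self, cell_type: str) -> bool:
        return cell_type in self.centroids

    def __getitem__(self, cell_type: str) -> np.ndarray:
        return self.centroids[cell_type]

    def __len__(self) -> int:
        return len(self.centroids)

    def as_matrix(self) -> np.ndarray:
        """Centroid matrix of shape (n_types, n_markers), rows in sorted type order."""
        return np.vstack([self.centroids[t] for t in self.types])

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Euclidean distances from each row of ``X`` to each centroid.

        Returns an (n_cells, n_types) array with columns in sorted type order.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = self.as_matrix()
        if X.shape[1] != C.shape[1]:
            raise SampleError(
                f"cell vectors have {X.shape[1]} markers, centroids {C.shape[1]}"
            )
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2)


def compute_centroids(
    sample: ExpressionSample, cell_types: Iterable[str] | None = None
) -> CentroidSet:
    """Arithmetic-mean centroid of every gated cell type; ungated cells excluded.

    ``cell_types`` optionally declares the expected type set; a declared type
    with zero cells raises an error listing the missing types.
    """
    if sample.is_raw:
        raise SampleError("centroids must be computed on arcsinh-transformed data")
    if sample.labels is None:
        raise SampleError("centroids require a labelled sample")
    present = sample.gated_types()
    if cell_types is not None:
        declared = sorted(set(cell_types) - {sample.ungated_sentinel})
        missing = [t for t in declared if t not in present]
        if missing:
            raise SampleError(f"declared cell types with zero cells: {missing}")
        present = tuple(declared)
    cents = {
        t: sample.matrix[sample.labels == t].mean(axis=0) for t in present
    }
    return CentroidSet(marker_names=sample.marker_names, centroids=cents)
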