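"""Loading, validation, and min-max normalization of labeled expression matrices.

A dataset is a dense ``n_samples x n_features`` real-valued matrix (expression
intensities, spectral peak heights, ...) with unique feature names and one class
label per sample.  Files are delimited text with a header row; labels come either
from a designated column of the matrix file or from a separate one-label-per-line
file.  Because microarray exports frequently store probes in rows and samples in
columns, both orientations are accepted and normalized internally to samples-in-rows.

Min-max scaling maps every feature column onto [0, 1]:

    x_scaled = (x - min(X)) / (max(X) - min(X))

A constant column makes the denominator zero; such a column is mapped to all
zeros (it carries no class information, and 0 keeps the value inside [0, 1] and
non-negative, which the chi-squared scorer requires).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Dataset", "load_dataset", "minmax_scale", "write_dataset"]


@dataclass
class Dataset:
    """Labeled expression matrix, samples in rows.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; no NaN/inf allowed.
    feature_names
        ``n_features`` unique strings, aligned with the columns of ``values``.
    labels
        ``n_samples`` class identifiers (kept as given, typically strings);
        at least two distinct classes are required.
    """

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if len(self.feature_names) != m:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(set(self.feature_names)) != m:
            dupes = sorted(
                {f for f in self.feature_names if self.feature_names.count(f) > 1}
            )
            raise ValueError(f"duplicate feature names: {dupes}")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if len(self.classes) < 2:
            raise ValueError("labels must contain at least 2 distinct classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def feature(self, name: str) -> np.ndarray:
        """Return the column for one feature name."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def subset(self, names: list[str]) -> np.ndarray:
        """Column submatrix for an ordered list of feature names."""
        idx = []
        for name in names:
            try:
                idx.append(self.feature_names.index(name))
            except ValueError:
                raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, idx]

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.labels
        return df


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".tab"} else ","


def load_dataset(
    path: str,
    label_spec: str,
    orientation: str = "samples-in-rows",
    delimiter: str | None = None,
) -> Dataset:
    """Read a delimited expression matrix plus class labels.

    Parameters
    ----------
    path
        CSV/TSV file with a header row (delimiter inferred from the extension
        unless ``delimiter`` is given).
    label_spec
        Either the name of the label column inside the matrix file, or the path
        of a separate text file with one label per sample (same sample order).
    orientation
        ``"samples-in-rows"`` (header = feature names) or ``"features-in-rows"``
        (first column = feature names, remaining columns = samples); the latter
        is transposed on load.  A label column inside the file is only
        meaningful for samples-in-rows.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if orientation not in {"samples-in-rows", "features-in-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)

    labels_from_file = os.path.exists(label_spec) and os.path.isfile(label_spec)

    if orientation == "features-in-rows":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df = df.T  # now samples x features
        df.columns = [str(c) for c in df.columns]
    else:
        # pandas silently renames duplicate header fields, so check them raw
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").rstrip("\r").split(sep)
        dupes = sorted({h for h in header if header.count(h) > 1})
        if dupes:
            raise ValueError(f"duplicate feature names in header: {dupes}")
        df = pd.read_csv(path, sep=sep)
        df.columns = [str(c) for c in df.columns]

    if labels_from_file:
        with open(label_spec, encoding="utf-8") as fh:
            labels = np.array([line.strip() for line in fh if line.strip()])
        matrix = df
    else:
        if label_spec not in df.columns:
            raise ValueError(
                f"label column {label_spec!r} not found and no such labels file exists"
            )
        labels = df[label_spec].to_numpy()
        matrix = df.drop(columns=[label_spec])

    if len(labels) != len(matrix):
        raise ValueError(
            f"label count {len(labels)} does not match sample count {len(matrix)}"
        )

    non_numeric = [
        c for c in matrix.columns if not pd.api.types.is_numeric_dtype(matrix[c])
    ]
    if non_numeric:
        raise ValueError(f"non-numeric values in feature columns: {non_numeric}")
    if matrix.isna().any().any():
        raise ValueError("missing values in feature matrix (imputation unsupported)")

    return Dataset(
        values=matrix.to_numpy(dtype=float),
        feature_names=list(matrix.columns),
        labels=labels,
    )


def minmax_scale(data: Dataset) -> Dataset:
    """Scale every feature column to [0, 1]; constant columns become all-zero.

    Idempotent, and order-preserving within each column.
    """
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    scaled = (data.values - lo) / safe
    scaled[:, constant] = 0.0
    return replace(data, values=scaled)


def write_dataset(
    data: Dataset,
    path: str,
    label_column: str = "class",
    delimiter: str | None = None,
) -> None:
    """Write samples-in-rows with the label as the last column."""
    sep = _delimiter_for(path, delimiter)
    data.to_frame(label_column).to_csv(path, sep=sep, index=False)
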