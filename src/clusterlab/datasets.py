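"""Feature-table loading, z-score standardization and the seven benchmark profiles.

A :class:`Dataset` couples an ``n x d`` observation matrix with optional
integer class labels.  Labels are carried along for external validity
indices only; no clustering routine in this package ever reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError, ParseError

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "?"}


@dataclass(frozen=True)
class DatasetProfile:
    """Shape descriptor of one benchmark dataset: sizes and reference cluster count."""

    name: str
    n: int
    d: int
    n_classes: int
    k_optimal: int


#: The seven benchmark profiles (sample size, features, classes, reference k).
PROFILES: dict[str, DatasetProfile] = {
    p.name: p
    for p in (
        DatasetProfile("leukemia", 64, 4, 2, 2),
        DatasetProfile("prostate", 30, 3, 2, 2),
        DatasetProfile("colon", 111, 4, 2, 2),
        DatasetProfile("haberman", 306, 3, 2, 2),
        DatasetProfile("iris", 150, 4, 3, 3),
        DatasetProfile("wine", 178, 13, 3, 3),
        DatasetProfile("glass", 214, 10, 7, 7),
    )
}


@dataclass
class Dataset:
    """Observations, optional ground-truth labels and a standardization flag.

    Attributes
    ----------
    name : str
        Identifier used in reports.
    X : ndarray of shape (n, d)
        Feature matrix, one row per observation.
    labels : ndarray of shape (n,) or None
        Ground-truth classes encoded as consecutive integers from 0.
    standardized : bool
        True once every column has been z-scored (sample SD, ``ddof=1``).
    dropped_rows : int
        Number of rows removed at load time because of missing values.
    feature_names : list of str
        Column headers of the feature columns.
    """

    name: str
    X: np.ndarray
    labels: Optional[np.ndarray] = None
    standardized: bool = False
    dropped_rows: int = 0
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InputError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 2 or d < 1:
            raise InputError(f"need n >= 2 and d >= 1, got n={n}, d={d}")
        if not np.isfinite(self.X).all():
            raise InputError("X contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise InputError("labels length must equal number of rows")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(d)]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_table(path: str | Path, label_column: Optional[str] = None, name: Optional[str] = None) -> Dataset:
    """Read a delimited text table (CSV or TSV, header row required).

    Rows with missing values in any feature column are dropped and counted in
    ``dropped_rows``.  A non-numeric, non-missing feature cell raises
    :class:`ParseError` naming the offending row and column.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if label_column is not None and label_column not in raw.columns:
        raise ConfigError(f"label column {label_column!r} not found in {path.name}")

    feature_cols = [c for c in raw.columns if c != label_column]
    values = np.empty((len(raw), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(raw[col].to_numpy()):
            token = str(cell).strip()
            if token.lower() in _NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {token!r} at row {i}, column {col!r} in {path.name}"
                ) from None

    keep = np.isfinite(values).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("load_table(%s): dropped %d row(s) with missing values", path.name, dropped)
    values = values[keep]
    if values.shape[0] < 2:
        raise InputError(f"{path.name}: fewer than 2 complete rows")

    labels = None
    if label_column is not None:
        raw_labels = raw[label_column].to_numpy()[keep]
        _, labels = np.unique(raw_labels, return_inverse=True)

    return Dataset(
        name=name or path.stem,
        X=values,
        labels=labels,
        standardized=False,
        dropped_rows=dropped,
        feature_names=feature_cols,
    )


def write_table(ds: Dataset, path: str | Path, label_column: str = "class") -> None:
    """Write a Dataset back to CSV in the dialect :func:`load_table` reads."""
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    if ds.labels is not None:
        df[label_column] = ds.labels
    df.to_csv(path, index=False)


def standardize(ds: Dataset) -> Dataset:
    """Z-score every feature column using the sample (n-1) standard deviation.

    Returns a new Dataset; labels pass through unchanged.  A zero-variance
    column is an error because its z-score is undefined.
    """
    if ds.standardized:
        raise InputError(f"dataset {ds.name!r} is already standardized")
    sd = ds.X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        cols = ", ".join(ds.feature_names[j] for j in zero)
        raise InputError(f"zero-variance column(s): {cols}")
    Z = (ds.X - ds.X.mean(axis=0)) / sd
    return replace(ds, X=Z, standardized=True)
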