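"""Observed-data container, standardization and CSV I/O.

All estimation works on columns standardized to mean 0 and variance 1, with
the variance computed with divisor N so that unit-variance component scores
satisfy the criterion constraint sum_i diag(gamma_i gamma_i') = N I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dataset", "standardize", "load_data"]


@dataclass
class Dataset:
    """An N×J table of observed variables.

    ``center``/``scale`` record the transformation applied by
    :func:`standardize` (both ``None`` for raw data); they allow new rows —
    e.g. held-out cross-validation folds — to be mapped onto the same scale.
    """

    values: np.ndarray
    column_names: tuple[str, ...]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("data must be a 2-D table")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match data width")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing or non-finite value at row {bad[0]}, "
                f"column {self.column_names[bad[1]]!r}; complete data required"
            )

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Dataset":
        names = [str(c) for c in df.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in data")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric data: {exc}") from exc
        return cls(values, tuple(names))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_names))

    @property
    def is_standardized(self) -> bool:
        return self.center is not None

    def transform_rows(self, values: np.ndarray) -> np.ndarray:
        """Standardize new rows with this dataset's stored center/scale."""
        if not self.is_standardized:
            raise ValueError("dataset carries no standardization to apply")
        return (np.asarray(values, dtype=float) - self.center) / self.scale


def standardize(dataset: Dataset) -> Dataset:
    """Return a column-standardized copy (mean 0, variance 1, divisor N).

    Raises ``ValueError`` naming the offending column if any column has zero
    variance.  Idempotent up to floating point on already-standardized data.
    """
    X = dataset.values
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0 -> divisor N
    dead = np.nonzero(scale <= 0)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance column {dataset.column_names[dead[0]]!r} cannot be standardized"
        )
    return Dataset(
        (X - center) / scale, dataset.column_names, center=center, scale=scale
    )


def load_data(path) -> Dataset:
    """Read an observations CSV (header row, numeric cells) into a Dataset.

    Genotype columns coded {1,2,3} are ordinary numeric columns.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    names = [h.strip() for h in header]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column name(s) in {path}: {dup}")
    df = pd.read_csv(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError("missing values in data; complete data required")
    return Dataset.from_dataframe(df)
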