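"""Labeled TSV/CSV readers and writers for tables, vectors and matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from compmix.compositional import CompositionTable, CountTable
from compmix.kernels import DistanceMatrix

__all__ = [
    "read_count_table",
    "read_composition_table",
    "read_outcome",
    "read_distance_matrix",
    "write_table",
    "write_distance_matrix",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row IDs {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column IDs {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or non-numeric cells")
    return df


def read_count_table(path: str | Path) -> CountTable:
    """First column = sample IDs, header row = taxon IDs."""
    df = _read_frame(path)
    return CountTable(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def read_composition_table(path: str | Path) -> CompositionTable:
    df = _read_frame(path)
    return CompositionTable(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def read_outcome(path: str | Path, sample_ids: list[str] | None = None) -> np.ndarray:
    """Outcome vector keyed by sample ID (first column)."""
    df = _read_frame(path)
    series = df.iloc[:, 0]
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(df.index.astype(str)))
        extra = sorted(set(df.index.astype(str)) - set(sample_ids))
        if missing or extra:
            raise ValueError(
                f"{path}: sample-ID mismatch with abundance table; "
                f"missing from outcome: {missing[:5]}, extra in outcome: {extra[:5]}"
            )
        series = series.loc[sample_ids]
    return series.to_numpy()


def read_distance_matrix(path: str | Path, axis: str = "samples") -> DistanceMatrix:
    df = _read_frame(path)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column IDs of a distance matrix must match")
    values = df.to_numpy()
    asym = np.abs(values - values.T)
    if asym.size and asym.max() > 1e-10:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: asymmetric distance matrix; worst cell ({df.index[i]}, {df.columns[j]}) "
            f"differs from its transpose by {asym[i, j]:.3g}"
        )
    return DistanceMatrix(values, axis=axis, ids=list(df.index.astype(str)))


def write_table(path: str | Path, values: np.ndarray, index: list[str], columns: list[str]) -> None:
    pd.DataFrame(values, index=index, columns=columns).to_csv(path, sep=_sep(path))


def write_distance_matrix(path: str | Path, D: DistanceMatrix) -> None:
    write_table(path, D.D, D.ids, D.ids)
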