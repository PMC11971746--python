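"""Compositional tables: pseudo-counts, closure, and the log design matrix.

Relative abundances carry only ratio information; regression on them uses
``Z = log(X)`` together with a (soft) sum-to-zero constraint on the slope
vector, which makes the linear predictor invariant to per-sample rescaling
of the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountTable",
    "CompositionTable",
    "add_pseudocount",
    "close",
    "softmax_rows",
]


def _default_ids(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class CountTable:
    """Raw (or pseudo-count adjusted) taxon counts, samples in rows."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count table must be 2-dimensional (samples x taxa)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("count table contains non-finite entries")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"count table has negative entry at sample row {bad[0]}, taxon column {bad[1]}"
            )
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = _default_ids("S", n)
        if not self.taxon_ids:
            self.taxon_ids = _default_ids("T", m)
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise ValueError("id lengths do not match table shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CompositionTable:
    """Closed compositions ``X`` (rows sum to 1) plus ``Z = log(X)``."""

    X: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("composition table must be 2-dimensional")
        if np.any(self.X <= 0):
            raise ValueError(
                "composition has nonpositive entries; apply add_pseudocount() before closure"
            )
        rowsums = self.X.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-8):
            raise ValueError("composition rows must sum to 1; use close() to normalize")
        n, m = self.X.shape
        if not self.sample_ids:
            self.sample_ids = _default_ids("S", n)
        if not self.taxon_ids:
            self.taxon_ids = _default_ids("T", m)
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise ValueError("id lengths do not match table shape")
        self.Z = np.log(self.X)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.X.shape[1]


def add_pseudocount(
    counts: CountTable, pseudo: float = 0.5, mode: str = "constant"
) -> CountTable:
    """Replace zero entries so the log transform is defined.

    Parameters
    ----------
    counts:
        Nonnegative count (or abundance) table.
    pseudo:
        Replacement value in ``"constant"`` mode, or the multiplier of the
        minimum positive entry in ``"relative-min"`` mode.  Default 0.5.
    mode:
        ``"constant"`` replaces zeros by ``pseudo``; ``"relative-min"``
        replaces zeros by ``pseudo`` times the smallest positive entry of
        the table.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    values = counts.values.copy()
    zeros = values == 0
    if mode == "constant":
        fill = pseudo
    elif mode == "relative-min":
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("table has no positive entries; relative-min mode undefined")
        fill = pseudo * positive.min()
    else:
        raise ValueError(f"unknown pseudo-count mode {mode!r}")
    values[zeros] = fill
    return CountTable(values, list(counts.sample_ids), list(counts.taxon_ids))


def close(counts: CountTable) -> CompositionTable:
    """Divide each row by its total, yielding relative abundances."""
    values = counts.values
    if np.any(values == 0):
        raise ValueError(
            "table still contains zeros; apply add_pseudocount() before closure"
        )
    rowsums = values.sum(axis=1, keepdims=True)
    if np.any(rowsums <= 0):
        raise ValueError("every sample row must have a positive total")
    return CompositionTable(values / rowsums, list(counts.sample_ids), list(counts.taxon_ids))


def softmax_rows(
    U: np.ndarray,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
) -> CompositionTable:
    """Row-wise softmax ``x_ij = exp(u_ij) / sum_k exp(u_ik)``.

    The maximum of each row is subtracted first; by shift invariance this
    leaves the result unchanged while preventing overflow.
    """
    U = np.asarray(U, dtype=float)
    if np.any(~np.isfinite(U)):
        raise ValueError("softmax input must be finite")
    shifted = U - U.max(axis=1, keepdims=True)
    expU = np.exp(shifted)
    X = expU / expU.sum(axis=1, keepdims=True)
    return CompositionTable(X, list(sample_ids or []), list(taxon_ids or []))
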