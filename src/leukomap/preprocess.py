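"""Ct-to-expression preprocessing for multiplex single-cell qPCR.

Raw data arrive as threshold-cycle (Ct) matrices, cells in rows and genes
in columns.  Lower Ct means higher expression; reactions that never cross
the fluorescence threshold are encoded at (or above) a background level,
28 cycles by default.  Expression on the log2 scale is obtained by
subtracting Ct from the background, with Ct values beyond the background
clamped first, so a non-detected gene has expression exactly 0.  Network
construction works on the linear (anti-logged) scale, where we keep the
convention that 0 stays 0 — "no expression" is not the same as an
expression level of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BACKGROUND_CT = 28.0

__all__ = [
    "DEFAULT_BACKGROUND_CT",
    "CtMatrix",
    "ExpressionMatrix",
    "ct_to_expression",
    "to_linear",
]


def _check_axes(data: pd.DataFrame) -> None:
    if data.index.duplicated().any():
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell identifiers: {dups}")
    if data.columns.duplicated().any():
        dups = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups}")


def _name_offenders(data: pd.DataFrame, bad: np.ndarray, what: str) -> str:
    rows, cols = np.nonzero(bad)
    pairs = [
        f"(cell={data.index[r]!r}, gene={data.columns[c]!r})"
        for r, c in list(zip(rows, cols))[:5]
    ]
    more = "" if len(rows) <= 5 else f" and {len(rows) - 5} more"
    return f"{what} at {', '.join(pairs)}{more}"


@dataclass
class CtMatrix:
    """Raw threshold-cycle values, cells x genes, plus the background level."""

    data: pd.DataFrame
    background_ct: float = DEFAULT_BACKGROUND_CT

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_axes(self.data)
        if not self.background_ct > 0:
            raise ValueError(f"background_ct must be positive, got {self.background_ct}")
        vals = self.data.to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ValueError(_name_offenders(self.data, bad, "non-finite Ct"))
        bad = vals <= 0
        if bad.any():
            raise ValueError(_name_offenders(self.data, bad, "non-positive Ct"))

    @property
    def cell_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path, background_ct: float = DEFAULT_BACKGROUND_CT) -> "CtMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        if df.isna().any().any():
            raise ValueError(
                f"{path}: missing values are not allowed; encode no-signal "
                "reactions as Ct >= background"
            )
        return cls(df, background_ct=background_ct)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "cell_id"
        out.to_csv(path)


@dataclass
class ExpressionMatrix:
    """Expression values, cells x genes, on either the log2 or the linear scale."""

    data: pd.DataFrame
    scale: str = "log2"
    background_ct: float = DEFAULT_BACKGROUND_CT

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        _check_axes(self.data)
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.scale == "log2" and (vals > self.background_ct + 1e-9).any():
            raise ValueError(
                f"log2 expression cannot exceed the background level {self.background_ct}"
            )

    @property
    def cell_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        missing = [c for c in cells if c not in self.data.index]
        if missing:
            raise KeyError(f"unknown cells: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(cells)], self.scale, self.background_ct)

    @classmethod
    def from_csv(cls, path, scale: str = "log2",
                 background_ct: float = DEFAULT_BACKGROUND_CT) -> "ExpressionMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        return cls(df, scale=scale, background_ct=background_ct)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "cell_id"
        out.to_csv(path)


def ct_to_expression(ct: CtMatrix) -> ExpressionMatrix:
    """Convert Ct values to log2-scale expression: max(0, background - Ct).

    Ct values above the background are clamped to the background first, so
    they land at exactly 0 ("no expression").  The transform is strictly
    decreasing in Ct below the background and idempotent under re-clamping.
    """
    vals = np.maximum(0.0, ct.background_ct - ct.data.to_numpy(dtype=float))
    data = pd.DataFrame(vals, index=ct.data.index, columns=ct.data.columns)
    return ExpressionMatrix(data, scale="log2", background_ct=ct.background_ct)


def to_linear(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Anti-log2 transform, with the zero-preservation convention 0 -> 0.

    A literal anti-log maps 0 to 1, which would conflate censored
    (non-detected) genes with genes expressed at one unit; keeping zeros at
    zero preserves the "no expression" semantics of the censoring rule.
    """
    if expr.scale != "log2":
        raise ValueError("to_linear expects a log2-scale matrix")
    vals = expr.data.to_numpy(dtype=float)
    out = np.where(vals > 0, np.exp2(vals), 0.0)
    data = pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(data, scale="linear", background_ct=expr.background_ct)
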