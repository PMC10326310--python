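"""Balanced unit x period panel container used by every estimation stage."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PanelDataset", "BalanceError"]


class BalanceError(ValueError):
    """The panel is missing (unit, period) cells or contains duplicates."""


class PanelDataset:
    """A balanced panel of named variables over units and calendar periods.

    Wraps a :class:`pandas.DataFrame` with a two-level ``(unit, year)`` index
    and one column per variable. Construction validates balance (every unit
    observed in every period), uniqueness, and finiteness; estimation code can
    then rely on rectangular ``n x T`` variable matrices.

    Parameters
    ----------
    df : DataFrame
        Long-format frame indexed by ``(unit, year)`` or with ``unit``/``year``
        columns.
    transforms : mapping, optional
        Per-variable provenance tag (``none``/``log``/``ratio``/``deflated``).
    """

    def __init__(self, df: pd.DataFrame, transforms: Mapping[str, str] | None = None):
        if not isinstance(df.index, pd.MultiIndex):
            if {"unit", "year"}.issubset(df.columns):
                df = df.set_index(["unit", "year"])
            else:
                raise ValueError("df must be indexed by (unit, year)")
        df = df.sort_index()
        dup = df.index.duplicated()
        if dup.any():
            cells = df.index[dup].tolist()
            raise BalanceError(f"duplicated (unit, year) rows: {cells[:10]}")
        units = df.index.get_level_values(0).unique()
        years = df.index.get_level_values(1).unique()
        full = pd.MultiIndex.from_product([units, years], names=["unit", "year"])
        missing = full.difference(df.index)
        if len(missing):
            raise BalanceError(
                f"panel is unbalanced; missing cells: {missing.tolist()[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        bad = df.columns[~np.isfinite(df.to_numpy(dtype=float)).all(axis=0)]
        if len(bad):
            raise ValueError(f"non-finite values in variables: {list(bad)}")
        self.df = df.reindex(full).astype(float)
        self.transforms = dict(transforms or {})

    # -- basic descriptors -------------------------------------------------
    @property
    def unit_ids(self) -> tuple:
        return tuple(self.df.index.get_level_values(0).unique())

    @property
    def periods(self) -> tuple:
        return tuple(self.df.index.get_level_values(1).unique())

    @property
    def variables(self) -> tuple:
        return tuple(self.df.columns)

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def T(self) -> int:
        return len(self.periods)

    def __repr__(self) -> str:
        return (f"PanelDataset(n={self.n}, T={self.T}, "
                f"variables={list(self.variables)})")

    # -- access ------------------------------------------------------------
    def matrix(self, variable: str) -> np.ndarray:
        """Return variable as an ``(n, T)`` array, units x periods, in panel order."""
        if variable not in self.df.columns:
            raise KeyError(f"unknown variable {variable!r}")
        return (
            self.df[variable].unstack(level=1).loc[list(self.unit_ids), list(self.periods)]
            .to_numpy()
        )

    def cross_section(self, variable: str, year) -> np.ndarray:
        """One period of one variable as an n-vector in unit order."""
        t = list(self.periods).index(year)
        return self.matrix(variable)[:, t]

    def subset_units(self, units: Sequence) -> "PanelDataset":
        unknown = set(units) - set(self.unit_ids)
        if unknown:
            raise KeyError(f"unknown units: {sorted(unknown)}")
        sub = self.df.loc[list(units)]
        # preserve requested unit order
        sub = sub.reindex(
            pd.MultiIndex.from_product([list(units), list(self.periods)],
                                       names=["unit", "year"])
        )
        return PanelDataset(sub, self.transforms)

    def select(self, variables: Iterable[str]) -> "PanelDataset":
        variables = list(variables)
        return PanelDataset(self.df[variables],
                            {v: self.transforms.get(v, "none") for v in variables})

    def with_variable(self, name: str, values: pd.Series | np.ndarray,
                      transform: str = "none") -> "PanelDataset":
        df = self.df.copy()
        df[name] = np.asarray(values, dtype=float) if not isinstance(values, pd.Series) else values
        tr = dict(self.transforms)
        tr[name] = transform
        return PanelDataset(df, tr)
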