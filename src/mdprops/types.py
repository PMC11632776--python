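"""Shared containers for all analyses.

Every downstream module consumes only these types; file parsing lives in
:mod:`mdprops.io`.  Canonical internal units are nm, ns, K, g/cm^3, GPa and
cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DIMENSIONLESS = "dimensionless"


class ParseError(ValueError):
    """Malformed tabular or coordinate input."""


class AnalysisError(ValueError):
    """An analysis precondition is violated (bad window, empty data, ...)."""


class UnsupportedError(ValueError):
    """Input is valid but outside the supported contract (e.g. triclinic box)."""


@dataclass
class TimeSeriesTable:
    """Ordered numeric records with named, unit-tagged columns.

    The first column is the independent variable (time in ns, temperature in
    K, or dimensionless strain) and must be strictly increasing.
    """

    columns: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.columns))
        if self.values.shape[1] != len(self.columns):
            raise ParseError(
                f"row arity {self.values.shape[1]} does not match "
                f"{len(self.columns)} declared columns"
            )
        for name, unit in self.columns:
            if not name or not unit:
                raise ParseError(f"column {name!r} has empty name or unit")
        x = self.values[:, 0]
        if len(x) > 1 and not np.all(np.diff(x) > 0):
            raise ParseError("independent variable must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite value in table")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.columns]

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    def column(self, name: str) -> np.ndarray:
        """Return the values of the named column."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}; have {self.names}") from None
        return self.values[:, i]

    def unit(self, name: str) -> str:
        return dict(self.columns)[name]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, units: Mapping[str, str] | Sequence[str]
    ) -> "TimeSeriesTable":
        if isinstance(units, Mapping):
            cols = [(str(c), units.get(str(c), DIMENSIONLESS)) for c in df.columns]
        else:
            cols = [(str(c), u) for c, u in zip(df.columns, units)]
        return cls(columns=cols, values=df.to_numpy(dtype=float))


@dataclass
class ConfigurationFrame:
    """One periodic configuration: atom identities, positions and box.

    Positions and box edges are in nm; only orthorhombic boxes are supported.
    ``mol_index`` groups atoms into molecules (0-based).
    """

    elements: np.ndarray
    names: np.ndarray
    mol_index: np.ndarray
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.names = np.asarray(self.names, dtype=object)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = len(self.positions)
        if not (len(self.elements) == len(self.names) == len(self.mol_index) == n):
            raise ParseError("atom attribute arrays have inconsistent lengths")
        if n and not np.all(np.isfinite(self.positions)):
            raise ParseError("non-finite atom position")
        if not np.all(self.box > 0):
            raise ParseError(f"box edges must be positive, got {self.box}")
        if np.any(self.mol_index < 0):
            raise ParseError("molecule indices must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class PropertyResult:
    """A named scalar property with units, uncertainty and provenance.

    ``provenance`` records every window, threshold and convention that
    influenced the value, so a result file is self-describing.
    """

    name: str
    value: float
    unit: str
    error: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.error is not None and self.error < 0:
            raise ValueError("error must be non-negative")

    @property
    def flags(self) -> list[str]:
        return list(self.provenance.get("flags", []))
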