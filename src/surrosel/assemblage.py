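"""Core data model: species-by-site incidence and species metadata.

The universal substrate of every stage is a boolean species x grid-cell
presence/absence matrix plus a per-species metadata table (taxonomic
order, threatened flag, endemic flag). Both are held as pandas objects
with strict validation: duplicate ids and zero-occupancy species are
rejected at construction, so downstream code can rely on every species
occupying at least one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "FormatError",
    "PresenceAbsence",
    "Assemblage",
    "occupancy",
    "validate_metadata",
]

METADATA_COLUMNS = ("order", "threatened", "endemic")


class FormatError(ValueError):
    """Raised when on-disk or in-memory data violate the format contract."""


class PresenceAbsence:
    """Boolean species x cell incidence matrix with ordered ids.

    Parameters
    ----------
    values
        2-D array-like of 0/1 or booleans, shape (n_species, n_cells).
    species
        Species identifiers (strings), one per row, in row order.
    cells
        Cell identifiers (integers), one per column, in column order.
    """

    def __init__(self, values, species, cells):
        vals = np.asarray(values)
        if vals.ndim != 2:
            raise FormatError("incidence matrix must be 2-D")
        vals = vals.astype(bool)
        species = pd.Index([str(s) for s in species], name="species_id")
        cells = pd.Index([int(c) for c in cells], name="cell")
        if vals.shape != (len(species), len(cells)):
            raise FormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(species)} species x {len(cells)} cells"
            )
        dup = species[species.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate species id: {dup[0]!r}")
        dupc = cells[cells.duplicated()]
        if len(dupc):
            raise FormatError(f"duplicate cell id: {dupc[0]}")
        empty = np.flatnonzero(~vals.any(axis=1))
        if empty.size:
            raise FormatError(
                f"species {species[empty[0]]!r} occupies no cell (zero-occupancy rows rejected)"
            )
        self._df = pd.DataFrame(vals, index=species, columns=cells)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceAbsence":
        return cls(df.to_numpy(), df.index, df.columns)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    # -- basic accessors ------------------------------------------------------

    @property
    def species(self) -> pd.Index:
        return self._df.index

    @property
    def cells(self) -> pd.Index:
        return self._df.columns

    @property
    def n_species(self) -> int:
        return self._df.shape[0]

    @property
    def n_cells(self) -> int:
        return self._df.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Boolean (n_species, n_cells) array; a view, do not mutate."""
        return self._df.to_numpy()

    def occupancy(self) -> pd.Series:
        """Number of occupied cells per species, in matrix row order."""
        return pd.Series(self._df.to_numpy().sum(axis=1), index=self.species, name="occupancy")

    def subset_species(self, ids) -> "PresenceAbsence":
        """Restrict to the given species, preserving this matrix's row order."""
        wanted = set(str(s) for s in ids)
        missing = wanted - set(self.species)
        if missing:
            raise KeyError(f"unknown species id: {sorted(missing)[0]!r}")
        keep = [s for s in self.species if s in wanted]
        if not keep:
            raise ValueError("species subset is empty")
        return PresenceAbsence.from_frame(self._df.loc[keep])

    def presence_in(self, cells) -> pd.Series:
        """Per-species count of occupied cells within a cell selection."""
        cols = [int(c) for c in cells]
        if not cols:
            return pd.Series(0, index=self.species, dtype=int)
        return self._df[cols].sum(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceAbsence):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"PresenceAbsence({self.n_species} species x {self.n_cells} cells)"


def occupancy(matrix: PresenceAbsence) -> pd.Series:
    """Occupied-cell count per species (row sums), in matrix order."""
    return matrix.occupancy()


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Coerce and validate a species-metadata table.

    Expects an index of species ids and columns ``order`` (non-empty
    string), ``threatened`` and ``endemic`` (boolean or 0/1).
    """
    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise FormatError(f"metadata missing column {col!r}")
    md = metadata[list(METADATA_COLUMNS)].copy()
    md.index = pd.Index([str(s) for s in metadata.index], name="species_id")
    dup = md.index[md.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate species id in metadata: {dup[0]!r}")
    md["order"] = md["order"].astype(str)
    if (md["order"].str.len() == 0).any():
        bad = md.index[md["order"].str.len() == 0][0]
        raise FormatError(f"empty order name for species {bad!r}")
    for col in ("threatened", "endemic"):
        vals = md[col]
        if not set(pd.unique(vals)) <= {0, 1, True, False}:
            raise FormatError(f"metadata column {col!r} must be boolean or 0/1")
        md[col] = vals.astype(bool)
    return md


@dataclass
class Assemblage:
    """A region's incidence matrix, metadata and (optionally) its grid.

    The grid is only needed while generating data (range growth uses
    adjacency); assemblages loaded from the two-CSV interchange format
    carry ``grid=None``.
    """

    region: str
    matrix: PresenceAbsence
    metadata: pd.DataFrame
    grid: Grid | None = None

    def __post_init__(self):
        self.metadata = validate_metadata(self.metadata)
        mat_ids = set(self.matrix.species)
        md_ids = set(self.metadata.index)
        only_mat = mat_ids - md_ids
        if only_mat:
            raise FormatError(f"metadata missing species {sorted(only_mat)[0]!r}")
        only_md = md_ids - mat_ids
        if only_md:
            raise FormatError(f"metadata lists unknown species {sorted(only_md)[0]!r}")
        # align metadata rows to matrix order
        self.metadata = self.metadata.loc[self.matrix.species]
        if self.grid is not None and self.grid.n_cells != self.matrix.n_cells:
            raise FormatError(
                f"grid has {self.grid.n_cells} cells but matrix has {self.matrix.n_cells}"
            )

    @property
    def n_species(self) -> int:
        return self.matrix.n_species

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def __eq__(self, other) -> bool:
        if not isinstance(other, Assemblage):
            return NotImplemented
        return (
            self.region == other.region
            and self.matrix == other.matrix
            and self.metadata.equals(other.metadata)
        )

    def __repr__(self) -> str:
        return f"Assemblage({self.region!r}, {self.n_species} species x {self.n_cells} cells)"
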