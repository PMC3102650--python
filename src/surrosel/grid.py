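"""Planning-unit lattices.

Sites ("planning units") live on a rectangular grid abstracting the
half-degree cells used in continental-scale conservation planning. Cells
are identified by 0-based integers in row-major order; spatial structure
enters only through rook (4-neighbour) adjacency, which is what the
range-growth model in :mod:`surrosel.synthetic` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

__all__ = ["Grid", "make_grid"]


@dataclass(frozen=True)
class Grid:
    """A rectangular lattice of ``n_rows * n_cols`` planning units.

    Cell ``i`` sits at row ``i // n_cols``, column ``i % n_cols``.
    """

    n_rows: int
    n_cols: int

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, cell: int) -> bool:
        return 0 <= cell < self.n_cells

    def row_col(self, cell: int) -> tuple[int, int]:
        if not self.contains(cell):
            raise ValueError(f"cell {cell} outside grid with {self.n_cells} cells")
        return divmod(cell, self.n_cols)

    def neighbors(self, cell: int) -> list[int]:
        """Rook neighbours of ``cell``, in increasing id order."""
        r, c = self.row_col(cell)
        out = []
        if r > 0:
            out.append(cell - self.n_cols)
        if c > 0:
            out.append(cell - 1)
        if c < self.n_cols - 1:
            out.append(cell + 1)
        if r < self.n_rows - 1:
            out.append(cell + self.n_cols)
        return out

    @cached_property
    def adjacency_pairs(self) -> frozenset[tuple[int, int]]:
        """All unordered rook-adjacent pairs, stored as (low id, high id)."""
        pairs = set()
        for cell in range(self.n_cells):
            for nb in self.neighbors(cell):
                pairs.add((min(cell, nb), max(cell, nb)))
        return frozenset(pairs)


def make_grid(n_rows: int, n_cols: int) -> Grid:
    """Build a validated row-major grid with rook adjacency."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    return Grid(int(n_rows), int(n_cols))
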