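"""File I/O: the two-CSV assemblage interchange format and MARXAN inputs.

An assemblage on disk is a pair of UTF-8 comma-separated files:

* ``matrix.csv`` — rows are species, columns are integer cell ids,
  values 0/1, first column ``species_id``;
* ``metadata.csv`` — columns ``species_id, order, threatened, endemic``
  with the flags coded 0/1.

For interoperability with site-selection tools the package also writes
the classic MARXAN input triplet (``pu.dat``, ``spec.dat``,
``puvspr.dat``) in its comma-separated dialect, and can read it back to
an incidence matrix for round-trip verification.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .assemblage import Assemblage, FormatError, PresenceAbsence

__all__ = [
    "write_assemblage",
    "read_assemblage",
    "write_marxan_inputs",
    "read_marxan_inputs",
]


def write_assemblage(assemblage: Assemblage, out_dir) -> tuple[Path, Path]:
    """Write ``matrix.csv`` and ``metadata.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "matrix.csv"
    metadata_path = out / "metadata.csv"
    df = assemblage.matrix.to_frame().astype(int)
    df.to_csv(matrix_path)
    md = assemblage.metadata.copy()
    md["threatened"] = md["threatened"].astype(int)
    md["endemic"] = md["endemic"].astype(int)
    md.to_csv(metadata_path)
    return matrix_path, metadata_path


def read_assemblage(matrix_path, metadata_path, region: str = "assemblage") -> Assemblage:
    """Load and validate an assemblage from the two-CSV format.

    Species order is preserved exactly as in the files; violations of
    the data contract (duplicate ids, zero-occupancy species, matrix /
    metadata id mismatch) raise :class:`FormatError` naming the
    offending id.
    """
    for p in (matrix_path, metadata_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    mat = pd.read_csv(matrix_path, index_col=0)
    try:
        cells = [int(c) for c in mat.columns]
    except ValueError as exc:
        raise FormatError(f"matrix columns must be integer cell ids: {exc}") from None
    matrix = PresenceAbsence(mat.to_numpy(), mat.index, cells)
    md = pd.read_csv(metadata_path, index_col="species_id")
    return Assemblage(region=region, matrix=matrix, metadata=md)


def write_marxan_inputs(assemblage: Assemblage, targets: pd.Series, spf: float, out_dir):
    """Write ``pu.dat``, ``spec.dat`` and ``puvspr.dat``.

    Planning units all cost 1 with status 0 (the analyses optimise site
    counts only). Species get 1-based numeric ids in matrix row order;
    ``spec.dat`` carries the representation target and species penalty
    factor, and ``puvspr.dat`` one ``amount=1`` row per presence, sorted
    by planning unit then species.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = assemblage.matrix

    pu = pd.DataFrame({"id": matrix.cells, "cost": 1, "status": 0})
    pu.to_csv(out / "pu.dat", index=False)

    sp_ids = {s: i + 1 for i, s in enumerate(matrix.species)}
    spec_rows = []
    for s in matrix.species:
        if s not in targets.index:
            raise FormatError(f"no target for species {s!r}")
        spec_rows.append((sp_ids[s], int(targets[s]), spf, s))
    spec = pd.DataFrame(spec_rows, columns=["id", "target", "spf", "name"])
    spec.to_csv(out / "spec.dat", index=False)

    vals = matrix.values
    rows = []
    for j, cell in enumerate(matrix.cells):
        for i in range(matrix.n_species):
            if vals[i, j]:
                rows.append((i + 1, int(cell), 1))
    puvspr = pd.DataFrame(rows, columns=["species", "pu", "amount"])
    puvspr = puvspr.sort_values(["pu", "species"], kind="stable")
    puvspr.to_csv(out / "puvspr.dat", index=False)
    return out / "pu.dat", out / "spec.dat", out / "puvspr.dat"


def read_marxan_inputs(in_dir) -> tuple[PresenceAbsence, pd.Series, float]:
    """Read a MARXAN triplet back into (matrix, targets, spf).

    Reconstructs the incidence matrix over all planning units listed in
    ``pu.dat`` and all species listed in ``spec.dat``, so a write/read
    round trip reproduces the original incidence content exactly.
    """
    in_dir = Path(in_dir)
    pu = pd.read_csv(in_dir / "pu.dat")
    spec = pd.read_csv(in_dir / "spec.dat")
    puvspr = pd.read_csv(in_dir / "puvspr.dat")
    cells = [int(c) for c in pu["id"]]
    names = [str(n) for n in spec["name"]]
    id_to_row = {int(i): r for r, i in enumerate(spec["id"])}
    cell_to_col = {c: j for j, c in enumerate(cells)}
    vals = np.zeros((len(names), len(cells)), dtype=bool)
    for sp, pu_id in zip(puvspr["species"], puvspr["pu"]):
        vals[id_to_row[int(sp)], cell_to_col[int(pu_id)]] = True
    matrix = PresenceAbsence(vals, names, cells)
    targets = pd.Series(spec["target"].to_numpy(), index=pd.Index(names, name="species_id"))
    spf = float(spec["spf"].iloc[0]) if len(spec) else 0.0
    return matrix, targets, spf
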