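"""Bounded 3-D lattice geometry.

The cell society lives on a rectangular box of lattice sites with hard
walls (no wraparound).  Each site holds at most one cell.  Distances are
measured in cellular space units; the default metric is Chebyshev, so a
radius-1 neighborhood is the 26-cell Moore neighborhood and a radius-r
"ball" is a cube of side 2r+1 with the origin removed.  Euclidean balls
are available for sensitivity analyses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Position = tuple[int, int, int]

NORMAL = 1
TUMOR = 2
FREE = 0

Phenotype = Literal["normal", "tumor", "any"]

_PHEN_CODE = {"normal": NORMAL, "tumor": TUMOR}


def ball_offsets(radius: int, metric: str = "chebyshev") -> list[Position]:
    """All nonzero integer offsets within ``radius`` of the origin.

    Parameters
    ----------
    radius : int
        Non-negative reach in cellular space units.
    metric : {"chebyshev", "euclidean"}
        Chebyshev (default) gives cube-shaped neighborhoods:
        ``len(ball_offsets(r)) == (2r+1)**3 - 1``.

    Returns
    -------
    list of (dx, dy, dz), lexicographically sorted, origin excluded.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if metric not in ("chebyshev", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = range(-radius, radius + 1)
    offsets = []
    for off in itertools.product(rng, rng, rng):
        if off == (0, 0, 0):
            continue
        if metric == "euclidean" and sum(c * c for c in off) > radius * radius:
            continue
        offsets.append(off)
    return offsets


def shell_offsets(distance: int, metric: str = "chebyshev") -> list[Position]:
    """Offsets at exactly ``distance`` from the origin (distance >= 1)."""
    if distance < 1:
        raise ValueError("shell distance must be >= 1")
    inner = set(ball_offsets(distance - 1, metric)) if distance > 1 else set()
    return [o for o in ball_offsets(distance, metric) if o not in inner]


def chebyshev(a: Position, b: Position) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2]))


@dataclass
class Cell:
    """A single cell occupying one lattice site."""

    id: int
    phenotype: str  # "normal" | "tumor"
    pos: Position
    prolif_prob: float = 0.0
    death_prob: float = 0.0
    generation_potential: int = 0
    age: int = 0
    generation: int = 0
    # intact life-protocol flags; a cell is tumor iff all four are lost
    protocols_intact: dict = field(
        default_factory=lambda: {
            "repair": True,
            "apoptosis": True,
            "proliferation_suppression": True,
            "distance_regulation": True,
        }
    )


class Grid:
    """Bounded 3-D lattice mapping positions to cells.

    A light container used by the per-cell reference operations, test
    fixtures and snapshot export.  The production time-stepper keeps its
    own array representation (see :mod:`rescuesim.engine`) but exports to
    this format.
    """

    def __init__(self, extents: tuple[int, int, int]):
        if len(extents) != 3 or any(e <= 0 for e in extents):
            raise ValueError(f"extents must be three positive integers, got {extents}")
        self.extents = tuple(int(e) for e in extents)
        self.cells: dict[Position, Cell] = {}

    # -- occupancy -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        x, y, z = self.extents
        return x * y * z

    def in_bounds(self, pos: Position) -> bool:
        return all(0 <= pos[i] < self.extents[i] for i in range(3))

    def is_free(self, pos: Position) -> bool:
        return self.in_bounds(pos) and pos not in self.cells

    def place(self, cell: Cell) -> None:
        if not self.in_bounds(cell.pos):
            raise ValueError(f"position {cell.pos} out of bounds {self.extents}")
        if cell.pos in self.cells:
            raise ValueError(f"site {cell.pos} already occupied")
        self.cells[cell.pos] = cell

    def remove(self, pos: Position) -> Cell:
        return self.cells.pop(pos)

    def free_neighbors(self, pos: Position, radius: int = 1) -> list[Position]:
        """In-bounds FREE sites within ``radius`` of ``pos``, sorted."""
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} out of bounds {self.extents}")
        out = []
        for dx, dy, dz in ball_offsets(radius):
            q = (pos[0] + dx, pos[1] + dy, pos[2] + dz)
            if self.is_free(q):
                out.append(q)
        return sorted(out)

    def neighbors_of_phenotype(self, pos: Position, phenotype: str, radius: int = 1) -> list[Position]:
        out = []
        for dx, dy, dz in ball_offsets(radius):
            q = (pos[0] + dx, pos[1] + dy, pos[2] + dz)
            c = self.cells.get(q)
            if c is not None and c.phenotype == phenotype:
                out.append(q)
        return sorted(out)

    def occupancy(self, phenotype: Phenotype = "any") -> float:
        """Fraction of all lattice sites holding a matching cell."""
        if phenotype == "any":
            n = len(self.cells)
        else:
            n = sum(1 for c in self.cells.values() if c.phenotype == phenotype)
        return n / self.n_sites

    def count(self, phenotype: Phenotype = "any") -> int:
        if phenotype == "any":
            return len(self.cells)
        return sum(1 for c in self.cells.values() if c.phenotype == phenotype)

    # -- array conversion ----------------------------------------------
    def phenotype_array(self) -> np.ndarray:
        arr = np.zeros(self.extents, dtype=np.int8)
        for pos, c in self.cells.items():
            arr[pos] = _PHEN_CODE[c.phenotype]
        return arr

    # -- snapshot export -----------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "x": p[0], "y": p[1], "z": p[2],
                "phenotype": c.phenotype, "cell_id": c.id,
                "age": c.age, "generation": c.generation,
            }
            for p, c in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["x", "y", "z", "phenotype", "cell_id", "age", "generation"]
        )

    def export_snapshot(self, path: str | Path, step: int = 0, meta: dict | None = None) -> None:
        """Write one row per occupied site as CSV plus a JSON sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"extents": list(self.extents), "step": step}
        if meta:
            sidecar.update(meta)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def grid_from_phenotypes(phen: np.ndarray, **cell_kwargs) -> Grid:
    """Build a Grid from an int8 phenotype array (0 free, 1 normal, 2 tumor)."""
    grid = Grid(tuple(phen.shape))
    next_id = 0
    for pos in zip(*np.nonzero(phen)):
        pos = tuple(int(v) for v in pos)
        kind = "normal" if phen[pos] == NORMAL else "tumor"
        cell = Cell(id=next_id, phenotype=kind, pos=pos, **cell_kwargs)
        if kind == "tumor":
            cell.protocols_intact = dict.fromkeys(cell.protocols_intact, False)
        grid.place(cell)
        next_id += 1
    return grid
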