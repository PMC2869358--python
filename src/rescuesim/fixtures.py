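"""Small deterministic grid states for tests and worked examples."""

from __future__ import annotations

import numpy as np

from .lattice import FREE, NORMAL, TUMOR, Grid, grid_from_phenotypes


def uniform_phenotypes(extents=(7, 7, 7), phenotype: int = NORMAL) -> np.ndarray:
    """A fully occupied membrane of one phenotype."""
    return np.full(extents, phenotype, dtype=np.int8)


def tumor_block_phenotypes(
    extents=(11, 11, 11), block_radius: int = 2
) -> np.ndarray:
    """Confluent normal tissue with a centered cubic tumor cluster.

    The tumor occupies every site within Chebyshev ``block_radius`` of the
    center, giving a two-shell structure: the outer tumor shell touches
    normal tissue, the interior (radius <= block_radius - 1) sits at
    Chebyshev distance >= 2 from every normal cell.
    """
    phen = uniform_phenotypes(extents, NORMAL)
    center = tuple(e // 2 for e in extents)
    cheb = chebyshev_field(extents, center)
    phen[cheb <= block_radius] = TUMOR
    return phen


def chebyshev_field(extents, center) -> np.ndarray:
    """Chebyshev distance of every site from ``center``."""
    axes = np.ix_(*(np.abs(np.arange(e) - c) for e, c in zip(extents, center)))
    out = axes[0]
    for a in axes[1:]:
        out = np.maximum(out, a)
    return out


def single_tumor_phenotypes(extents=(9, 9, 9)) -> np.ndarray:
    """Confluent normal tissue with one central tumor cell."""
    phen = uniform_phenotypes(extents, NORMAL)
    phen[tuple(e // 2 for e in extents)] = TUMOR
    return phen


def make_grid(phen: np.ndarray, prolif: float = 0.0, death: float = 0.0) -> Grid:
    """Grid object from a phenotype array with fixed per-cell traits."""
    return grid_from_phenotypes(
        phen, prolif_prob=prolif, death_prob=death, generation_potential=50
    )


def checkerboard_phenotypes(extents=(6, 6, 6)) -> np.ndarray:
    """Half-occupied membrane (free/normal checkerboard) for geometry tests."""
    grids = np.ogrid[tuple(slice(0, e) for e in extents)]
    parity = (grids[0] + grids[1] + grids[2]) % 2
    return np.where(parity == 0, NORMAL, FREE).astype(np.int8)
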