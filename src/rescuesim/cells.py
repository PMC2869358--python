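"""Cell phenotypes and life protocols.

Each cell carries a stochastic phenotype: a per-step proliferation
probability, a per-step intrinsic death probability, and a bounded number
of remaining divisions (generation potential, Hayflick-like).  Normal
cells obey contact inhibition — they divide only into free neighboring
sites — while tumor cells violate spatial regulation: they reach for free
sites up to radius 2 and, failing that, displace (crush) an adjacent
normal cell, which is how a growing tumor exerts pressure on confluent
tissue.

Population heterogeneity is produced by drawing each cell's probabilities
uniformly from phenotype-specific ranges and letting daughters inherit
with multiplicative random skew, clipped back into the population range.
The tumor/normal proliferation-range quotient is summarized by the ratio
labels 6, 10 and 20.

Tumorigenesis proceeds through loss of the four guarding protocols —
repair, apoptosis, proliferation-suppression and distance regulation — in
orderings where repair falls first (an intact repair protocol restores any
other freshly lost flag).  A cell whose four protocols are all lost is a
tumor cell and never reverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Cell, Grid, Position, ball_offsets

PROTOCOLS = ("repair", "apoptosis", "proliferation_suppression", "distance_regulation")

#: Normal proliferation-probability ranges per relative proliferation ratio.
NORMAL_PROLIF_BY_RATIO = {
    6: (0.05, 0.15),
    10: (0.03, 0.09),
    20: (0.015, 0.045),
}
TUMOR_PROLIF_RANGE = (0.3, 0.9)
NORMAL_DEATH_RANGE = (0.0024, 0.0048)
TUMOR_DEATH_RANGE = (0.0001, 0.0002)

#: Tumor cells are not generation-limited; sentinel "unlimited" value.
UNLIMITED = 2**30


@dataclass(frozen=True)
class PopulationRanges:
    """Uniform sampling ranges for per-cell probabilities."""

    normal_prolif: tuple[float, float]
    tumor_prolif: tuple[float, float] = TUMOR_PROLIF_RANGE
    normal_death: tuple[float, float] = NORMAL_DEATH_RANGE
    tumor_death: tuple[float, float] = TUMOR_DEATH_RANGE
    ratio_label: int | None = None

    def __post_init__(self):
        for name in ("normal_prolif", "tumor_prolif", "normal_death", "tumor_death"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi <= 1, got ({lo}, {hi})")

    @classmethod
    def from_ratio(cls, ratio: int) -> "PopulationRanges":
        """Preset ranges for the relative proliferation ratios 6, 10, 20."""
        if ratio not in NORMAL_PROLIF_BY_RATIO:
            raise ValueError(
                f"unknown proliferation ratio {ratio}; presets exist for "
                f"{sorted(NORMAL_PROLIF_BY_RATIO)} (custom ratios require explicit ranges)"
            )
        return cls(normal_prolif=NORMAL_PROLIF_BY_RATIO[ratio], ratio_label=ratio)

    def prolif(self, phenotype: str) -> tuple[float, float]:
        return self.tumor_prolif if phenotype == "tumor" else self.normal_prolif

    def death(self, phenotype: str) -> tuple[float, float]:
        return self.tumor_death if phenotype == "tumor" else self.normal_death


@dataclass
class CellParams:
    prolif_prob: float
    death_prob: float
    generation_potential: int
    protocols_intact: dict = field(default_factory=lambda: dict.fromkeys(PROTOCOLS, True))

    @property
    def is_tumor(self) -> bool:
        return not any(self.protocols_intact.values())


def sample_population_params(
    ranges: PopulationRanges,
    phenotype: str,
    rng: np.random.Generator,
    generation_potential: int = 50,
) -> CellParams:
    """Draw a fresh phenotype uniformly from the population ranges.

    Normal cells receive a finite generation potential (default 50
    divisions); tumor cells are unlimited.
    """
    plo, phi = ranges.prolif(phenotype)
    dlo, dhi = ranges.death(phenotype)
    params = CellParams(
        prolif_prob=float(rng.uniform(plo, phi)),
        death_prob=float(rng.uniform(dlo, dhi)),
        generation_potential=UNLIMITED if phenotype == "tumor" else generation_potential,
    )
    if phenotype == "tumor":
        params.protocols_intact = dict.fromkeys(PROTOCOLS, False)
    return params


def inherit_params(
    parent: CellParams,
    ranges: PopulationRanges,
    skew_frac: float,
    rng: np.random.Generator,
    decrement_generation: bool = True,
) -> CellParams:
    """Daughter phenotype: parent values with symmetric multiplicative skew.

    Each probability is multiplied by U(1 - skew, 1 + skew) and clipped into
    the population range for the cell's phenotype.
    """
    if skew_frac < 0:
        raise ValueError("skew_frac must be >= 0")
    phenotype = "tumor" if parent.is_tumor else "normal"
    plo, phi = ranges.prolif(phenotype)
    dlo, dhi = ranges.death(phenotype)
    p = parent.prolif_prob * rng.uniform(1 - skew_frac, 1 + skew_frac)
    d = parent.death_prob * rng.uniform(1 - skew_frac, 1 + skew_frac)
    gp = parent.generation_potential
    if decrement_generation and gp != UNLIMITED:
        gp = max(gp - 1, 0)
    return CellParams(
        prolif_prob=float(np.clip(p, plo, phi)),
        death_prob=float(np.clip(d, dlo, dhi)),
        generation_potential=gp,
        protocols_intact=dict(parent.protocols_intact),
    )


def mutate_step(
    params: CellParams,
    mutation_prob_per_protocol: float,
    ranges: PopulationRanges,
    rng: np.random.Generator,
) -> CellParams:
    """One mutation check-point at replication.

    Each intact guarding protocol is lost independently with the given
    probability.  While the repair protocol survives, any other freshly
    lost flag is restored — repair must fall first, enforcing the mutation
    ordering through which tumors arise.  When all four flags are lost the
    phenotype is tumor and the probabilities are resampled from the tumor
    ranges.  Tumor cells never run this protocol (no back-mutation).
    """
    if params.is_tumor:
        raise ValueError("mutate_step applies to normal cells only; tumors cannot back-mutate")
    if mutation_prob_per_protocol == 0:
        return params
    flags = dict(params.protocols_intact)
    lost_now = [p for p in PROTOCOLS if flags[p] and rng.random() < mutation_prob_per_protocol]
    for p in lost_now:
        flags[p] = False
    if flags["repair"]:
        for p in lost_now:  # repair intact: restore everything else that just broke
            flags[p] = True
        flags["repair"] = True
    out = replace(params, protocols_intact=flags)
    if out.is_tumor:
        tumor = sample_population_params(ranges, "tumor", rng)
        tumor.protocols_intact = flags
        return tumor
    return out


# ---------------------------------------------------------------------------
# Per-cell reference operations on Grid objects.  The production engine
# vectorizes the same semantics; these are the readable single-cell forms
# used by tests and small constructed scenarios.
# ---------------------------------------------------------------------------

def division_target(
    grid: Grid,
    cell: Cell,
    rng: np.random.Generator,
    allow_displacement: bool = True,
) -> tuple[Position, str] | None:
    """Admissible daughter site for a division, or None.

    Normal cells: a uniformly random FREE radius-1 neighbor, else nothing.
    Tumor cells: FREE radius-1, else FREE radius-2, else (pressure) a
    radius-1 site occupied by a normal cell, whose occupant is crushed.
    Returns (position, mode) with mode in {"free", "displace"}.
    """
    free1 = grid.free_neighbors(cell.pos, radius=1)
    if free1:
        return free1[int(rng.integers(len(free1)))], "free"
    if cell.phenotype == "normal":
        return None
    free2 = grid.free_neighbors(cell.pos, radius=2)
    if free2:
        return free2[int(rng.integers(len(free2)))], "free"
    if allow_displacement:
        victims = grid.neighbors_of_phenotype(cell.pos, "normal", radius=1)
        if victims:
            return victims[int(rng.integers(len(victims)))], "displace"
    return None


def attempt_division(
    grid: Grid,
    cell: Cell,
    ranges: PopulationRanges,
    rng: np.random.Generator,
    skew_frac: float = 0.1,
    prolif_modifier: float = 1.0,
    next_id: int = -1,
    allow_displacement: bool = True,
) -> Cell | None:
    """One division attempt; mutates the grid in place on success.

    ``prolif_modifier`` folds in contact-pressure suppression and
    repopulation acceleration.  Returns the daughter cell or None.
    """
    if cell.generation_potential <= 0:
        return None
    p = min(cell.prolif_prob * prolif_modifier, 1.0)
    if rng.random() >= p:
        return None
    target = division_target(grid, cell, rng, allow_displacement=allow_displacement)
    if target is None:
        return None
    pos, mode = target
    if mode == "displace":
        grid.remove(pos)
    parent_params = CellParams(
        prolif_prob=cell.prolif_prob,
        death_prob=cell.death_prob,
        generation_potential=cell.generation_potential,
        protocols_intact=dict(cell.protocols_intact),
    )
    daughter_params = inherit_params(parent_params, ranges, skew_frac, rng)
    cell.generation_potential = daughter_params.generation_potential
    cell.generation += 1
    daughter = Cell(
        id=next_id,
        phenotype=cell.phenotype,
        pos=pos,
        prolif_prob=daughter_params.prolif_prob,
        death_prob=daughter_params.death_prob,
        generation_potential=daughter_params.generation_potential,
        generation=cell.generation,
        protocols_intact=dict(cell.protocols_intact),
    )
    grid.place(daughter)
    return daughter


def intrinsic_death(
    cell: Cell, rng: np.random.Generator, senescence_age: int = 200
) -> bool:
    """Random intrinsic death, plus deterministic senescent death.

    True marks the cell as dying this step (its death report, if any, is
    emitted downstream).  A cell with exhausted generation potential dies
    deterministically once its age exceeds the senescence horizon.
    """
    if cell.generation_potential <= 0 and cell.age > senescence_age:
        return True
    return bool(rng.random() < cell.death_prob)


def plant_tumor(
    grid: Grid,
    ranges: PopulationRanges,
    rng: np.random.Generator,
    site: Position | None = None,
    next_id: int = -1,
) -> Cell:
    """Replace one occupied site's cell with a freshly sampled tumor cell.

    Default site is the grid center (nearest occupied site if the center is
    free); the membrane stays full at planting time.
    """
    if not grid.cells:
        raise RuntimeError("cannot plant a tumor into an empty grid")
    if site is None:
        center = tuple(e // 2 for e in grid.extents)
        site = center if center in grid.cells else min(
            grid.cells, key=lambda p: max(abs(p[i] - center[i]) for i in range(3))
        )
    if site not in grid.cells:
        raise ValueError(f"plant site {site} is not occupied")
    grid.remove(site)
    params = sample_population_params(ranges, "tumor", rng)
    tumor = Cell(
        id=next_id,
        phenotype="tumor",
        pos=site,
        prolif_prob=params.prolif_prob,
        death_prob=params.death_prob,
        generation_potential=params.generation_potential,
        protocols_intact=dict.fromkeys(PROTOCOLS, False),
    )
    grid.place(tumor)
    return tumor
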