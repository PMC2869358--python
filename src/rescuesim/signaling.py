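"""The two inter-cellular rescue protocols.

"Please die": normal cells whose space is violated by an adjacent tumor
cluster (or that were primed by nearby alarm signals) broadcast an
apoptosis request over a short radius.

"I'm dying": every dying cell — whatever killed it — reports its death
over a phenotype-specific radius.  The report is the basic citizenship
commitment: at the high threshold it carries apoptosis deeper into a
tumor cluster (a dying shell of tumor cells triggers the shell behind
it), at the low threshold it accelerates normal cells' replication so the
evacuated space is repopulated.

Signals decay with distance: a receiver at distance d from an emitter of
strength s and radius r observes s * (1 - d / (r + 1)) (linear law,
default) and nothing beyond r.  Receivers integrate signal over time with
a leaky accumulator (retention rho per step) and compare the total
against their phenotype's thresholds.

Tumor resistance comes in two forms: stochastic — each received deposit
is ignored with probability q, and each dying tumor cell fails to emit
its report with probability f — and deterministic, a minimum count of
distinct (at-least-half-strength) requests before a cell complies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import Cell, Grid, Position, ball_offsets, chebyshev

SIGNAL_CLASSES = ("tumor_im_dying", "normal_im_dying", "normal_please_die")


@dataclass(frozen=True)
class SignalSpec:
    """Radius (cellular space units) and emitted strength (signal units)."""

    radius: int
    strength: float

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("signal radius must be >= 0")
        if self.strength <= 0:
            raise ValueError("signal strength must be > 0")


@dataclass(frozen=True)
class SignalConfig:
    tumor_im_dying: SignalSpec
    normal_im_dying: SignalSpec
    normal_please_die: SignalSpec
    decay: str = "linear"  # or "exponential"
    metric: str = "chebyshev"

    @classmethod
    def from_table1(cls, label: int, **kwargs) -> "SignalConfig":
        if label not in TABLE1_SETS:
            raise ValueError(f"Table 1 set label must be in 1..5, got {label}")
        t, n, p = TABLE1_SETS[label]
        return cls(
            tumor_im_dying=SignalSpec(*t),
            normal_im_dying=SignalSpec(*n),
            normal_please_die=SignalSpec(*p),
            **kwargs,
        )

    def spec(self, signal_class: str) -> SignalSpec:
        return getattr(self, signal_class)


#: The five published rescue-signal parameter sets, label -> (radius,
#: strength) for tumor "I'm dying", normal "I'm dying", normal "please die".
TABLE1_SETS: dict[int, tuple[tuple[int, float], ...]] = {
    1: ((1, 1.0), (1, 1.0), (1, 1.0)),
    2: ((1, 2.0), (1, 2.0), (1, 1.0)),
    3: ((1, 2.0), (1, 2.0), (1, 2.0)),
    4: ((1, 3.0), (1, 3.0), (1, 3.0)),
    5: ((2, 3.0), (1, 2.0), (1, 2.0)),
}


@dataclass(frozen=True)
class Thresholds:
    """Signal-unit response thresholds plus deterministic request counts.

    ``high_*`` are apoptosis thresholds on the accumulated apoptotic
    signal.  ``low_normal_please_die`` primes early "please die" emission
    (compared against the please-die signal received in the current step);
    ``low_normal_repop`` triggers replication acceleration (compared
    against the accumulated death-report signal).  The request-count pair
    (tumor/normal) is the deterministic-resistance legend: a cell complies
    only after that many distinct at-least-half-strength requests.
    """

    high_tumor: float = 1.0
    high_normal: float = 16.0
    low_normal_please_die: float = 2.0
    low_normal_repop: float = 1.0
    count_tumor: int = 1
    count_normal: int = 1
    acceleration_factor: float = 2.0
    acceleration_steps: int = 5

    def __post_init__(self):
        if not (0 < self.low_normal_please_die < self.high_normal):
            raise ValueError("low_normal_please_die must lie in (0, high_normal)")
        if not (0 < self.low_normal_repop < self.high_normal):
            raise ValueError("low_normal_repop must lie in (0, high_normal)")
        if self.high_tumor <= 0:
            raise ValueError("high_tumor must be > 0")
        if self.count_tumor < 1 or self.count_normal < 1:
            raise ValueError("request counts must be >= 1")


@dataclass(frozen=True)
class ResistanceParams:
    """Stochastic tumor resistance to the rescue protocols."""

    ignore_prob: float = 0.0  # q: per received deposit
    fail_emit_prob: float = 0.0  # f: per dying tumor cell

    def __post_init__(self):
        for name in ("ignore_prob", "fail_emit_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


# ---------------------------------------------------------------------------
# Decay law
# ---------------------------------------------------------------------------

def received_strength(s: float, r: int, d: int, decay: str = "linear") -> float:
    """Signal observed at distance ``d`` from an emitter of strength ``s``.

    Zero beyond the radius; full strength at d = 0; strictly decreasing
    in d on [0, r] for the linear law s * (1 - d/(r+1)).  The exponential
    alternative halves per unit distance, truncated at r.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d > r:
        return 0.0
    if decay == "linear":
        return s * (1.0 - d / (r + 1.0))
    if decay == "exponential":
        return s * 0.5**d
    raise ValueError(f"unknown decay law {decay!r}")


def decay_profile(spec: SignalSpec, decay: str = "linear") -> np.ndarray:
    """Deposit value per Chebyshev distance 1..radius (emitter excluded)."""
    return np.array(
        [received_strength(spec.strength, spec.radius, d, decay) for d in range(1, spec.radius + 1)]
    )


def build_kernel(spec: SignalSpec, decay: str = "linear", metric: str = "chebyshev") -> np.ndarray:
    """(2r+1)^3 deposit kernel with zero center, for field convolution."""
    r = spec.radius
    k = np.zeros((2 * r + 1,) * 3)
    for off in ball_offsets(r, metric):
        d = max(abs(c) for c in off) if metric == "chebyshev" else int(
            np.ceil(np.sqrt(sum(c * c for c in off)))
        )
        k[off[0] + r, off[1] + r, off[2] + r] = received_strength(spec.strength, r, d, decay)
    return k


# ---------------------------------------------------------------------------
# Per-cell reference operations (deposit maps on Grid objects)
# ---------------------------------------------------------------------------

def detect_spatial_violation(grid: Grid, cell: Cell, violation_radius: int = 1) -> bool:
    """True iff a tumor cell sits within the violation radius of a normal cell."""
    if cell.phenotype != "normal":
        raise ValueError("only normal cells sense spatial violation (and emit 'please die')")
    return bool(grid.neighbors_of_phenotype(cell.pos, "tumor", radius=violation_radius))


def _deposit_map(grid: Grid, origin: Position, spec: SignalSpec, decay: str) -> dict[Position, float]:
    deposits: dict[Position, float] = {}
    for off in ball_offsets(spec.radius):
        q = (origin[0] + off[0], origin[1] + off[1], origin[2] + off[2])
        if grid.in_bounds(q) and q in grid.cells:
            v = received_strength(spec.strength, spec.radius, chebyshev(origin, q), decay)
            if v > 0:
                deposits[q] = v
    return deposits


def emit_please_die(grid: Grid, cell: Cell, cfg: SignalConfig) -> dict[Position, float]:
    """Deposit the please-die signal on every occupied site within radius."""
    if cell.phenotype != "normal":
        raise ValueError("only normal cells emit 'please die'")
    return _deposit_map(grid, cell.pos, cfg.normal_please_die, cfg.decay)


def emit_im_dying(
    grid: Grid,
    cell: Cell,
    cfg: SignalConfig,
    resistance: ResistanceParams,
    rng: np.random.Generator,
) -> dict[Position, float]:
    """Death report from a dying cell (any death path).

    A dying tumor cell fails to emit with probability f; normal cells
    always report.
    """
    if cell.phenotype == "tumor" and rng.random() < resistance.fail_emit_prob:
        return {}
    spec = cfg.tumor_im_dying if cell.phenotype == "tumor" else cfg.normal_im_dying
    return _deposit_map(grid, cell.pos, spec, cfg.decay)


# ---------------------------------------------------------------------------
# Accumulation and response
# ---------------------------------------------------------------------------

@dataclass
class Accumulator:
    """Leaky per-cell signal integrator (consumed with the cell on death)."""

    apoptotic: float = 0.0
    repop: float = 0.0
    requests: float = 0.0

    def is_nonnegative(self) -> bool:
        return self.apoptotic >= 0 and self.repop >= 0 and self.requests >= 0


def apply_deposits(acc: float, deposits, rho: float) -> float:
    """One accumulation step: rho * old + sum of this step's deposits."""
    if not (0.0 <= rho <= 1.0):
        raise ValueError("retention rho must be in [0, 1]")
    return rho * acc + float(sum(deposits))


def respond(
    cell: Cell,
    acc: Accumulator,
    thresholds: Thresholds,
    alarm_please_die: float = 0.0,
) -> str:
    """Highest-priority action for a cell given its accumulated signal.

    Tumor: apoptose when the apoptotic accumulator reaches the tumor high
    threshold and at least ``count_tumor`` qualifying requests arrived
    (stochastic ignoring is applied earlier, at deposit time).  Normal:
    apoptose at the normal high threshold with ``count_normal`` requests;
    otherwise accelerate replication at the repopulation threshold;
    otherwise become primed to emit "please die" early when this step's
    please-die receipts reach the priming threshold.
    Returns one of {"none", "apoptose", "accelerate", "emit_early"}.
    """
    if cell.phenotype == "tumor":
        if acc.apoptotic >= thresholds.high_tumor and acc.requests >= thresholds.count_tumor:
            return "apoptose"
        return "none"
    if acc.apoptotic >= thresholds.high_normal and acc.requests >= thresholds.count_normal:
        return "apoptose"
    if acc.repop >= thresholds.low_normal_repop:
        return "accelerate"
    if alarm_please_die >= thresholds.low_normal_please_die:
        return "emit_early"
    return "none"


def qualifying_request(value: float, strength: float) -> bool:
    """A deposit counts as a distinct apoptotic request at >= half strength."""
    return value >= 0.5 * strength
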