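"""Replicated sweep experiments and success-rate aggregation.

Every condition is run as n independent replicates whose seeds derive
deterministically from a master seed and a stable hash of the condition
itself, so results are reproducible and independent of the order in which
conditions are executed.  Success rates carry Wilson score intervals.

The three preset sweeps mirror the robustness analyses of the combined
rescue protocol: the full protocol-parameter grid (proliferation ratios
x the five published signal parameter sets), the stochastic-resistance
curves (success vs per-signal ignore probability q and vs per-death
emission-failure probability f), and the delayed-activation curve
(success vs tumor volume at protocol activation).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import Config, make_config
from .engine import run

log = logging.getLogger(__name__)

#: Published experiment scale: runs per ratio graph / per resistance figure.
PAPER_SCALE_GRID = 570
PAPER_SCALE_RESISTANCE = 665


def condition_seed(master_seed: int, condition: str, replicate: int) -> np.random.SeedSequence:
    """Seed stream for one replicate, stable under condition reordering."""
    digest = hashlib.blake2b(condition.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "little") % (2**31)
    return np.random.SeedSequence([master_seed % (2**31), key, replicate])


def run_replicates(
    config: Config,
    n: int,
    master_seed: int,
    condition: str = "base",
) -> tuple[int, int]:
    """Run ``n`` independently seeded replicates; returns (successes, runs)."""
    if n < 1:
        raise ValueError("need at least one replicate")
    successes = 0
    for i in range(n):
        rng = np.random.default_rng(condition_seed(master_seed, condition, i))
        if run(config, rng).success:
            successes += 1
    return successes, n


def summarize(records: list[dict]) -> pd.DataFrame:
    """Tidy success-rate table with 95% Wilson score intervals."""
    if not records:
        raise ValueError("no conditions to summarize")
    df = pd.DataFrame(records)
    if (df["n_runs"] < 1).any():
        raise ValueError("every condition needs n_runs >= 1")
    df["success_rate"] = df["n_success"] / df["n_runs"]
    lo, hi = proportion_confint(df["n_success"], df["n_runs"], alpha=0.05, method="wilson")
    df["ci_low"] = lo
    df["ci_high"] = hi
    return df


@dataclass
class ExperimentSpec:
    """Axes and scale of a sweep experiment."""

    base: Config = field(default_factory=make_config)
    ratios: tuple[int, ...] = (6, 10, 20)
    table1_sets: tuple[int, ...] = (1, 2, 3, 4, 5)
    threshold_pairs: tuple[tuple[int, int], ...] = ((1, 1),)
    q_grid: tuple[float, ...] = ()
    f_grid: tuple[float, ...] = ()
    volume_grid: tuple[float, ...] = ()
    replicates: int = 30
    master_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def sweep_protocol_grid(spec: ExperimentSpec) -> pd.DataFrame:
    """Full factorial: proliferation ratio x signal set x threshold pair."""
    records = []
    for ratio in spec.ratios:
        for set_label in spec.table1_sets:
            for ct, cn in spec.threshold_pairs:
                cfg = spec.base.with_overrides(**{
                    "population.ratio": ratio,
                    "signals.table1_set": set_label,
                    "thresholds.count_tumor": ct,
                    "thresholds.count_normal": cn,
                })
                cond = f"grid:r{ratio}:s{set_label}:t{ct}/{cn}"
                s, n = run_replicates(cfg, spec.replicates, spec.master_seed, cond)
                log.info("%s -> %d/%d", cond, s, n)
                records.append(
                    {"ratio": ratio, "table1_set": set_label,
                     "count_tumor": ct, "count_normal": cn,
                     "n_success": s, "n_runs": n}
                )
    return summarize(records).sort_values(
        ["ratio", "table1_set", "count_tumor"], ignore_index=True
    )


def sweep_resistance(spec: ExperimentSpec) -> pd.DataFrame:
    """Success vs stochastic resistance: q with f=0, then f with q=0."""
    if not spec.q_grid and not spec.f_grid:
        raise ValueError("resistance sweep needs a nonempty q grid and/or f grid")
    records = []
    for axis, grid in (("ignore_prob", spec.q_grid), ("fail_emit_prob", spec.f_grid)):
        for v in grid:
            cfg = spec.base.with_overrides(**{f"resistance.{axis}": float(v)})
            cond = f"resist:{axis}={v:.4f}"
            s, n = run_replicates(cfg, spec.replicates, spec.master_seed, cond)
            log.info("%s -> %d/%d", cond, s, n)
            records.append({"axis": axis, "value": float(v), "n_success": s, "n_runs": n})
    return summarize(records).sort_values(["axis", "value"], ignore_index=True)


def sweep_activation_volume(spec: ExperimentSpec) -> pd.DataFrame:
    """Success vs tumor occupancy at delayed rescue activation."""
    if not spec.volume_grid or not all(0 < v < 1 for v in spec.volume_grid):
        raise ValueError("volume grid must lie strictly inside (0, 1)")
    records = []
    for v in spec.volume_grid:
        cfg = spec.base.with_overrides(**{"engine.activation_volume": float(v)})
        cond = f"volume:{v:.4f}"
        s, n = run_replicates(cfg, spec.replicates, spec.master_seed, cond)
        log.info("%s -> %d/%d", cond, s, n)
        records.append({"activation_volume": float(v), "n_success": s, "n_runs": n})
    return summarize(records).sort_values("activation_volume", ignore_index=True)


def critical_resistance(table: pd.DataFrame, axis: str, min_rate: float = 0.95) -> float | None:
    """Largest swept resistance level whose success rate is still >= min_rate."""
    sub = table[(table["axis"] == axis) & (table["success_rate"] >= min_rate)]
    return None if sub.empty else float(sub["value"].max())


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_spec(name: str, replicates: int | None = None, master_seed: int = 0) -> ExperimentSpec:
    """Named sweep presets.

    ``fig3``: ratio x signal-set grid at baseline thresholds (immediate
    scale: 38 replicates x 15 conditions per the published 570-run graphs
    when ``replicates`` is not given).
    ``fig4``: resistance curves with rescue active from planting, on an
    even q/f grid.
    ``fig3d``: activation-volume sweep 0.1..0.9.
    """
    if name == "fig3":
        return ExperimentSpec(
            replicates=replicates or PAPER_SCALE_GRID // 15,
            master_seed=master_seed,
        )
    if name == "fig4":
        grid = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 3))
        return ExperimentSpec(
            base=make_config(**{"engine.activation_delay": 0}),
            q_grid=grid,
            f_grid=grid,
            replicates=replicates or max(PAPER_SCALE_RESISTANCE // (2 * len(grid)), 1),
            master_seed=master_seed,
        )
    if name == "fig3d":
        return ExperimentSpec(
            volume_grid=tuple(np.round(np.arange(0.1, 0.9001, 0.1), 3)),
            replicates=replicates or 30,
            master_seed=master_seed,
        )
    raise ValueError(f"unknown preset {name!r}; expected fig3, fig4 or fig3d")


def run_preset(name: str, replicates: int | None = None, master_seed: int = 0) -> pd.DataFrame:
    spec = preset_spec(name, replicates, master_seed)
    if name == "fig3":
        return sweep_protocol_grid(spec)
    if name == "fig4":
        return sweep_resistance(spec)
    return sweep_activation_volume(spec)
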