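"""Engine dynamics: growth, homeostasis, determinism, tumor battles."""

import numpy as np
import pandas as pd
import pytest

from conftest import quick_config
from rescuesim.config import make_config
from rescuesim.engine import (
    SimulationState,
    classify_outcome,
    grow_to_confluence,
    run,
)
from rescuesim.fixtures import tumor_block_phenotypes
from rescuesim.lattice import NORMAL, TUMOR


class TestGrowth:
    def test_small_membrane_fills_completely_without_deaths(self):
        cfg = quick_config(**{
            "grid.extents": (5, 5, 5),
            "population.ratio": None,
            "population.normal_prolif": (0.1, 0.1),
            "population.normal_death": (0.0, 0.0),
            "engine.confluence_frac": 1.0,
        })
        state = grow_to_confluence(cfg, 0)
        assert state.count("any") == 125
        assert state.count("tumor") == 0
        assert not state.growth_degenerate

    def test_zero_proliferation_hits_the_step_cap(self):
        cfg = quick_config(**{
            "grid.extents": (5, 5, 5),
            "population.ratio": None,
            "population.normal_prolif": (0.0, 0.0),
            "population.normal_death": (0.0, 0.0),
            "engine.growth_step_cap": 50,
        })
        state = grow_to_confluence(cfg, 0)
        assert state.growth_degenerate
        assert state.count("any") == 1

    def test_occupancy_nondecreasing_during_growth(self):
        # deaths are two orders below proliferation, so near-monotone growth
        transitions = ok = 0
        for seed in range(20):
            cfg = quick_config(**{"grid.extents": (8, 8, 8)})
            state = SimulationState(cfg, seed)
            state.seed_cell()
            prev = state.count()
            while state.occupancy() < 0.99 and state.clock < 800:
                state.step()
                cur = state.count()
                transitions += 1
                ok += cur >= prev
                prev = cur
        assert ok / transitions >= 0.95


def test_bitwise_deterministic_replay(small_config):
    r1 = run(small_config, 99, keep_trace=True)
    r2 = run(small_config, 99, keep_trace=True)
    assert r1.outcome == r2.outcome
    assert r1.trace.equals(r2.trace)
    s1 = grow_to_confluence(small_config, 5)
    s2 = grow_to_confluence(small_config, 5)
    for a, b in ((s1.phen, s2.phen), (s1.prolif, s2.prolif), (s1.cellid, s2.cellid)):
        np.testing.assert_array_equal(a, b)


def test_homeostasis_of_confluent_normal_tissue(small_config):
    """An all-normal confluent membrane holds its count for 200 steps."""
    state = grow_to_confluence(small_config, 3)
    baseline = state.count("normal")
    counts = []
    for _ in range(200):
        state.step()
        counts.append(state.count("normal"))
    counts = np.array(counts)
    assert counts.min() >= 0.95 * baseline
    assert counts.max() <= state.phen.size
    assert state.count("tumor") == 0


def test_unchecked_tumor_takeover_without_rescue():
    cfg = quick_config(**{
        "signals.enable_please_die": False,
        "signals.enable_im_dying": False,
    })
    r = run(cfg, 2, keep_trace=True)
    tum = r.trace["n_tumor"].to_numpy()
    post = tum[tum > 0]
    assert r.outcome in ("collapse", "timeout")
    assert r.final_tumor_frac > 0.5  # tumor overran the membrane
    assert post[-1] > post[0]


def test_phenotype_monotonicity_over_trajectory():
    """No cell id observed as tumor is ever later observed as normal."""
    cfg = quick_config()
    state = grow_to_confluence(cfg, 11)
    state.plant_tumor()
    tumor_ids: set[int] = set()
    for t in range(60):
        if t >= cfg.engine.activation_delay:
            state.rescue_active = True
        state.step()
        ids = state.cellid[state.phen > 0]
        phen = state.phen[state.phen > 0]
        normal_ids = set(ids[phen == NORMAL].tolist())
        assert not (tumor_ids & normal_ids)
        tumor_ids |= set(ids[phen == TUMOR].tolist())


def test_success_means_tumor_hits_zero_and_stays(small_config):
    r = run(small_config, 4, keep_trace=True)
    assert r.outcome == "success"
    tum = r.trace["n_tumor"].to_numpy()
    first_zero_after_plant = np.nonzero(tum > 0)[0].max() + 1
    assert (tum[first_zero_after_plant:] == 0).all()
    assert tum[-1] == 0


class TestClassification:
    def test_constructed_terminal_states(self):
        assert classify_outcome(0, 900, 1000, 0.5, timed_out=False) == "success"
        assert classify_outcome(0, 400, 1000, 0.5, timed_out=True) == "collapse"
        assert classify_outcome(50, 900, 1000, 0.5, timed_out=True) == "timeout"
        assert classify_outcome(0, 0, 1000, 0.5, timed_out=True) == "collapse"

    def test_integrity_boundary_is_inclusive(self):
        assert classify_outcome(0, 500, 1000, 0.5, timed_out=True) == "success"


class TestPeripheryOnlyPleaseDie:
    """With death reports disabled, "please die" reaches only the tumor rim."""

    def make_state(self, block_radius=2):
        cfg = make_config(**{
            "signals.enable_im_dying": False,
            "population.ratio": None,
            "population.normal_prolif": (0.0, 0.0),
            "population.normal_death": (0.0, 0.0),
            "population.tumor_prolif": (0.0, 0.0),
            "population.tumor_death": (0.0, 0.0),
        })
        phen = tumor_block_phenotypes((11, 11, 11), block_radius)
        state = SimulationState.from_phenotype_array(phen, cfg, 0)
        state.rescue_active = True
        return state

    @staticmethod
    def cheb_from_center(state):
        from rescuesim.fixtures import chebyshev_field

        return chebyshev_field(state.extents, tuple(e // 2 for e in state.extents))

    def test_interior_tumor_accumulates_exactly_zero(self):
        state = self.make_state()
        state.step()
        cheb = self.cheb_from_center(state)
        interior = (cheb <= 1) & (state.phen == TUMOR)
        rim = (cheb == 2) & (state.phen == TUMOR)
        assert interior.any()
        # interior cells sit beyond please-die reach of every normal cell
        assert np.all(state.acc_ap[interior] == 0.0)

    def test_frozen_tissue_peels_only_the_rim(self):
        # without repopulation the gap exceeds the please-die radius and
        # the peel stalls: periphery-only, exactly as with no death reports
        state = self.make_state()
        cheb = self.cheb_from_center(state)
        for _ in range(10):
            state.step()
        assert (state.phen[cheb == 2] == TUMOR).sum() == 0  # rim died
        assert (state.phen[cheb <= 1] == TUMOR).all()  # interior untouchable

    def test_repopulating_tissue_peels_shell_by_shell(self):
        # normals refilling the vacated shell renew the violation, so the
        # tumor is eaten rim-first, the center cell dying last
        cfg = make_config(**{
            "signals.enable_im_dying": False,
            "population.ratio": None,
            "population.normal_prolif": (1.0, 1.0),
            "population.normal_death": (0.0, 0.0),
            "population.tumor_prolif": (0.0, 0.0),
            "population.tumor_death": (0.0, 0.0),
        })
        phen = tumor_block_phenotypes((11, 11, 11), 2)
        state = SimulationState.from_phenotype_array(phen, cfg, 0)
        state.rescue_active = True
        cheb = self.cheb_from_center(state)
        death_step = {}
        for t in range(1, 30):
            state.step()
            for shell in (2, 1, 0):
                if shell not in death_step and (state.phen[cheb == shell] == TUMOR).sum() == 0:
                    death_step[shell] = t
            if state.count("tumor") == 0:
                break
        assert state.count("tumor") == 0
        assert death_step[2] < death_step[1] <= death_step[0]


def test_total_resistance_degenerates_to_signal_inert_tumor():
    """q=1, f=1: no tumor cell ever dies from signaling."""
    cfg = quick_config(**{
        "resistance.ignore_prob": 1.0,
        "resistance.fail_emit_prob": 1.0,
        "engine.max_steps": 80,
    })
    r = run(cfg, 8, keep_trace=True)
    assert (r.trace["deaths_apoptosis_tumor"] == 0).all()
    assert r.outcome in ("timeout", "collapse")


def test_fig1c_style_regression_default_config():
    """Ratio-6 defaults remove a 10-step-old tumor in most seeded runs."""
    outcomes = [run(make_config(), seed) for seed in range(20)]
    n_success = sum(r.success for r in outcomes)
    assert n_success >= 14  # >= 70% of seeds
    for r in outcomes:
        if r.success:
            assert r.final_tumor_frac == 0.0
            # healthy tissue kept above half its pre-tumor baseline
            assert r.final_normal_frac * np.prod((20, 20, 20)) >= 0.5 * r.baseline_normal
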