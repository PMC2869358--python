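"""Rescue-protocol signaling: decay, emission, accumulation, response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuesim.fixtures import make_grid, single_tumor_phenotypes, uniform_phenotypes
from rescuesim.lattice import Cell, chebyshev
from rescuesim.signaling import (
    TABLE1_SETS,
    Accumulator,
    ResistanceParams,
    SignalConfig,
    SignalSpec,
    Thresholds,
    apply_deposits,
    build_kernel,
    detect_spatial_violation,
    emit_im_dying,
    emit_please_die,
    qualifying_request,
    received_strength,
    respond,
)


class TestReceivedStrength:
    def test_zero_distance_gives_full_strength(self):
        assert received_strength(2.0, 1, 0) == pytest.approx(2.0)

    @pytest.mark.parametrize("s,r", [(1.0, 0), (2.0, 1), (3.0, 2), (5.0, 4)])
    def test_zero_just_beyond_radius(self, s, r):
        assert received_strength(s, r, r + 1) == 0.0
        assert received_strength(s, r, r + 5) == 0.0

    def test_linear_decay_table(self):
        # brute-force table for s=3, r=2 over d = 0..3
        expected = {0: 3.0, 1: 2.0, 2: 1.0, 3: 0.0}
        for d, v in expected.items():
            assert received_strength(3.0, 2, d) == pytest.approx(v)

    @given(st.floats(0.1, 10), st.integers(0, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_in_distance(self, s, r):
        vals = [received_strength(s, r, d) for d in range(r + 3)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(s)

    def test_exponential_law_halves_per_step(self):
        assert received_strength(4.0, 3, 2, decay="exponential") == pytest.approx(1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            received_strength(1.0, 1, -1)
        with pytest.raises(ValueError):
            received_strength(1.0, 1, 0, decay="cubic")


class TestTable1:
    def test_published_parameter_sets(self):
        assert TABLE1_SETS[5] == ((2, 3.0), (1, 2.0), (1, 2.0))
        assert TABLE1_SETS[2] == ((1, 2.0), (1, 2.0), (1, 1.0))
        assert TABLE1_SETS[1] == ((1, 1.0), (1, 1.0), (1, 1.0))

    def test_preset_lookup(self):
        cfg = SignalConfig.from_table1(5)
        assert cfg.tumor_im_dying == SignalSpec(2, 3.0)
        assert cfg.normal_please_die == SignalSpec(1, 2.0)
        with pytest.raises(ValueError):
            SignalConfig.from_table1(6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SignalSpec(-1, 1.0)
        with pytest.raises(ValueError):
            SignalSpec(1, 0.0)


def test_kernel_matches_decay_profile():
    spec = SignalSpec(2, 3.0)
    k = build_kernel(spec)
    assert k[2, 2, 2] == 0.0  # emitter excluded
    assert k[2, 2, 1] == pytest.approx(2.0)  # d=1
    assert k[0, 0, 0] == pytest.approx(1.0)  # d=2 corner
    # total deposited signal <= strength x number of covered sites
    assert k.sum() <= spec.strength * (5**3 - 1)


class TestViolation:
    def test_adjacent_tumor_violates(self):
        g = make_grid(single_tumor_phenotypes((7, 7, 7)))
        assert detect_spatial_violation(g, g.cells[(3, 3, 2)])

    def test_distant_tumor_does_not(self):
        g = make_grid(single_tumor_phenotypes((9, 9, 9)))
        assert not detect_spatial_violation(g, g.cells[(4, 4, 1)])  # distance 3

    def test_all_normal_tissue_is_quiet(self):
        g = make_grid(uniform_phenotypes((5, 5, 5)))
        assert not detect_spatial_violation(g, g.cells[(2, 2, 2)])

    def test_tumor_cell_rejected(self):
        g = make_grid(single_tumor_phenotypes((7, 7, 7)))
        with pytest.raises(ValueError):
            detect_spatial_violation(g, g.cells[(3, 3, 3)])


class TestEmission:
    def test_please_die_set2_deposits(self):
        # set 2: please die radius 1, strength 1 -> 0.5 on each neighbor
        g = make_grid(single_tumor_phenotypes((7, 7, 7)))
        cfg = SignalConfig.from_table1(2)
        emitter = g.cells[(3, 3, 2)]
        deposits = emit_please_die(g, emitter, cfg)
        assert len(deposits) == 26  # confluent tissue: all neighbors occupied
        assert all(v == pytest.approx(0.5) for v in deposits.values())
        assert all(chebyshev(emitter.pos, p) == 1 for p in deposits)

    def test_isolated_emitter_deposits_nothing(self):
        phen = np.zeros((5, 5, 5), dtype=np.int8)
        phen[2, 2, 2] = 1
        g = make_grid(phen)
        assert emit_please_die(g, g.cells[(2, 2, 2)], SignalConfig.from_table1(2)) == {}

    def test_tumor_cannot_emit_please_die(self):
        g = make_grid(single_tumor_phenotypes((7, 7, 7)))
        with pytest.raises(ValueError):
            emit_please_die(g, g.cells[(3, 3, 3)], SignalConfig.from_table1(2))

    def test_im_dying_total_emission_failure(self, rng):
        g = make_grid(single_tumor_phenotypes((7, 7, 7)))
        cfg = SignalConfig.from_table1(5)
        res = ResistanceParams(fail_emit_prob=1.0)
        for _ in range(50):
            assert emit_im_dying(g, g.cells[(3, 3, 3)], cfg, res, rng) == {}

    def test_im_dying_set5_tumor_field(self, rng):
        g = make_grid(single_tumor_phenotypes((9, 9, 9)))
        cfg = SignalConfig.from_table1(5)
        deposits = emit_im_dying(g, g.cells[(4, 4, 4)], cfg, ResistanceParams(), rng)
        assert len(deposits) == 124  # radius-2 ball, all occupied
        d1 = {p: v for p, v in deposits.items() if chebyshev((4, 4, 4), p) == 1}
        d2 = {p: v for p, v in deposits.items() if chebyshev((4, 4, 4), p) == 2}
        assert all(v == pytest.approx(2.0) for v in d1.values())
        assert all(v == pytest.approx(1.0) for v in d2.values())

    def test_im_dying_set5_normal_field(self, rng):
        g = make_grid(uniform_phenotypes((7, 7, 7)))
        cfg = SignalConfig.from_table1(5)
        deposits = emit_im_dying(g, g.cells[(3, 3, 3)], cfg, ResistanceParams(), rng)
        assert len(deposits) == 26  # normal report: radius 1
        assert all(v == pytest.approx(1.0) for v in deposits.values())


class TestAccumulation:
    def test_pure_sum_at_full_retention(self):
        assert apply_deposits(3.0, [2.0, 1.0], 1.0) == pytest.approx(6.0)

    def test_memoryless_at_zero_retention(self):
        assert apply_deposits(100.0, [2.0], 0.0) == pytest.approx(2.0)

    def test_invalid_retention(self):
        with pytest.raises(ValueError):
            apply_deposits(0.0, [1.0], 1.5)

    def test_fold_matches_recursive_oracle(self, rng):
        # 50 random deposit batches, rho = 0.9, vs closed-form evaluation
        rho = 0.9
        batches = [list(rng.random(rng.integers(0, 4))) for _ in range(50)]
        acc = 0.0
        for b in batches:
            acc = apply_deposits(acc, b, rho)
        oracle = sum(
            rho ** (len(batches) - 1 - t) * sum(b) for t, b in enumerate(batches)
        )
        assert acc == pytest.approx(oracle)


class TestResponse:
    TH = Thresholds()

    def tumor(self):
        return Cell(0, "tumor", (0, 0, 0))

    def normal(self):
        return Cell(1, "normal", (0, 0, 0))

    def test_tumor_apoptosis_needs_threshold_and_requests(self):
        assert respond(self.tumor(), Accumulator(apoptotic=1.5, requests=1), self.TH) == "apoptose"
        assert respond(self.tumor(), Accumulator(apoptotic=0.5, requests=5), self.TH) == "none"
        assert respond(self.tumor(), Accumulator(apoptotic=5.0, requests=0), self.TH) == "none"

    def test_deterministic_resistance_raises_required_requests(self):
        th = Thresholds(count_tumor=6, count_normal=16)
        assert respond(self.tumor(), Accumulator(apoptotic=9.0, requests=5), th) == "none"
        assert respond(self.tumor(), Accumulator(apoptotic=9.0, requests=6), th) == "apoptose"

    def test_normal_priority_order(self):
        acc = Accumulator(apoptotic=20.0, repop=5.0, requests=3)
        assert respond(self.normal(), acc, self.TH, alarm_please_die=9.0) == "apoptose"
        acc = Accumulator(apoptotic=2.0, repop=5.0, requests=3)
        assert respond(self.normal(), acc, self.TH, alarm_please_die=9.0) == "accelerate"
        acc = Accumulator(apoptotic=2.0, repop=0.5, requests=3)
        assert respond(self.normal(), acc, self.TH, alarm_please_die=9.0) == "emit_early"
        assert respond(self.normal(), acc, self.TH, alarm_please_die=0.0) == "none"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(low_normal_repop=20.0)  # low above high
        with pytest.raises(ValueError):
            Thresholds(high_tumor=0.0)


def test_qualifying_request_boundary():
    assert qualifying_request(0.5, 1.0)  # exactly half strength counts
    assert not qualifying_request(0.49, 1.0)


def test_resistance_validation():
    with pytest.raises(ValueError):
        ResistanceParams(ignore_prob=1.5)
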