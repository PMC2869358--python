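"""Time-stepped simulation of the cell society.

The engine advances a 3-D membrane of normal and tumor cells through
fixed-order phases each step:

1. intrinsic deaths are drawn (random death, senescence);
2. rescue-signal emissions — death reports from every cell dying this
   step (and cells crushed by tumor pressure last step), "please die"
   from spatially violated or primed normal cells;
3. deposits are accumulated per receiving cell, with per-deposit
   stochastic ignoring by tumor cells;
4. responses — apoptosis marks, replication acceleration, priming for
   early emission; cells killed by a response report their own death in
   the same step (this carries the death wave into the tumor interior);
5. all dead cells are removed simultaneously;
6. divisions — every live cell attempts division concurrently; site
   conflicts are resolved uniformly at random, normal cells divide only
   into free Moore-neighborhood sites, tumor cells fall back to free
   radius-2 sites and then to displacing an adjacent normal cell;
7. the clock advances.

All state lives in dense per-site numpy arrays; neighborhood sums are
computed with small-kernel correlations, so a 20x20x20 membrane steps in
about a millisecond.  Every random draw flows through one
``numpy.random.Generator``, so a (config, seed) pair determines the
trajectory bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cells import UNLIMITED
from .config import Config
from .lattice import FREE, NORMAL, TUMOR, Cell, Grid, ball_offsets, shell_offsets
from .signaling import decay_profile

_PAD = 2  # halo width; covers division radius 2 and displacement lookups

_PHENOTYPE_NAME = {NORMAL: "normal", TUMOR: "tumor"}


def _shell_kernel(d: int, metric: str) -> np.ndarray:
    r = d
    k = np.zeros((2 * r + 1,) * 3)
    for off in shell_offsets(d, metric):
        k[off[0] + r, off[1] + r, off[2] + r] = 1.0
    return k


@dataclass
class RunResult:
    """Outcome of one full experiment run."""

    outcome: str  # success | collapse | timeout
    steps_elapsed: int  # steps after planting
    final_normal_frac: float
    final_tumor_frac: float
    baseline_normal: int
    seed: int | None = None
    config_hash: str = ""
    growth_steps: int = 0
    growth_degenerate: bool = False
    trace: pd.DataFrame | None = None

    @property
    def success(self) -> bool:
        return self.outcome == "success"


def classify_outcome(
    n_tumor: int, n_normal: int, baseline_normal: int, integrity_frac: float, timed_out: bool
) -> str:
    """Terminal-state classification.

    Success requires every tumor cell dead and the normal population at or
    above the integrity fraction of its pre-tumor baseline.  A run that
    exhausts the horizon with live tumor cells is a timeout; a tumor-free
    state whose normal population never recovered (or died out) is a
    collapse — the healthy system was irreversibly wiped out.
    """
    if n_tumor == 0 and n_normal >= integrity_frac * baseline_normal:
        return "success"
    if n_tumor > 0 and timed_out:
        return "timeout"
    return "collapse"


class SimulationState:
    """Dense-array state of the membrane plus the run bookkeeping."""

    def __init__(self, config: Config, rng: np.random.Generator | int | None = None):
        self.cfg = config
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.rng = rng

        self.extents = tuple(config.grid.extents)
        X, Y, Z = self.extents
        self.shape = (X, Y, Z)
        self._pshape = (X + 2 * _PAD, Y + 2 * _PAD, Z + 2 * _PAD)
        self._core = (slice(_PAD, -_PAD),) * 3

        self.phen = np.zeros(self.shape, dtype=np.int8)
        self.phen_p = np.full(self._pshape, -1, dtype=np.int8)  # halo = wall

        f8 = lambda: np.zeros(self.shape, dtype=np.float64)
        self.prolif = f8()
        self.death = f8()
        self.acc_ap = f8()  # accumulated apoptotic signal
        self.acc_rp = f8()  # accumulated death-report signal (repopulation cue)
        self.req = f8()  # accumulated qualifying-request count
        self.genpot = np.zeros(self.shape, dtype=np.int32)
        self.age = np.zeros(self.shape, dtype=np.int32)
        self.generation = np.zeros(self.shape, dtype=np.int32)
        self.cellid = np.full(self.shape, -1, dtype=np.int64)
        self.flags = np.zeros(self.shape, dtype=np.int8)  # intact-protocol bitmask
        self.accel = np.zeros(self.shape, dtype=np.int16)
        self.primed = np.zeros(self.shape, dtype=bool)
        self.pending_crushed = np.zeros(self.shape, dtype=bool)

        self._next_id = 0
        self.clock = 0
        self.rescue_active = False
        self.baseline_normal = 0
        self.growth_steps = 0
        self.growth_degenerate = False
        self._alarm = np.zeros(self.shape)
        self.trace_rows: list[dict] = []

        # resolved parameter objects
        self.ranges = config.ranges()
        self.signal_cfg = config.signal_config()
        self.thresholds = config.thresholds_obj()
        self.resistance = config.resistance_obj()

        # precomputed geometry: padded-flat offsets for division lookups
        pYZ = self._pshape[1] * self._pshape[2]
        pZ = self._pshape[2]
        self._off1 = np.array([dx * pYZ + dy * pZ + dz for dx, dy, dz in ball_offsets(1)])
        self._off2 = np.array([dx * pYZ + dy * pZ + dz for dx, dy, dz in shell_offsets(2)])
        ix, iy, iz = np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z), indexing="ij")
        self._pad_of = (
            ((ix + _PAD) * pYZ + (iy + _PAD) * pZ + (iz + _PAD)).ravel().astype(np.int64)
        )

        # per signal class: deposit value and request-qualification per shell
        self._class_profiles = {}
        for name in ("tumor_im_dying", "normal_im_dying", "normal_please_die"):
            spec = self.signal_cfg.spec(name)
            vals = decay_profile(spec, self.signal_cfg.decay)
            kerns = [_shell_kernel(d, self.signal_cfg.metric) for d in range(1, spec.radius + 1)]
            qual = vals >= 0.5 * spec.strength
            self._class_profiles[name] = (vals, kerns, qual)
        vr = config.signals.violation_radius
        self._violation_size = 2 * vr + 1

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def seed_cell(self, pos=None, phenotype: str = "normal") -> None:
        if pos is None:
            pos = tuple(e // 2 for e in self.extents)
        self._materialize(np.array([np.ravel_multi_index(pos, self.shape)]), phenotype)

    def _materialize(self, flat_idx: np.ndarray, phenotype: str) -> None:
        """Place freshly sampled cells of one phenotype at flat sites."""
        n = len(flat_idx)
        plo, phi = self.ranges.prolif(phenotype)
        dlo, dhi = self.ranges.death(phenotype)
        code = TUMOR if phenotype == "tumor" else NORMAL
        self.phen.ravel()[flat_idx] = code
        self.prolif.ravel()[flat_idx] = self.rng.uniform(plo, phi, n)
        self.death.ravel()[flat_idx] = self.rng.uniform(dlo, dhi, n)
        self.genpot.ravel()[flat_idx] = (
            UNLIMITED if phenotype == "tumor" else self.cfg.population.generation_potential
        )
        self.flags.ravel()[flat_idx] = 0 if phenotype == "tumor" else 0b1111
        self.cellid.ravel()[flat_idx] = np.arange(self._next_id, self._next_id + n)
        self._next_id += n

    @classmethod
    def from_phenotype_array(
        cls,
        phen: np.ndarray,
        config: Config,
        rng: np.random.Generator | int | None = None,
        prolif: float | np.ndarray | None = None,
        death: float | np.ndarray | None = None,
    ) -> "SimulationState":
        """State from an explicit 0/1/2 phenotype array (test fixtures).

        ``prolif``/``death`` may pin the per-step probabilities instead of
        sampling them from the population ranges.
        """
        phen = np.asarray(phen, dtype=np.int8)
        cfg = config.model_copy(deep=True)
        cfg.grid.extents = tuple(phen.shape)
        state = cls(cfg, rng)
        for code, name in ((NORMAL, "normal"), (TUMOR, "tumor")):
            idx = np.flatnonzero(phen.ravel() == code)
            if len(idx):
                state._materialize(idx, name)
        for arr, override in ((state.prolif, prolif), (state.death, death)):
            if override is not None:
                arr[phen > 0] = np.broadcast_to(np.asarray(override, dtype=float), phen.shape)[
                    phen > 0
                ]
        return state

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def count(self, phenotype: str = "any") -> int:
        if phenotype == "any":
            return int((self.phen > 0).sum())
        return int((self.phen == (TUMOR if phenotype == "tumor" else NORMAL)).sum())

    def occupancy(self, phenotype: str = "any") -> float:
        return self.count(phenotype) / self.phen.size

    def to_grid(self) -> Grid:
        grid = Grid(self.extents)
        for pos in zip(*np.nonzero(self.phen)):
            pos = tuple(int(v) for v in pos)
            grid.place(
                Cell(
                    id=int(self.cellid[pos]),
                    phenotype=_PHENOTYPE_NAME[int(self.phen[pos])],
                    pos=pos,
                    prolif_prob=float(self.prolif[pos]),
                    death_prob=float(self.death[pos]),
                    generation_potential=int(self.genpot[pos]),
                    age=int(self.age[pos]),
                    generation=int(self.generation[pos]),
                )
            )
        return grid

    # ------------------------------------------------------------------
    # signal fields
    # ------------------------------------------------------------------
    def _receipts(self, emitters: dict[str, np.ndarray]):
        """Per-site signal receipts from this round's emitter masks.

        Returns (apoptotic deposits, repop deposits, please-die alarm,
        qualifying-request additions); tumor sites have per-deposit
        ignoring already applied.
        """
        ap = np.zeros(self.shape)
        rp = np.zeros(self.shape)
        alarm = np.zeros(self.shape)
        reqs = np.zeros(self.shape)
        q = self.resistance.ignore_prob
        tumor_flat = np.flatnonzero((self.phen == TUMOR).ravel()) if q > 0 else None
        for name, mask in emitters.items():
            if not mask.any():
                continue
            vals, kerns, qual = self._class_profiles[name]
            field_ = mask.astype(np.float64)
            for vd, kern, qd in zip(vals, kerns, qual):
                counts = np.rint(
                    ndimage.correlate(field_, kern, mode="constant", cval=0.0)
                )
                if q > 0 and len(tumor_flat):
                    # tumor cells drop each individual deposit with prob q
                    c_t = counts.ravel()[tumor_flat].astype(np.int64)
                    passed = self.rng.binomial(c_t, 1.0 - q).astype(np.float64)
                    counts_t = counts.copy().ravel()
                    counts_t[tumor_flat] = passed
                    counts_t = counts_t.reshape(self.shape)
                else:
                    counts_t = counts
                tumor_mask = self.phen == TUMOR
                eff = np.where(tumor_mask, counts_t, counts)
                ap += vd * eff
                if qd:
                    reqs += eff
                if name != "normal_please_die":
                    rp += vd * counts  # repopulation cue, read by normals only
                else:
                    alarm += vd * counts
        return ap, rp, alarm, reqs

    def _emit_and_accumulate(self, dying: np.ndarray, fold: bool) -> int:
        """One emission round; returns the number of emitters.

        ``fold`` applies the leaky-retention decay before adding (used for
        the first round of a step); the second, same-step round adds on
        top without further decay.
        """
        cfgs = self.cfg.signals
        f = self.resistance.fail_emit_prob
        emitters: dict[str, np.ndarray] = {}
        n_emit = 0
        if cfgs.enable_im_dying:
            dying_t = dying & (self.phen == TUMOR)
            if f > 0 and dying_t.any():
                keep = self.rng.random(self.shape) >= f
                dying_t = dying_t & keep
            dying_n = dying & (self.phen == NORMAL)
            if fold and self.cfg.engine.crushed_emit:
                dying_n = dying_n | self.pending_crushed
            emitters["tumor_im_dying"] = dying_t
            emitters["normal_im_dying"] = dying_n
            n_emit += int(dying_t.sum()) + int(dying_n.sum())
        if fold and cfgs.enable_please_die:
            tumor_near = (
                ndimage.maximum_filter(
                    (self.phen == TUMOR).astype(np.int8),
                    size=self._violation_size,
                    mode="constant",
                    cval=0,
                )
                > 0
            )
            pd_emitters = (self.phen == NORMAL) & (tumor_near | self.primed)
            emitters["normal_please_die"] = pd_emitters
            n_emit += int(pd_emitters.sum())
        if not any(m.any() for m in emitters.values()):
            if fold:
                rho = cfgs.retention
                self.acc_ap *= rho
                self.acc_rp *= rho
                self.req *= rho
                self._alarm = np.zeros(self.shape)
            return 0
        ap, rp, alarm, reqs = self._receipts(emitters)
        if fold:
            rho = cfgs.retention
            self.acc_ap = rho * self.acc_ap + ap
            self.acc_rp = rho * self.acc_rp + rp
            self.req = rho * self.req + reqs
            self._alarm = alarm
        else:
            self.acc_ap += ap
            self.acc_rp += rp
            self.req += reqs
        return n_emit

    # ------------------------------------------------------------------
    # the step
    # ------------------------------------------------------------------
    def step(self) -> dict:
        """Advance one time step; returns the per-step count record."""
        normal = self.phen == NORMAL
        tumor = self.phen == TUMOR
        alive = normal | tumor

        # 1. intrinsic deaths (random + senescent)
        draw = self.rng.random(self.shape)
        senescent = alive & (self.genpot <= 0) & (self.age > self.cfg.engine.senescence_age)
        dying = (alive & (draw < self.death)) | senescent
        n_intrinsic = int(dying.sum())

        n_apop_t = n_apop_n = n_emitters = 0
        if self.rescue_active:
            # 2-3. emissions and accumulation
            n_emitters = self._emit_and_accumulate(dying, fold=True)

            # 4. responses
            th = self.thresholds
            apop_t = (
                tumor
                & ~dying
                & (self.acc_ap >= th.high_tumor)
                & (self.req >= th.count_tumor)
            )
            apop_n = (
                normal
                & ~dying
                & (self.acc_ap >= th.high_normal)
                & (self.req >= th.count_normal)
            )
            live_n = normal & ~dying & ~apop_n
            accelerate = live_n & (self.acc_rp >= th.low_normal_repop)
            self.accel[accelerate] = th.acceleration_steps
            self.primed = live_n & ~accelerate & (self._alarm >= th.low_normal_please_die)
            n_apop_t = int(apop_t.sum())
            n_apop_n = int(apop_n.sum())

            # 4b. cells killed by a response report their death this step
            apop = apop_t | apop_n
            if apop.any():
                n_emitters += self._emit_and_accumulate(apop, fold=False)
            dying = dying | apop
        else:
            self.primed[:] = False

        self.pending_crushed[:] = False

        # 5. simultaneous removal
        if dying.any():
            self._clear_sites(dying)

        # 6. divisions
        n_crushed = self._divisions()

        # 7. clock
        self.age[self.phen > 0] += 1
        np.maximum(self.accel - 1, 0, out=self.accel)
        self.clock += 1

        rec = {
            "step": self.clock,
            "n_normal": self.count("normal"),
            "n_tumor": self.count("tumor"),
            "deaths_intrinsic": n_intrinsic,
            "deaths_apoptosis_tumor": n_apop_t,
            "deaths_apoptosis_normal": n_apop_n,
            "deaths_crushed": n_crushed,
            "emitters": n_emitters,
            "rescue_active": self.rescue_active,
        }
        self.trace_rows.append(rec)
        return rec

    def _clear_sites(self, mask: np.ndarray) -> None:
        self.phen[mask] = FREE
        for arr in (self.prolif, self.death, self.acc_ap, self.acc_rp, self.req):
            arr[mask] = 0.0
        for arr in (self.genpot, self.age, self.generation, self.accel, self.flags):
            arr[mask] = 0
        self.cellid[mask] = -1
        self.primed[mask] = False

    # ------------------------------------------------------------------
    # divisions
    # ------------------------------------------------------------------
    def _divisions(self) -> int:
        cfgp = self.cfg.population
        normal = self.phen == NORMAL
        tumor = self.phen == TUMOR

        p_eff = self.prolif.copy()
        if tumor.any() and cfgp.suppression_factor != 1.0:
            near_tumor = (
                ndimage.maximum_filter(
                    tumor.astype(np.int8), size=3, mode="constant", cval=0
                )
                > 0
            )
            p_eff[normal & near_tumor] *= cfgp.suppression_factor
        boosted = normal & (self.accel > 0)
        p_eff[boosted] = np.minimum(
            p_eff[boosted] * self.thresholds.acceleration_factor, 1.0
        )

        attempt = (normal | tumor) & (self.genpot > 0) & (self.rng.random(self.shape) < p_eff)
        att = np.flatnonzero(attempt.ravel())
        if len(att) == 0:
            return 0

        self.phen_p[self._core] = self.phen  # refresh halo copy for neighbor lookups
        phenf = self.phen_p.ravel()
        ppos = self._pad_of[att]
        nb1 = ppos[:, None] + self._off1
        occ1 = phenf[nb1]
        free1 = occ1 == FREE
        n1 = free1.sum(axis=1)
        is_tumor = self.phen.ravel()[att] == TUMOR

        m = len(att)
        targets = np.full(m, -1, dtype=np.int64)
        displace = np.zeros(m, dtype=bool)

        sel = n1 > 0
        if sel.any():
            targets[sel] = self._choose(nb1[sel], free1[sel], n1[sel])

        t2 = is_tumor & ~sel
        if t2.any():
            idx2 = np.nonzero(t2)[0]
            nb2 = ppos[idx2][:, None] + self._off2
            free2 = phenf[nb2] == FREE
            n2 = free2.sum(axis=1)
            s2 = n2 > 0
            if s2.any():
                targets[idx2[s2]] = self._choose(nb2[s2], free2[s2], n2[s2])
            if cfgp.allow_displacement:
                rest = idx2[~s2]
                if len(rest):
                    vict = occ1[rest] == NORMAL
                    nv = vict.sum(axis=1)
                    sv = nv > 0
                    if sv.any():
                        targets[rest[sv]] = self._choose(nb1[rest[sv]], vict[sv], nv[sv])
                        displace[rest[sv]] = True

        valid = targets >= 0
        if not valid.any():
            return 0
        par = att[valid]
        tgt_p = targets[valid]
        disp = displace[valid]

        # simultaneous attempts: resolve site conflicts uniformly at random
        prio = self.rng.random(len(par))
        order = np.lexsort((prio, tgt_p))
        tgt_sorted = tgt_p[order]
        first = np.ones(len(order), dtype=bool)
        first[1:] = tgt_sorted[1:] != tgt_sorted[:-1]
        win = order[first]
        par, tgt_p, disp = par[win], tgt_p[win], disp[win]

        # padded flat -> interior flat
        pY, pZ = self._pshape[1], self._pshape[2]
        px, rem = np.divmod(tgt_p, pY * pZ)
        py, pz = np.divmod(rem, pZ)
        tgt = np.ravel_multi_index(
            (px - _PAD, py - _PAD, pz - _PAD), self.shape
        ).astype(np.int64)

        # gather parent traits before any in-place writes
        prolif_par = self.prolif.ravel()[par]
        death_par = self.death.ravel()[par]
        phen_par = self.phen.ravel()[par]
        flags_par = self.flags.ravel()[par]

        # parent bookkeeping (a crushed parent is overwritten below anyway)
        gp = self.genpot.ravel()
        limited = gp[par] != UNLIMITED
        gp[par] = np.where(limited, np.maximum(gp[par] - 1, 0), gp[par])
        self.generation.ravel()[par] += 1
        genpot_d = gp[par]
        gen_d = self.generation.ravel()[par]

        # crushed victims (displacement targets) die; they report next step
        n_crushed = int(disp.sum())
        if n_crushed:
            crushed_mask = np.zeros(self.phen.size, dtype=bool)
            crushed_mask[tgt[disp]] = True
            self._clear_sites(crushed_mask.reshape(self.shape))
            if self.rescue_active and self.cfg.engine.crushed_emit:
                self.pending_crushed.ravel()[tgt[disp]] = True

        # daughters inherit with multiplicative skew, clipped to range
        skew = cfgp.skew
        n = len(par)
        pl = self.rng.uniform(1 - skew, 1 + skew, n) * prolif_par
        dl = self.rng.uniform(1 - skew, 1 + skew, n) * death_par
        t_mask = phen_par == TUMOR
        for mask_, (plo, phi), (dlo, dhi) in (
            (~t_mask, self.ranges.prolif("normal"), self.ranges.death("normal")),
            (t_mask, self.ranges.prolif("tumor"), self.ranges.death("tumor")),
        ):
            pl[mask_] = np.clip(pl[mask_], plo, phi)
            dl[mask_] = np.clip(dl[mask_], dlo, dhi)

        self.phen.ravel()[tgt] = phen_par
        self.prolif.ravel()[tgt] = pl
        self.death.ravel()[tgt] = dl
        self.genpot.ravel()[tgt] = genpot_d
        self.age.ravel()[tgt] = -1  # ages to 0 in phase 7
        self.generation.ravel()[tgt] = gen_d
        self.flags.ravel()[tgt] = flags_par
        self.cellid.ravel()[tgt] = np.arange(self._next_id, self._next_id + n)
        self._next_id += n
        for arr in (self.acc_ap, self.acc_rp, self.req):
            arr.ravel()[tgt] = 0.0
        self.accel.ravel()[tgt] = 0
        self.primed.ravel()[tgt] = False

        if cfgp.mutation_prob > 0:
            self._mutate_daughters(tgt[phen_par == NORMAL])
        return n_crushed

    def _choose(self, nb: np.ndarray, mask: np.ndarray, n: np.ndarray) -> np.ndarray:
        """Uniform random pick of one True column per row."""
        r = self.rng.integers(0, n)
        csum = mask.cumsum(axis=1)
        col = (csum == (r + 1)[:, None]).argmax(axis=1)
        return nb[np.arange(len(nb)), col]

    def _mutate_daughters(self, tgt: np.ndarray) -> None:
        """Protocol-loss check-point for newborn normal cells.

        Repair must fall first: while the repair bit survives, other
        freshly lost bits are restored.  A cell losing all four protocols
        becomes a tumor cell with freshly sampled tumor traits.
        """
        p = self.cfg.population.mutation_prob
        REPAIR = 0b0001
        for i in tgt:
            bits = int(self.flags.ravel()[i])
            lost = 0
            for b in (0b0001, 0b0010, 0b0100, 0b1000):
                if bits & b and self.rng.random() < p:
                    lost |= b
            if not lost:
                continue
            if (bits & REPAIR) and not (lost & REPAIR):
                continue  # repair intact: every other fresh loss is corrected
            bits &= ~lost
            self.flags.ravel()[i] = bits
            if bits == 0:
                self._materialize(np.array([i]), "tumor")

    # ------------------------------------------------------------------
    # planting
    # ------------------------------------------------------------------
    def plant_tumor(self, site=None) -> None:
        """Replace one occupied site's cell with a sampled tumor cell."""
        occ = np.flatnonzero((self.phen > 0).ravel())
        if len(occ) == 0:
            raise RuntimeError("cannot plant a tumor into an empty membrane")
        if site is None:
            center = tuple(e // 2 for e in self.extents)
            cflat = np.ravel_multi_index(center, self.shape)
            if self.phen.ravel()[cflat] > 0:
                idx = cflat
            else:
                pos = np.array(np.unravel_index(occ, self.shape)).T
                d = np.abs(pos - np.array(center)).max(axis=1)
                idx = occ[int(d.argmin())]
        else:
            idx = np.ravel_multi_index(tuple(site), self.shape)
            if self.phen.ravel()[idx] == FREE:
                raise ValueError(f"plant site {site} is not occupied")
        mask = np.zeros(self.phen.size, dtype=bool)
        mask[idx] = True
        self._clear_sites(mask.reshape(self.shape))
        self._materialize(np.array([idx]), "tumor")
        self.baseline_normal = self.count("normal")

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace_rows)


# ---------------------------------------------------------------------------
# high-level drivers
# ---------------------------------------------------------------------------

def grow_to_confluence(
    config: Config, rng: np.random.Generator | int | None = None
) -> SimulationState:
    """Grow the membrane from a single central normal cell to confluence.

    Confluence is occupancy >= ``engine.confluence_frac`` (intrinsic
    deaths keep a handful of sites transiently vacant, so a full membrane
    holds a small, steady number of holes).  Hitting the growth step cap
    first flags the state as degenerate.
    """
    state = SimulationState(config, rng)
    state.seed_cell()
    target = config.engine.confluence_frac
    cap = config.engine.growth_step_cap
    state.growth_degenerate = False
    while state.occupancy() < target:
        state.step()
        if state.count() == 0:
            # the founder lineage died out before establishing; re-seed
            state.seed_cell()
        if state.clock >= cap:
            state.growth_degenerate = True
            break
    state.growth_steps = state.clock
    return state


def run(
    config: Config,
    seed: np.random.Generator | int | None = None,
    keep_trace: bool = False,
) -> RunResult:
    """One full experiment: growth, planting, rescue, classification.

    The membrane grows to confluence, a single tumor cell is planted, and
    the rescue protocols activate after ``engine.activation_delay`` steps
    (or once tumor occupancy reaches ``engine.activation_volume`` when
    set).  The run then steps until the tumor is extinct and the normal
    population has recovered to the integrity fraction of its pre-tumor
    baseline (success), the normal population is irrecoverable (collapse),
    or ``engine.max_steps`` post-planting steps elapse.
    """
    eng = config.engine
    state = grow_to_confluence(config, seed)
    if not eng.plant:
        # observational run of the homeostatic system
        for _ in range(eng.max_steps):
            state.step()
        n_n, n_t = state.count("normal"), state.count("tumor")
        return RunResult(
            outcome=classify_outcome(n_t, n_n, max(state.baseline_normal, n_n), eng.integrity_frac, True),
            steps_elapsed=eng.max_steps,
            final_normal_frac=state.occupancy("normal"),
            final_tumor_frac=state.occupancy("tumor"),
            baseline_normal=max(state.baseline_normal, n_n),
            seed=seed if isinstance(seed, int) else None,
            config_hash=config.hash(),
            growth_steps=state.growth_steps,
            growth_degenerate=state.growth_degenerate,
            trace=state.trace() if keep_trace else None,
        )

    state.plant_tumor(eng.plant_site)
    plant_step = state.clock
    if eng.activation_volume is None and eng.activation_delay == 0:
        state.rescue_active = True

    outcome = None
    while state.clock - plant_step < eng.max_steps:
        if not state.rescue_active:
            if eng.activation_volume is not None:
                if state.occupancy("tumor") >= eng.activation_volume:
                    state.rescue_active = True
            elif state.clock - plant_step >= eng.activation_delay:
                state.rescue_active = True
        state.step()
        n_t = state.count("tumor")
        n_n = state.count("normal")
        if n_t == 0 and n_n >= eng.integrity_frac * state.baseline_normal:
            outcome = "success"
            break
        if n_n == 0:
            outcome = "collapse"  # healthy tissue irreversibly gone
            break

    n_t, n_n = state.count("tumor"), state.count("normal")
    if outcome is None:
        outcome = classify_outcome(
            n_t, n_n, state.baseline_normal, eng.integrity_frac, timed_out=True
        )
    return RunResult(
        outcome=outcome,
        steps_elapsed=state.clock - plant_step,
        final_normal_frac=state.occupancy("normal"),
        final_tumor_frac=state.occupancy("tumor"),
        baseline_normal=state.baseline_normal,
        seed=seed if isinstance(seed, int) else None,
        config_hash=config.hash(),
        growth_steps=state.growth_steps,
        growth_degenerate=state.growth_degenerate,
        trace=state.trace() if keep_trace else None,
    )
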