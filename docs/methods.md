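# Model and methods

`rescuesim` simulates a society of cycling cells on a bounded 3-D lattice
("membrane") to study one question: what inter-cellular communication
rules let a tissue selectively eradicate a growing tumor without
destroying itself?  The answer it implements is a pair of "rescue
protocols" — *please die* and *I'm dying* — that rely only on minimal
citizenship behaviors every cell retains: reporting its own death and
partially complying with external apoptosis commands.

## The lattice

A rectangular box of sites (default 20×20×20 = 8,000 sites) with hard
walls and at most one cell per site.  Distances are Chebyshev by default,
so radius 1 is the 26-cell Moore neighborhood and a radius-r signal
covers a cube of side 2r+1; a Euclidean metric is available for
sensitivity checks.  The 20³ default is a desk-scale choice: it is large
enough that a planted tumor can grow two orders of magnitude before
touching the walls, and small enough that a full experiment (growth,
battle, recovery) takes a fraction of a second, which is what makes
hundreds of replicated sweep conditions practical.

## Life protocols

Each cell carries per-step probabilities drawn uniformly from
phenotype-specific population ranges:

| quantity            | normal                  | tumor            |
|---------------------|-------------------------|------------------|
| proliferation       | 0.05–0.15 (ratio 6), 0.03–0.09 (ratio 10), 0.015–0.045 (ratio 20) | 0.3–0.9 |
| intrinsic death     | 0.0024–0.0048           | 0.0001–0.0002    |

The *relative proliferation ratio* (6, 10, 20) is the quotient of the
range midpoints (0.6/0.1 = 6, etc.) and is the main dial for tumor
aggressiveness.  Daughters inherit their parent's probabilities with a
multiplicative skew U(1−s, 1+s), s = 0.1 by default, clipped back into
the population range; this keeps heterogeneity bounded while letting
lineages drift.  Normal cells carry a finite generation potential
(default 50 divisions, Hayflick-like; exhausted cells die after a
senescence horizon of 200 steps); tumor cells are unlimited.

Contact inhibition: a normal cell divides only into a free radius-1
site.  Tumor cells violate spatial regulation in two escalating ways:
they reach free sites up to radius 2, and when fully enclosed they
displace (crush) a random adjacent normal cell.  The displacement rule
is what lets a tumor exert pressure on confluent tissue — without it a
full membrane would only yield space at the intrinsic death rate
(~0.004/site/step) and a tumor could never reach a meaningful volume
within a run.  Crushed cells die and, when the rescue protocols are
active, report their deaths like any other dying cell.  Normal cells
adjacent to a tumor have their proliferation probability multiplied by a
suppression factor (default 0.5), the contact-pressure effect.

Tumorigenesis is the loss of four guarding protocols — repair,
apoptosis, proliferation-suppression, distance regulation — checked at
each division with a per-protocol mutation probability.  While the
repair protocol is intact it restores any other freshly lost flag, so
repair must fall first; a cell with all four lost is a tumor cell and
never reverts.  For the sweep experiments spontaneous mutation is off
(probability 0) and a single tumor cell is instead planted at the grid
center once the membrane is confluent, replacing the resident cell so
the membrane stays full.

## Rescue protocols

Signals are quantified in abstract signal units.  An emitter of strength
s and radius r deposits s·(1 − d/(r+1)) on every occupied site at
distance d ≤ r (emitter excluded); an exponential decay law is available
by configuration.  The five published signal parameter sets (radius/
strength for tumor death reports, normal death reports, and please-die
requests) are selectable by label 1–5.

*Please die*: a normal cell with a tumor cell inside its violation
radius (default 1) broadcasts an apoptosis request each step.  A normal
cell that received at least `low_please_die` (default 2.0) units of
please-die signal in the current step becomes *primed* and emits even
without direct violation — the early-warning halo that resists tumor
re-growth.

*I'm dying*: every cell dying this step — intrinsically, by signal, or
crushed — reports its death with its phenotype's radius/strength.  A
dying tumor cell fails to report with probability f (stochastic
resistance); normal cells always report.

Receivers integrate deposits in a leaky accumulator:
acc ← ρ·acc + Σ(deposits), with retention ρ = 0.9 per step.  A strictly
unit-retention accumulator would make every normal cell integrate the
~0.1 units/step of background death-report signal generated by ordinary
tissue turnover and eventually cross any finite apoptosis threshold
during long battles; ρ = 0.9 bounds that background near 1 unit while
leaving the sharp, localized deposits of a death wave (many units in one
or two steps) essentially undamped.  Tumor cells additionally drop each
individual incoming deposit with probability q (stochastic resistance at
the cell level); deposits worth at least half the emitted strength count
as distinct *requests* toward the deterministic-resistance quota.

Responses, in priority order:

* tumor cell: apoptose when acc ≥ `high_tumor` (default 1.0 — one
  full-strength request) and at least `count_tumor` requests accrued.
* normal cell: apoptose when acc ≥ `high_normal` (default 16.0) with
  `count_normal` requests; else accelerate replication (×2 for 5 steps)
  when the accumulated death-report signal reaches `low_repop`
  (default 1.0); else become primed as above.

The threshold asymmetry is deliberate and load-bearing.  Tumor death
must chain: one dying tumor cell's report (1–2 units at distance 1) has
to push its tumor neighbors over their threshold, so `high_tumor` sits
at one request-equivalent and a death wave sweeps a connected cluster at
roughly one shell per step — this is what carries eradication into the
tumor interior, where no please-die signal can reach.  Normal death must
*not* chain: a planar front of dying cells deposits at most ≈ 9 × 1.5
units on the tissue behind it, so `high_normal` = 16 keeps the healthy
tissue subcritical — normals die only where death is locally
overwhelming (pockets enclosed by a collapsing tumor), which is the
observed, limited collateral damage.  The deterministic-resistance
legend (1/1 … 6/16) raises the request quotas for tumor/normal cells
respectively.

## The step

Fixed phase order: (1) draw intrinsic deaths; (2) emissions from dying
cells, crushed-last-step cells, violated and primed normals; (3) deposit
and accumulate, with per-deposit ignoring for tumors; (4) responses;
cells killed by a response emit their death reports in the same step
(without this the chain reaction stalls at the rim); (5) simultaneous
removal of all dead cells; (6) divisions — all attempts are concurrent
and site conflicts are resolved uniformly at random; (7) clock.

All state is dense numpy arrays; deposits are computed with small-kernel
shell correlations and per-deposit ignoring with binomial thinning of
the per-shell deposit counts, which is exact because the decay law takes
finitely many values per signal class.  A (config, seed) pair determines
the trajectory bit-for-bit.

## A run

1. **Growth**: from one normal cell at the center to confluence, defined
   as occupancy ≥ 0.99 (intrinsic deaths keep ~30 sites transiently
   vacant at equilibrium, so exact fullness is unreachable on large
   grids).  A founder lineage that dies out is re-seeded.
2. **Planting**: one tumor cell replaces the center cell; the normal
   count at this moment is the *baseline*.
3. **Activation**: the rescue protocols switch on after
   `activation_delay` steps (default 10, so the tumor establishes a
   cluster first) or, in delayed-activation experiments, once tumor
   occupancy reaches `activation_volume`.
4. **Battle and recovery**: stepping continues until the tumor is
   extinct *and* the normal population is at or above
   `integrity_frac` (default 0.5) of baseline — success; or the normal
   population hits zero — collapse; or `max_steps` (default 500
   post-planting) elapse — timeout, or collapse if the tumor is gone but
   the tissue never recovered.  Letting a below-integrity tissue keep
   regrowing after extinction implements "not *irreversibly* wiping out
   the healthy system": a recovered tissue was never irreversibly lost.

## Sweep experiments

Replicate seeds derive from (master seed, a stable hash of the condition
label, replicate index), so results are independent of the execution
order of conditions.  Success rates carry 95% Wilson score intervals.
Presets: the ratio × signal-set grid (38 replicates × 15 conditions
reproduces the published 570-run scale; tests use 30), the resistance
curves (success vs q and vs f on an even 0–1 grid, rescue active from
planting), and the activation-volume curve (0.1–0.9).

## What the generator does and does not emulate

Runs are self-generating: there is no external data.  The model captures
population heterogeneity, contact inhibition, stochastic growth and
death, signal decay and temporal integration, and both resistance modes.
It does not model molecular identities, immune cells, angiogenesis,
nutrient limits, chemotherapy, continuous-space mechanics, or diffusion
of free ligand (signals exist only on occupied sites).  Passing tests
therefore demonstrate the internal logic of the communication protocols,
not clinical efficacy.

## Numerical choices and limitations

* Thresholds compare with ≥, and a deposit of exactly half strength
  counts as a request, so the all-unit-strength signal set still
  functions.
* Division conflicts make concurrent attempts slightly sub-Poisson near
  crowded frontiers; growth speed is Eden-like, ∼0.15 sites/step radial
  at proliferation 0.1.
* With immediate activation a planted tumor is usually killed within a
  step or two by the please-die barrage of its 26 violated neighbors —
  resistance up to very high q/f changes little, which is why the
  resistance curves stay near 100% until close to total resistance and
  then collapse sharply (at q = 1 or f+q total the protocols are inert
  and the tumor overruns the membrane).
* Delayed activation succeeds even at high occupancies because the
  death-report chain sweeps any connected tumor mass; failures there are
  dominated by tissue recovery running out of horizon, so `max_steps`
  binds at large volumes.
* Desk scale throughout: 20³ sites, 30–40 replicates per condition.
  Larger membranes and replicate counts are configuration changes only.
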