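# Methods

## Problem and model

A multi-step preparative chromatography process must decide, at every step
*s*, which resin *r* and operating condition *c* to run and between which
two time intervals (*start*, *finish*) to pool the eluate.  The inputs are
high-throughput screening (HTS) experiments: for each candidate
(step, resin, condition) a microscale column run recording the loaded mass
`lm[s,r,c,p]` of every protein species *p* and the collected mass
`cm[s,r,c,p,t]` in every time interval *t* of a stepwise salt-gradient
elution.

Two criteria are computed for a complete decision:

- **Yield** `Y = CM[last, dp] / LM[first, dp]` — collected target-protein
  (*dp*) mass at the last step over its load at the first step;
- **Purity** `P = CM[last, dp] / Σ_p CM[last, p]` — the target's share of
  everything pooled at the last step.

First-step masses are the calibration experiment's own numbers restricted
to the pooled window.  Later steps receive whatever the previous step
pooled, an amount generally never run in the lab; their behaviour is
predicted with the **constant load-collection-ratio assumption**: the
fraction `lcr[s,r,c,p,t] = cm / lm` of a protein's load that appears in
interval *t* is taken to be independent of the loaded amount and of the
other species.  Predicted collected mass is then `M = lcr · LM`, so a
doubled load doubles every per-interval mass and a halved load halves it
(this exact proportionality is asserted in the tests and recomputed by
`scripts/acceptance.py`).  The assumption is the model's central
idealization: it ignores overloading/displacement effects and any
composition dependence of the isotherm, and is most defensible when the
later-step load stays within the linear range of the resin.

Consecutive steps are linked through the eluent: the salt concentration at
the previous step's finish cut-point may not exceed that at the next
step's start cut-point (a pool eluted at high salt cannot be loaded onto a
step that starts collecting below it without an intermediate conditioning
step, which the model excludes).

### Constraint system

Binary variables: `Z[s,r,c]` (condition choice, exactly one per step),
`Xs[s,t]`/`Xf[s,t]` (start/finish cut-points, exactly one each),
`X[s,t]` (interval selected), linked by the recursion
`X[s,t] = X[s,t-1] + Xs[s,t] - Xf[s,t-1]`.  The convention is
**inclusive**: the start-marked interval is the first pooled interval and
the finish-marked one the last, so a window `T4..T15` means `Xs` at T4 and
`Xf` at T15.  The joint indicator `W[s,r,c,t] = X[s,t] · Z[s,r,c]` is
linearized with an aggregated per-interval gate (`Σ_{r,c} W ≤ X`, valid
with coefficient 1 because only one condition is selected), an aggregated
per-condition gate (`Σ_t W ≤ T·Z`) and the lower bound `W ≥ X + Z − 1`.

Two formulation details found during verification:

- The recursion alone admits one spurious solution per position: placing
  the finish cut-point directly before the start (`finish = start − 1`)
  cancels the start and selects the empty window.  Since a decision must
  pool *something* (there is a starting and a finishing time for protein
  collection), an explicit ordering row `Σ_t t·Xs[s,t] ≤ Σ_t t·Xf[s,t]`
  per step excludes it.  Without this row, a purity floor that no real
  pool can meet is "satisfied" by collecting nothing.
- A worked illustration of the cut-point semantics that excludes the
  start-marked interval contradicts the recursion; the recursion
  (inclusive start) is authoritative here.

Mass balance: at the first step `LM = Σ lm·Z` and `M = cm·W` (no big-M
needed); `CM[s,p] = Σ M`, and `LM[s+1,p] = CM[s,p]` chains the steps
(instantiated only for `s <` last, avoiding a dangling load variable past
the final step).  At later steps the prediction `M = lcr·LM` holds only on
selected tuples, enforced by three rows per (s,r,c,p,t): `M ≤ lcr·LM`,
`M ≥ lcr·LM − U(1−W)`, `M ≤ U·W` with the tuple-specific bound
`U = lcr · UB(LM)`, where `UB(LM)` is the largest first-step calibration
load of that protein (ratios sum to ≤ 1, so the bound propagates
unchanged down the chain).

The purity requirement is kept in mass form, `CM[last,dp] ≥ ε·Σ_p
CM[last,p]`, so the constraint stays linear and an ε of 1 is expressible.

### Relaxations and tightening

`W` is declared continuous in `[0,1]`: the gates force it to exactly
`X · Z` once `X` and `Z` are binary, so no integrality is lost, and the
solver branches on far fewer variables.  Two redundant-but-tightening row
families are added: per-tuple `W ≤ Z` and per-(step, protein) `CM ≤ LM`
(mass conservation).  Both are implied for integer solutions and only
strengthen the LP relaxation; on the full-scale synthetic campaign they
reduce one MILP solve from minutes to seconds.  The MILP backend is HiGHS
(via `scipy.optimize.milp`) with relative and absolute optimality gaps of
0 and a MIP feasibility tolerance of 1e-7 (one decade below the stock
1e-6; tighter settings made this HiGHS build declare large feasible
instances infeasible).  Feasibility within solver tolerances is never
taken on faith: every returned decision is re-evaluated by exact forward
simulation, and exactly-infeasible knife-edge points are excluded with
no-good cuts (below).  Separately, the HiGHS build shipped with scipy
1.17 was observed losing integer incumbents while mapping them back
through presolve and then reporting a suboptimal point as optimal at 0%
gap; solves whose optimality the algorithm relies on therefore run with
presolve disabled (see below).

## Fractional objective: Dinkelbach iterations

For a fixed purity floor ε, maximizing `Y = CM/LM` over the mixed-integer
polytope is a linear-fractional program.  Dinkelbach's scheme solves
`max CM − f·LM` for a parameter `f ≥ 0`; at the optimum the residual
`CM* − f·LM*` is zero exactly when `f` equals the maximal ratio.
The update `f ← CM*/LM*` produces a strictly increasing `f` sequence with
non-negative, non-increasing residuals, terminating finitely on the
finite decision space.  The start value is warm: for one- and two-step
campaigns a vectorized enumeration of all (condition, window) options
(window sums by prefix sums, steps crossed by array broadcasting, the
salt-linking rule as a mask) finds the best exactly-feasible decision in
well under a second even at full scale, and its ratio — a valid lower
bound on the optimum — seeds `f` and the incumbent, so the first MILP
typically certifies convergence outright.  Where no warm start is
available (more steps, oversized enumeration, or an infeasible-looking
floor) the iterations start from `f = 0`, whose MILP maximizes collected
target mass and is feasible whenever anything is.  Defaults:
absolute residual tolerance `δ = 1e-6` mg, iteration cap 50 with an
explicit non-convergence status (never a silent answer).  The denominator
is always positive because loaded masses are required positive.  Returned
metrics are recomputed by forward simulation of the extracted decision,
never read from solver variable values, and the purity floor is re-checked
on those exact masses before a point may become the incumbent or update
`f` — solver feasibility tolerances cannot smuggle an infeasible
knife-edge point into the answer.  When the solver's optimum *is* such an
exactly-infeasible point and the residual has not yet converged, that
single decision is excluded by a no-good cut (the sum of its selection
binaries is bounded below 3 per step) and the MILP re-solved at the same
`f`; cutting an exactly-infeasible decision can never remove a truly
feasible one, and the decision space is finite, so this terminates.
Conversely a converged residual is accepted even from such a point: the
solver optimum over the tolerance-relaxed feasible set upper-bounds the
exact optimum.

The iterations use a hybrid presolve strategy around the HiGHS defect
noted above.  When no warm start is available, the first MILP runs with
presolve on and the stock feasibility tolerance: it is fast and its
result is used only to *seed* `f` and the incumbent (both are safe — an
exactly-feasible point's ratio is a valid lower bound on the optimum).
Every subsequent iteration (and every iteration after a warm start) runs
with presolve off, and convergence or infeasibility is only ever declared
on such a trusted solve.  Trusted iterations also carry a valid
acceleration row `CM − f·LM ≥ 0`: the incumbent achieving ratio `f` has
objective exactly zero, so the optimum of the parametric MILP is
non-negative and the row prunes without cutting any optimal solution
(rows from earlier, smaller `f` are implied and harmless).  If a trusted
solve reports infeasibility while an incumbent exists (possible once the
bound row or no-good cuts are present), nothing feasible beats the
incumbent's ratio, and it is returned as the converged optimum.  The best
exactly-feasible incumbent is kept across iterations, so a final MILP
returning a merely near-optimal point (residual ≤ δ, possibly negative)
cannot displace a better earlier decision.

When every first-step experiment loaded the same target mass the
denominator is constant and one MILP suffices (`solve_direct_milp`); it is
kept as an independent cross-check of the iterative route.

## Pareto frontier

The bi-objective problem is scalarized by the ε-constraint method: yield
is maximized once per purity floor on a grid, by default 90% to 99% in
steps of 1% (ten fractional solves).  An optimal-but-not-unique solution
at some ε is only weakly Pareto-optimal, and the solver cannot certify
uniqueness, so all swept points are post-filtered for componentwise
dominance (exact duplicates collapse to one).  The filter sorts by yield
and keeps strict purity improvements — O(n log n), verified against a
quadratic brute-force filter.  Feasibility of each returned point
(`P ≥ ε`) and frontier monotonicity (purity up ⇒ yield down) are asserted
rather than assumed.

Infeasible floors are recorded and skipped; floors whose optimum collects
nothing (possible when a window holds no mass at all) are reported as
degenerate rather than turned into points, because purity is undefined on
an empty pool.

## Exhaustive oracle

The decision space is finite: per step, (conditions) × (ordered interval
pairs), filtered across steps by the salt-linking rule.  On small
instances everything is enumerated and evaluated by the same forward
simulation (via per-condition prefix sums), giving exact optima and exact
Pareto sets with no pruning — deliberately trivial so it can serve as the
reference for the MILP route.  The enumeration budget defaults to 5·10⁶
decisions and aborts loudly beyond it; a full-scale campaign (~3·10⁷
decisions) exceeds it by design, the oracle is for reduced instances.
Feasibility at a floor uses the same mass-form inequality as the MILP so
the two routes agree on edge cases.  Ties are broken lexicographically.

## Synthetic screening data

The generator emulates the structure of an industrial two-step campaign —
cation exchange (8 resins × 2 conditions, 17 intervals, NaCl 0→300 mM)
into mixed mode (3 resins × 7/8/12 conditions, 29 intervals, NaCl
0→1000 mM with a regeneration tail) — with a three-species feed of 86.2%
target monomer, 10.6% aggregate and 3.2% fragment.

Model and defaults (all per-spec overridable):

- **Total load 10 mg** per microscale experiment — a realistic column
  load for ~600 µL robotic screening columns;
- **Elution**: each species leaves the column as a Gaussian band in
  eluent salt, discretized onto the elution intervals via the schedule's
  effective salt and normalized so the recovered fraction of the load is
  exactly the **recovery** (default 0.95);
- **Flow-through** (default 0.02 of the load) spread uniformly over
  load/wash intervals;
- **Band centers/widths**: per-protein means (e.g. monomer 150 mM,
  aggregate 230 mM, fragment 70 mM on the 0–300 mM step; widths ~40 mM),
  perturbed multiplicatively per (resin, condition) with ~5% lognormal
  jitter so no condition dominates by construction;
- **Effective salt** for intervals without a stated concentration: 0 mM
  during load/wash (the gradient has not started), carry-forward of the
  last elution value during regeneration — this also makes load-phase
  start cut-points orderable in the salt-linking rule.

A `separability_knob` re-centers impurity bands a chosen distance from
the target's (congruent widths): at distance 0 all species co-elute and no
pooling can beat the feed's target fraction; larger distances weakly
increase the attainable purity.  These closed-form anchors are asserted in
the tests.

What the generator does **not** emulate: column overloading and
displacement (the constant-ratio assumption is true by construction here,
whereas real data can violate it), quantification noise, pH effects,
inter-protein competition, and host-cell impurities.  Passing tests
therefore demonstrate the correctness of the optimization machinery on
structurally faithful data, not the biological validity of the
constant-ratio assumption itself.

## Problem sizes and numerical choices

- Oracle-versus-solver equivalence runs on 25 seeded campaigns of 2 steps,
  2 resins × 2 conditions and 8 intervals per step (~10⁴ decisions each),
  at purity floors {0, 0.90, 0.95, 0.99}, with agreement required to 1e-9
  on yield.
- Constraint-semantics checks fix every cut-point/condition assignment
  exhaustively on a 2-step, T = 4 instance (512 MILP feasibility solves).
- The full-scale synthetic campaign is solved integrated (two steps) as a
  single fractional program per floor; with the tightened formulation,
  the warm start and the acceleration row, one solve is dominated by a
  single proving MILP and takes on the order of 20–30 s at mid-grid
  floors (longer at 99%, where the purity constraint makes the MILP
  hardest).
- Ties among alternate optima are accepted as returned by the solver and
  resolved by the dominance filter; the oracle breaks ties
  lexicographically.  Comparisons between the two routes are therefore on
  criteria values, never on decision identity.
- Salt-linking comparisons use an absolute slack of 1e-9 mM to guard
  against float noise in effective-salt arithmetic.

## Known limitations

- The constant-ratio assumption is inherited from the screening-data
  setting; no attempt is made to detect or correct its violation.
- Only yield and purity are modelled; cost, productivity, buffer
  consumption and step count are out of scope.
- One condition per step and a single contiguous pooling window; no
  recycle streams or parallel pools.
- The ε grid is static; no adaptive refinement of the frontier.
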