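# resinopt

Optimization-based decision support for downstream bioprocess development:
given high-throughput screening (HTS) data from microscale chromatography
experiments, **resinopt** selects the resin, operating condition and
elution pooling cut-points of every step in a (possibly multi-step)
protein purification sequence, and traces the full yield–purity
Pareto frontier.

It is written for purification process development scientists who run
robotic resin screens (many resins × operating conditions per step, with
per-time-interval fraction analysis) and need to turn those tables into
an integrated, defensible choice of process — rather than picking the
best single-step result by eye.

## The model in brief

For each step *s* the data give, per resin *r*, condition *c* and protein
species *p*, the loaded mass `lm` and the collected mass `cm[t]` in each
time interval *t* of a salt-gradient elution.  Decision variables select
one `(r, c)` per step and one contiguous pooling window
`[start, finish]`.  Two criteria are evaluated for the target protein
*dp*:

```
Yield   Y = CM[last, dp] / LM[first, dp]
Purity  P = CM[last, dp] / Σ_p CM[last, p]
```

First-step masses come straight from the experiment; later steps are
predicted with the constant load-collection-ratio assumption
`M[s,r,c,p,t] = (cm/lm) · LM[s,p]`, chained by `LM[s+1,p] = CM[s,p]` and
constrained so the eluent salt never decreases from one step's finish
cut-point to the next step's start.  For a fixed purity floor ε the
problem `max Y s.t. P ≥ ε` is a mixed-integer linear *fractional*
program; it is solved exactly by Dinkelbach's algorithm (a sequence of
MILPs `max CM − f·LM`, updating `f ← CM*/LM*` until the residual
vanishes), with HiGHS as the MILP backend at 0% optimality gap.
Sweeping ε (default 90–99% in 1% steps) and filtering for dominance
yields the Pareto frontier.

An exhaustive enumeration oracle (`resinopt oracle`, for small
instances) provides exact reference optima, and a seeded synthetic-data
generator emulates the structure of an industrial two-step campaign —
cation exchange (8 resins × 2 conditions, 17 intervals, 0→300 mM NaCl)
into mixed mode (3 resins × 7/8/12 conditions, 29 intervals, 0→1000 mM)
with a feed of 86.2% monomer, 10.6% aggregates, 3.2% fragments — so the
whole pipeline is testable without proprietary data.

See `docs/methods.md` for the full formulation, assumptions and
numerical choices.

## Worked example

Generate a small synthetic two-step campaign, optimize the integrated
process over the default purity-floor grid, and render the solutions:

```
resinopt simulate --preset toy --seed 7 --out data/
resinopt validate data/
resinopt optimize data/ --mode integrated --out run/
resinopt report run/pareto.csv
```

`validate` prints the campaign shape:

```
step S1: 2 resins, 4 conditions, 8 intervals
step S2: 2 resins, 4 conditions, 8 intervals
proteins: monomer, aggregate, fragment (target: monomer)
OK
```

and `report` the dominance-filtered frontier (one block per solution,
one row per step):

```
Solution  Step    Resin     Condition   Collection window                            Yield  Purity
--------------------------------------------------------------------------------------------------
S1        S1      RS12      CS12-2      Elution (181.255-302.092 mM NaCl): T5-T7     36.5%   94.8%
          S2      RS22      CS22-1      Elution (344.861-689.721 mM NaCl): T5-T8
S2        S1      RS12      CS12-2      Elution (181.255-302.092 mM NaCl): T5-T7     35.7%   95.1%
          S2      RS22      CS22-1      Elution (344.861-574.768 mM NaCl): T5-T7
S3        S1      RS12      CS12-1      Elution (241.673-302.092 mM NaCl): T6-T7     32.4%   98.3%
          S2      RS22      CS22-1      Elution (344.861-689.721 mM NaCl): T5-T8
S4        S1      RS11      CS11-1      Elution (241.673-302.092 mM NaCl): T6-T7     27.5%   99.1%
          S2      RS21      CS21-1      Elution (344.861-459.814 mM NaCl): T5-T6
```

Reading S1 (the highest-yield solution): run condition CS12-2 of resin
RS12 at the first step and pool fractions T5–T7 (eluting between 181 and
302 mM NaCl), feed the pool to resin RS22 under CS22-1 and pool T5–T8;
the model predicts 36.5% of the loaded monomer recovered at 94.8%
purity.  Tightening the purity floor trades yield for purity down the
table — the characteristic shape of the frontier.  `run/pareto.csv`
holds the same data in machine-readable form and `run/run_log.json` the
per-ε Dinkelbach traces (typically a single certifying MILP per floor,
thanks to an enumerative warm start).

The library API mirrors the CLI:

```python
import resinopt as ro

ds = ro.generate(ro.random_spec(7))       # or ro.load_dataset("data/")
rt = ro.compute_ratios(ds)
front = ro.sweep(ds, rt)                  # default 90..99% grid
for pt in front.points:
    print(f"eps={pt.eps:.2f}  Y={pt.yield_:.3f}  P={pt.purity:.3f}")
```

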