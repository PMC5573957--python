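"""Mixed-integer constraint system for resin selection and pooling cut-points.

The decision space per chromatographic step is: which (resin, operating
condition) to run, and between which two time intervals to pool the
eluate.  Binary variables encode the choice (``Z``), the start/finish
cut-points (``Xs``/``Xf``), the per-interval selection flag ``X`` obtained
from the cut-points by a first-order recursion, and the joint indicator
``W = X * Z`` linearized with big-M rows.  Continuous variables carry the
mass balance: loaded mass per protein ``LM``, collected mass per
(resin, condition, protein, interval) ``M``, and the per-step total ``CM``
that becomes the next step's load.

At the first step the loaded and collected masses are the calibration
experiment's own numbers.  At later steps the collected mass is predicted
by the constant load-collection-ratio assumption, ``M = lcr * LM``,
enforced only on selected tuples via big-M rows.  Consecutive steps are
linked by requiring the eluent salt concentration at the previous step's
finish cut-point to not exceed that at the next step's start cut-point.

The fractional yield objective is handled outside this module: the model
carries the linearized objective ``CM[last, target] - f * LM[first, target]``
for a given parameter ``f`` (see :mod:`resinopt.fractional_solver`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .backend import LinearModel
from .hts_data import HTSDataset, RatioTable

__all__ = ["BigMPolicy", "ChromatographyModel", "build_model", "default_bigM"]


@dataclass(frozen=True)
class BigMPolicy:
    """Big-M bounds, chosen so every bound dominates the quantity it relaxes.

    ``window_gate`` bounds the number of joint indicators active in one
    interval (1, since exactly one condition is selected per step);
    ``condition_gate`` bounds the number of intervals selectable under one
    condition (the step's interval count); ``lm_upper[(s, p)]`` is an upper
    bound on the loaded mass of protein ``p`` entering step ``s``, from
    which the per-tuple bound on predicted collected mass follows as
    ``lcr * lm_upper``.
    """

    window_gate: float
    condition_gate: Mapping[str, float]
    lm_upper: Mapping[tuple[str, str], float]

    def mass_bound(
        self, rt: RatioTable, s: str, r: str, c: str, p: str, t: int
    ) -> float:
        return rt.get(s, r, c, p, t) * self.lm_upper[(s, p)]


def default_bigM(ds: HTSDataset, rt: RatioTable) -> BigMPolicy:
    """Tightest simple bounds implied by mass conservation.

    The first-step load is bounded by the largest calibration load over the
    step's conditions; because per-condition ratios sum to at most 1, that
    bound propagates unchanged to every later step.
    """
    lm_upper: dict[tuple[str, str], float] = {}
    fs = ds.first_step
    for p in ds.proteins:
        ub = max(
            ds.records[(fs, r, c)].loaded_mass[p] for r, c in ds.step_conditions(fs)
        )
        lm_upper[(fs, p)] = ub
    for prev, s in zip(ds.steps, ds.steps[1:]):
        for p in ds.proteins:
            lm_upper[(s, p)] = lm_upper[(prev, p)]
    return BigMPolicy(
        window_gate=1.0,
        condition_gate={s: float(ds.n_intervals(s)) for s in ds.steps},
        lm_upper=lm_upper,
    )


@dataclass
class ChromatographyModel:
    """A built MILP plus the variable-index maps needed to read solutions."""

    model: LinearModel
    ds: HTSDataset
    eps: float
    f: float
    z: dict[tuple[str, str, str], int]
    xs: dict[tuple[str, int], int]
    xf: dict[tuple[str, int], int]
    x: dict[tuple[str, int], int]
    w: dict[tuple[str, str, str, int], int]
    lm: dict[tuple[str, str], int]
    m: dict[tuple[str, str, str, str, int], int]
    cm: dict[tuple[str, str], int]

    def set_fraction_parameter(self, f: float) -> None:
        """Re-point the linear objective at a new fractional parameter ``f``."""
        if f < 0:
            raise ValueError(f"fractional parameter must be >= 0, got {f}")
        self.f = f
        ds = self.ds
        obj = {
            self.cm[(ds.last_step, ds.target_protein)]: 1.0,
            self.lm[(ds.first_step, ds.target_protein)]: -f,
        }
        self.model.set_objective(obj, maximize=True)


def build_model(
    ds: HTSDataset,
    rt: RatioTable,
    eps: float,
    f: float = 0.0,
    policy: BigMPolicy | None = None,
) -> ChromatographyModel:
    """Construct the full constraint system with purity floor ``eps``.

    ``eps`` is the minimum target-protein purity, written in mass form
    (collected target mass >= eps * total collected mass) so the model stays
    linear.  The objective is ``CM[last, target] - f * LM[first, target]``,
    maximized.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"purity floor eps must lie in [0, 1], got {eps}")
    if f < 0:
        raise ValueError(f"fractional parameter must be >= 0, got {f}")
    if policy is None:
        policy = default_bigM(ds, rt)

    md = LinearModel()
    fs, ls = ds.first_step, ds.last_step
    dp = ds.target_protein
    p_index = {p: i for i, p in enumerate(ds.proteins)}

    z: dict[tuple[str, str, str], int] = {}
    xs: dict[tuple[str, int], int] = {}
    xf: dict[tuple[str, int], int] = {}
    x: dict[tuple[str, int], int] = {}
    w: dict[tuple[str, str, str, int], int] = {}
    lm_v: dict[tuple[str, str], int] = {}
    m_v: dict[tuple[str, str, str, str, int], int] = {}
    cm_v: dict[tuple[str, str], int] = {}

    for s in ds.steps:
        T = ds.n_intervals(s)
        for r, c in ds.step_conditions(s):
            z[(s, r, c)] = md.add_binary(f"Z[{s},{r},{c}]")
        for t in range(1, T + 1):
            xs[(s, t)] = md.add_binary(f"Xs[{s},{t}]")
            xf[(s, t)] = md.add_binary(f"Xf[{s},{t}]")
            x[(s, t)] = md.add_binary(f"X[{s},{t}]")
        for r, c in ds.step_conditions(s):
            for t in range(1, T + 1):
                # W = X * Z is fully determined by the gating rows once X and
                # Z are binary, so W can stay continuous in [0, 1]; it still
                # takes only the values 0 and 1 in every feasible solution
                w[(s, r, c, t)] = md.add_continuous(f"W[{s},{r},{c},{t}]", 0.0, 1.0)
        for p in ds.proteins:
            lm_v[(s, p)] = md.add_continuous(
                f"LM[{s},{p}]", 0.0, policy.lm_upper[(s, p)]
            )
            cm_v[(s, p)] = md.add_continuous(
                f"CM[{s},{p}]", 0.0, policy.lm_upper[(s, p)]
            )
        for r, c in ds.step_conditions(s):
            rec = ds.records[(s, r, c)]
            cm_arr = rec.collected_array(ds.proteins, T)
            for p in ds.proteins:
                for t in range(1, T + 1):
                    if s == fs:
                        ub = float(cm_arr[p_index[p], t - 1])
                    else:
                        ub = policy.mass_bound(rt, s, r, c, p, t)
                    m_v[(s, r, c, p, t)] = md.add_continuous(
                        f"M[{s},{r},{c},{p},{t}]", 0.0, ub
                    )

    # exactly one condition and one start/finish cut-point per step
    for s in ds.steps:
        T = ds.n_intervals(s)
        md.add_constraint(
            [(z[(s, r, c)], 1.0) for r, c in ds.step_conditions(s)],
            "=", 1.0, family="one_condition",
        )
        md.add_constraint(
            [(xs[(s, t)], 1.0) for t in range(1, T + 1)], "=", 1.0,
            family="one_start",
        )
        md.add_constraint(
            [(xf[(s, t)], 1.0) for t in range(1, T + 1)], "=", 1.0,
            family="one_finish",
        )
        # selected-interval recursion: X_t = X_{t-1} + Xs_t - Xf_{t-1};
        # the start-marked interval is included, the finish-marked is the last
        for t in range(1, T + 1):
            terms = [(x[(s, t)], 1.0), (xs[(s, t)], -1.0)]
            if t > 1:
                terms += [(x[(s, t - 1)], -1.0), (xf[(s, t - 1)], 1.0)]
            md.add_constraint(terms, "=", 0.0, family="window_recursion")
        # the recursion alone admits one spurious solution per window position
        # (finish cut-point directly before the start, selecting nothing);
        # an explicit ordering row excludes the empty window
        md.add_constraint(
            [(xs[(s, t)], float(t)) for t in range(1, T + 1)]
            + [(xf[(s, t)], -float(t)) for t in range(1, T + 1)],
            "<=", 0.0, family="window_order",
        )

    # joint indicator W = X * Z, linearized
    for s in ds.steps:
        T = ds.n_intervals(s)
        pairs = ds.step_conditions(s)
        for t in range(1, T + 1):
            md.add_constraint(
                [(w[(s, r, c, t)], 1.0) for r, c in pairs]
                + [(x[(s, t)], -policy.window_gate)],
                "<=", 0.0, family="window_gate",
            )
        for r, c in pairs:
            md.add_constraint(
                [(w[(s, r, c, t)], 1.0) for t in range(1, T + 1)]
                + [(z[(s, r, c)], -policy.condition_gate[s])],
                "<=", 0.0, family="condition_gate",
            )
            for t in range(1, T + 1):
                md.add_constraint(
                    [(w[(s, r, c, t)], 1.0), (x[(s, t)], -1.0), (z[(s, r, c)], -1.0)],
                    ">=", -1.0, family="joint_lower",
                )
                # redundant for integer solutions (implied by the aggregated
                # condition gate) but tightens the LP relaxation substantially
                md.add_constraint(
                    [(w[(s, r, c, t)], 1.0), (z[(s, r, c)], -1.0)],
                    "<=", 0.0, family="tighten_wz",
                )

    # first step: masses are the calibration experiment's own numbers
    for p in ds.proteins:
        md.add_constraint(
            [(lm_v[(fs, p)], 1.0)]
            + [
                (z[(fs, r, c)], -ds.records[(fs, r, c)].loaded_mass[p])
                for r, c in ds.step_conditions(fs)
            ],
            "=", 0.0, family="first_load",
        )
    for r, c in ds.step_conditions(fs):
        cm_arr = ds.records[(fs, r, c)].collected_array(
            ds.proteins, ds.n_intervals(fs)
        )
        for p in ds.proteins:
            for t in range(1, ds.n_intervals(fs) + 1):
                md.add_constraint(
                    [
                        (m_v[(fs, r, c, p, t)], 1.0),
                        (w[(fs, r, c, t)], -float(cm_arr[p_index[p], t - 1])),
                    ],
                    "=", 0.0, family="first_collect",
                )

    # per-step totals and the chain load
    for s in ds.steps:
        T = ds.n_intervals(s)
        for p in ds.proteins:
            md.add_constraint(
                [(cm_v[(s, p)], 1.0)]
                + [
                    (m_v[(s, r, c, p, t)], -1.0)
                    for r, c in ds.step_conditions(s)
                    for t in range(1, T + 1)
                ],
                "=", 0.0, family="total_collected",
            )
    for prev, s in zip(ds.steps, ds.steps[1:]):
        for p in ds.proteins:
            md.add_constraint(
                [(lm_v[(s, p)], 1.0), (cm_v[(prev, p)], -1.0)],
                "=", 0.0, family="chain_load",
            )

    # later steps: constant-ratio mass prediction, active on selected tuples
    for s in ds.steps[1:]:
        T = ds.n_intervals(s)
        for r, c in ds.step_conditions(s):
            lcr = rt.ratio[(s, r, c)]
            for p in ds.proteins:
                for t in range(1, T + 1):
                    ratio = float(lcr[p_index[p], t - 1])
                    U = policy.mass_bound(rt, s, r, c, p, t)
                    mi = m_v[(s, r, c, p, t)]
                    md.add_constraint(
                        [(mi, 1.0), (lm_v[(s, p)], -ratio)],
                        "<=", 0.0, family="ratio_upper",
                    )
                    md.add_constraint(
                        [(mi, 1.0), (lm_v[(s, p)], -ratio), (w[(s, r, c, t)], -U)],
                        ">=", -U, family="ratio_lower",
                    )
                    md.add_constraint(
                        [(mi, 1.0), (w[(s, r, c, t)], -U)],
                        "<=", 0.0, family="selection_gate",
                    )

    # non-decreasing eluent salt across consecutive steps
    for prev, s in zip(ds.steps, ds.steps[1:]):
        sc_prev = ds.effective_salt(prev)
        sc_s = ds.effective_salt(s)
        md.add_constraint(
            [(xf[(prev, t)], float(sc_prev[t - 1]))
             for t in range(1, ds.n_intervals(prev) + 1)]
            + [(xs[(s, t)], -float(sc_s[t - 1]))
               for t in range(1, ds.n_intervals(s) + 1)],
            "<=", 0.0, family="salt_link",
        )

    # mass conservation CM <= LM per step and protein: implied by the ratio
    # rows (per-condition ratios sum to <= 1) but a strong LP-level bound
    for s in ds.steps:
        for p in ds.proteins:
            md.add_constraint(
                [(cm_v[(s, p)], 1.0), (lm_v[(s, p)], -1.0)],
                "<=", 0.0, family="tighten_conservation",
            )

    # purity floor in mass form: CM[ls, dp] >= eps * sum_p CM[ls, p]
    md.add_constraint(
        [(cm_v[(ls, dp)], 1.0 - eps)]
        + [(cm_v[(ls, p)], -eps) for p in ds.proteins if p != dp],
        ">=", 0.0, family="purity_floor",
    )

    cm_model = ChromatographyModel(
        model=md, ds=ds, eps=eps, f=f,
        z=z, xs=xs, xf=xf, x=x, w=w, lm=lm_v, m=m_v, cm=cm_v,
    )
    cm_model.set_fraction_parameter(f)
    return cm_model
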