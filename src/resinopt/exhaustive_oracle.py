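"""Brute-force enumeration of the finite decision space.

Per step the choices are one (resin, condition) pair and one pooling
window ``start <= finish``; across steps only salt-compatible window
combinations survive.  The space is finite, so small instances can be
solved exactly by enumeration — this module exists purely to verify the
optimizer and must stay trivially correct (no pruning, no bounding).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .fractional_solver import SolutionMetrics, StepDecision, ProcessDecision
from .hts_data import HTSDataset, RatioTable
from .pareto_engine import pareto_maxima

__all__ = [
    "EnumerationBudget",
    "BudgetExceededError",
    "enumerate_decisions",
    "evaluate_all",
    "oracle_max_yield",
    "oracle_pareto",
]

_FEAS_TOL = 1e-9


class BudgetExceededError(RuntimeError):
    """The decision space is larger than the enumeration budget allows."""


@dataclass(frozen=True)
class EnumerationBudget:
    """Hard cap on the number of enumerated decisions (loud abort beyond it)."""

    max_decisions: int = 5_000_000

    def __post_init__(self) -> None:
        if self.max_decisions < 1:
            raise ValueError("max_decisions must be positive")


def _step_choices(ds: HTSDataset, s: str) -> list[StepDecision]:
    T = ds.n_intervals(s)
    return [
        StepDecision(step=s, resin=r, condition=c, start=t1, finish=t2)
        for r, c in ds.step_conditions(s)
        for t1 in range(1, T + 1)
        for t2 in range(t1, T + 1)
    ]


def enumerate_decisions(
    ds: HTSDataset, budget: EnumerationBudget | None = None
) -> Iterator[ProcessDecision]:
    """Yield every salt-compatible complete decision exactly once.

    Order is lexicographic by step over (resin, condition, start, finish)
    in dataset declaration order.  Raises :class:`BudgetExceededError` as
    soon as the count would exceed the budget.
    """
    budget = budget or EnumerationBudget()
    per_step = [_step_choices(ds, s) for s in ds.steps]
    salts = {s: ds.effective_salt(s) for s in ds.steps}
    count = 0
    for combo in itertools.product(*per_step):
        ok = True
        for prev, d in zip(combo, combo[1:]):
            if salts[prev.step][prev.finish - 1] > salts[d.step][d.start - 1] + _FEAS_TOL:
                ok = False
                break
        if not ok:
            continue
        count += 1
        if count > budget.max_decisions:
            raise BudgetExceededError(
                f"decision space exceeds the enumeration budget of "
                f"{budget.max_decisions} decisions"
            )
        yield combo


def evaluate_all(
    ds: HTSDataset, rt: RatioTable, budget: EnumerationBudget | None = None
) -> list[tuple[ProcessDecision, float, float, float]]:
    """Every feasible decision with (yield, collected target mass, total
    collected mass) at the last step.

    The mass chain is evaluated with per-condition prefix sums of the ratio
    table, which is exact and fast enough for verification-sized instances.
    """
    # prefix[s, r, c][p, t] = sum of ratios over intervals 1..t (t 0 = 0)
    prefix = {
        key: np.concatenate(
            [np.zeros((len(ds.proteins), 1)), np.cumsum(arr, axis=1)], axis=1
        )
        for key, arr in rt.ratio.items()
    }
    fs = ds.first_step
    dp_i = ds.proteins.index(ds.target_protein)
    out = []
    for combo in enumerate_decisions(ds, budget):
        first = combo[0]
        rec = ds.records[(fs, first.resin, first.condition)]
        lm0 = rec.loaded_array(ds.proteins)
        pre = prefix[(fs, first.resin, first.condition)]
        carry = lm0 * (pre[:, first.finish] - pre[:, first.start - 1])
        for d in combo[1:]:
            pre = prefix[(d.step, d.resin, d.condition)]
            carry = carry * (pre[:, d.finish] - pre[:, d.start - 1])
        y = carry[dp_i] / lm0[dp_i]
        out.append((combo, float(y), float(carry[dp_i]), float(carry.sum())))
    return out


def oracle_max_yield(
    ds: HTSDataset,
    rt: RatioTable,
    eps: float,
    budget: EnumerationBudget | None = None,
    evaluated: list[tuple[ProcessDecision, float, float, float]] | None = None,
) -> tuple[ProcessDecision, SolutionMetrics] | None:
    """Exact yield maximizer at purity floor ``eps``, or ``None`` if no
    decision meets the floor.

    Feasibility uses the same mass-form inequality as the optimizer
    (collected target mass >= eps * total collected).  Ties are broken by
    enumeration order, i.e. lexicographically.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    if evaluated is None:
        evaluated = evaluate_all(ds, rt, budget)
    best = None
    best_y = -np.inf
    for combo, y, cm_dp, cm_total in evaluated:
        if cm_dp < eps * cm_total - _FEAS_TOL * max(1.0, cm_total):
            continue
        if y > best_y:
            best, best_y = combo, y
    if best is None:
        return None
    from .fractional_solver import evaluate_decision

    return best, evaluate_decision(ds, rt, best)


def oracle_pareto(
    ds: HTSDataset,
    rt: RatioTable,
    budget: EnumerationBudget | None = None,
    evaluated: list[tuple[ProcessDecision, float, float, float]] | None = None,
) -> list[tuple[ProcessDecision, float, float]]:
    """Exact Pareto set of (yield, purity) over all enumerable decisions.

    Decisions that collect nothing have no defined purity and are excluded.
    Returns (decision, yield, purity) sorted by purity ascending.
    """
    if evaluated is None:
        evaluated = evaluate_all(ds, rt, budget)
    usable = [
        (combo, y, cm_dp / cm_total)
        for combo, y, cm_dp, cm_total in evaluated
        if cm_total > 0
    ]
    idx = pareto_maxima([u[1] for u in usable], [u[2] for u in usable])
    return [usable[i] for i in idx]
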