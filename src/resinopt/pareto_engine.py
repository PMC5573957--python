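"""Yield-purity Pareto frontier by an epsilon-constraint sweep.

Purity is converted into a floor constraint and yield maximized once per
floor value; the resulting points are post-filtered for Pareto dominance
because an optimizer cannot certify uniqueness of each epsilon-solution
(an optimal but non-unique solution is only weakly Pareto-optimal).  The
default grid raises the floor from 90% to 99% in steps of 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fractional_solver import (
    DinkelbachTrace,
    ProcessDecision,
    SolverSettings,
    evaluate_decision,
    solve_milfp,
)
from .hts_data import HTSDataset, RatioTable, compute_ratios

__all__ = [
    "DEFAULT_EPS_GRID",
    "ParetoPoint",
    "ParetoFront",
    "sweep",
    "filter_dominated",
    "run_mode",
    "front_to_dataframe",
]

#: Purity floors 90%..99% in 1% steps.
DEFAULT_EPS_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.90, 0.9949, 0.01), 10)
)

_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class ParetoPoint:
    """One swept solution: the purity floor used, the decision and its metrics."""

    eps: float
    decision: ProcessDecision
    yield_: float
    purity: float
    trace: DinkelbachTrace


@dataclass(frozen=True)
class ParetoFront:
    """Nondominated points sorted by purity ascending (yield non-increasing).

    ``infeasible_eps`` lists grid values whose purity floor no decision can
    meet; ``degenerate_eps`` lists floors where the optimum collects nothing
    (zero yield, purity undefined) — both are diagnostics, not points.
    """

    points: tuple[ParetoPoint, ...]
    infeasible_eps: tuple[float, ...] = ()
    degenerate_eps: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.points)

    def pairs(self) -> list[tuple[float, float]]:
        return [(p.yield_, p.purity) for p in self.points]


def pareto_maxima(ys: Sequence[float], ps: Sequence[float]) -> list[int]:
    """Indices of the maximal elements under the componentwise (Y, P) order.

    Weakly dominated points and exact (Y, P) duplicates are dropped; among
    duplicates the earliest index wins.  Output is sorted by purity
    ascending, yield descending.
    """
    order = sorted(
        range(len(ys)), key=lambda i: (-ys[i], -ps[i], i)
    )
    keep: list[int] = []
    best_p = -np.inf
    for i in order:
        if ps[i] > best_p:
            keep.append(i)
            best_p = ps[i]
    keep.sort(key=lambda i: (ps[i], -ys[i]))
    return keep


def filter_dominated(points: Iterable[ParetoPoint]) -> ParetoFront:
    """Retain exactly the nondominated subset of ``points``, deterministically."""
    pts = list(points)
    idx = pareto_maxima([p.yield_ for p in pts], [p.purity for p in pts])
    return ParetoFront(points=tuple(pts[i] for i in idx))


def sweep(
    ds: HTSDataset,
    rt: RatioTable,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    settings: SolverSettings | None = None,
) -> ParetoFront:
    """One fractional solve per purity floor, then dominance filtering.

    Every returned point satisfies ``purity >= eps`` (to numerical
    tolerance); infeasible floors are recorded and skipped.
    """
    if len(eps_grid) == 0:
        raise ValueError("eps_grid must be non-empty")
    for e in eps_grid:
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"eps value {e} outside [0, 1]")
    candidates: list[ParetoPoint] = []
    infeasible: list[float] = []
    degenerate: list[float] = []
    for eps in eps_grid:
        result = solve_milfp(ds, rt, eps, settings)
        if result.status == "infeasible":
            infeasible.append(eps)
            continue
        if result.status != "converged":
            raise RuntimeError(
                f"fractional solve did not converge at eps={eps:g} "
                f"({result.status})"
            )
        m = result.metrics
        if m.purity is None:
            degenerate.append(eps)
            continue
        if m.purity < eps - _FEAS_TOL:
            raise AssertionError(
                f"solver returned purity {m.purity:.12f} below floor {eps:g}"
            )
        candidates.append(
            ParetoPoint(
                eps=eps, decision=result.decision,
                yield_=m.yield_, purity=m.purity, trace=result.trace,
            )
        )
    front = filter_dominated(candidates)
    return ParetoFront(
        points=front.points,
        infeasible_eps=tuple(infeasible),
        degenerate_eps=tuple(degenerate),
    )


def run_mode(
    ds: HTSDataset,
    mode: str,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    settings: SolverSettings | None = None,
) -> ParetoFront:
    """Sweep either one step in isolation or the integrated multi-step chain.

    ``mode`` is ``"integrated"`` or ``"single:<step_id>"``.  Single-step
    mode restricts the campaign to that step (it becomes both first and
    last, so no salt-linking constraint is active); integrated mode uses
    the full chain.
    """
    if mode == "integrated":
        sub = ds
    elif mode.startswith("single:"):
        step = mode.split(":", 1)[1]
        if step not in ds.steps:
            raise ValueError(f"unknown step {step!r}; campaign has {list(ds.steps)}")
        sub = ds.subset([step])
    else:
        raise ValueError(
            f"mode must be 'integrated' or 'single:<step>', got {mode!r}"
        )
    rt = compute_ratios(sub)
    return sweep(sub, rt, eps_grid, settings)


def front_to_dataframe(front: ParetoFront, ds: HTSDataset) -> pd.DataFrame:
    """Flatten a front to the canonical ``pareto.csv`` layout (one row per
    step of each solution)."""
    rows = []
    for sol_id, pt in enumerate(front.points, start=1):
        for d in pt.decision:
            salt = ds.effective_salt(d.step)
            rows.append(
                {
                    "solution": sol_id,
                    "eps": pt.eps,
                    "step": d.step,
                    "resin": d.resin,
                    "condition": d.condition,
                    "start_interval": f"T{d.start}",
                    "finish_interval": f"T{d.finish}",
                    "salt_start_mM": salt[d.start - 1],
                    "salt_finish_mM": salt[d.finish - 1],
                    "yield": pt.yield_,
                    "purity": pt.purity,
                    "dinkelbach_iterations": pt.trace.n_iterations,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "solution", "eps", "step", "resin", "condition",
            "start_interval", "finish_interval", "salt_start_mM",
            "salt_finish_mM", "yield", "purity", "dinkelbach_iterations",
        ],
    )
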