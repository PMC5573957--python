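"""Maximize chromatography yield at a purity floor via Dinkelbach iterations.

The yield objective is a ratio of two affine mass expressions — collected
target mass at the last step over loaded target mass at the first step —
so for a fixed purity floor the problem is a mixed-integer *linear
fractional* program.  Dinkelbach's algorithm solves it through a sequence
of plain MILPs: with parameter ``f``, maximize ``CM - f * LM``; if the
optimum is (near) zero, ``f`` equals the maximal ratio and the incumbent is
optimal, otherwise update ``f`` to the incumbent's ratio ``CM*/LM*`` and
repeat.  On maximization with a positive denominator the ``f`` iterates
increase monotonically and the scheme terminates finitely on a finite
decision space.

Solutions are returned as explicit decisions (resin, condition and
cut-points per step) with metrics recomputed by forward simulation —
never read back from solver variable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .hts_data import HTSDataset, RatioTable
from .model_builder import ChromatographyModel, build_model

__all__ = [
    "StepDecision",
    "ProcessDecision",
    "SolutionMetrics",
    "DinkelbachTrace",
    "SolverSettings",
    "MILFPResult",
    "solve_milfp",
    "solve_direct_milp",
    "evaluate_decision",
    "fixed_assignment",
]

_SALT_TOL = 1e-9


@dataclass(frozen=True)
class StepDecision:
    """Chosen resin, operating condition and pooling window of one step."""

    step: str
    resin: str
    condition: str
    start: int   # 1-based first pooled interval (inclusive)
    finish: int  # 1-based last pooled interval (inclusive)

    def __post_init__(self) -> None:
        if self.start < 1 or self.finish < self.start:
            raise ValueError(
                f"step {self.step!r}: invalid window T{self.start}-T{self.finish}"
            )


ProcessDecision = tuple[StepDecision, ...]


@dataclass(frozen=True)
class SolutionMetrics:
    """Mass flows and the two performance criteria of one decision.

    ``loaded[(s, p)]`` / ``collected[(s, p)]`` are per-step, per-protein
    masses in mg.  ``yield_`` is collected target mass at the last step
    over its load at the first step; ``purity`` is the target's share of
    everything collected at the last step, or ``None`` when nothing was
    collected at all.
    """

    loaded: dict[tuple[str, str], float]
    collected: dict[tuple[str, str], float]
    yield_: float
    purity: float | None

    @property
    def empty_collection(self) -> bool:
        return self.purity is None


@dataclass
class DinkelbachTrace:
    """Per-iteration record: (f, MILP objective value, incumbent yield)."""

    iterations: list[tuple[float, float, float]] = field(default_factory=list)
    terminal_status: Literal["converged", "infeasible", "iteration_limit"] = (
        "converged"
    )

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


@dataclass(frozen=True)
class SolverSettings:
    """Tunables of the fractional solve.

    ``delta`` is the absolute convergence tolerance on the Dinkelbach
    residual (mg); ``mip_gap`` is the MILP optimality gap, 0 by default so
    every MILP is solved to proven optimality.
    """

    delta: float = 1e-6
    max_iterations: int = 50
    mip_gap: float = 0.0
    time_limit: float | None = None
    feasibility_tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class MILFPResult:
    status: Literal["converged", "infeasible", "iteration_limit"]
    decision: ProcessDecision | None
    metrics: SolutionMetrics | None
    trace: DinkelbachTrace


class SolverFailure(RuntimeError):
    """The MILP backend stopped without a usable answer (e.g. time limit)."""


# -- forward simulation -------------------------------------------------------

def evaluate_decision(
    ds: HTSDataset, rt: RatioTable, decision: Sequence[StepDecision]
) -> SolutionMetrics:
    """Forward-simulate the mass balance of a complete decision.

    First-step masses are the calibration experiment's own numbers over the
    pooled window; later steps apply the constant load-collection ratios to
    the mass chained in from the previous step.  Raises ``ValueError`` on a
    decision violating the dataset (unknown condition, window out of range,
    or decreasing eluent salt between consecutive steps).
    """
    decision = tuple(decision)
    if tuple(d.step for d in decision) != ds.steps:
        raise ValueError(
            f"decision steps {[d.step for d in decision]} do not match the "
            f"campaign steps {list(ds.steps)}"
        )
    for d in decision:
        if (d.step, d.resin, d.condition) not in ds.records:
            raise ValueError(
                f"unknown condition step={d.step} resin={d.resin} "
                f"condition={d.condition}"
            )
        if d.finish > ds.n_intervals(d.step):
            raise ValueError(
                f"step {d.step!r}: window end T{d.finish} exceeds "
                f"T{ds.n_intervals(d.step)}"
            )
    for prev, d in zip(decision, decision[1:]):
        salt_out = ds.effective_salt(prev.step)[prev.finish - 1]
        salt_in = ds.effective_salt(d.step)[d.start - 1]
        if salt_out > salt_in + _SALT_TOL:
            raise ValueError(
                f"salt linking violated: step {prev.step!r} finishes at "
                f"{salt_out:g} mM but step {d.step!r} starts at {salt_in:g} mM"
            )

    loaded: dict[tuple[str, str], float] = {}
    collected: dict[tuple[str, str], float] = {}
    first = decision[0]
    rec = ds.records[(first.step, first.resin, first.condition)]
    lm_vec = rec.loaded_array(ds.proteins)
    cm_arr = rec.collected_array(ds.proteins, ds.n_intervals(first.step))
    cm_vec = cm_arr[:, first.start - 1 : first.finish].sum(axis=1)
    for i, p in enumerate(ds.proteins):
        loaded[(first.step, p)] = float(lm_vec[i])
        collected[(first.step, p)] = float(cm_vec[i])
    carry = cm_vec
    for d in decision[1:]:
        lm_vec = carry
        ratios = rt.window_sum(d.step, d.resin, d.condition, d.start, d.finish)
        cm_vec = lm_vec * ratios
        for i, p in enumerate(ds.proteins):
            loaded[(d.step, p)] = float(lm_vec[i])
            collected[(d.step, p)] = float(cm_vec[i])
        carry = cm_vec

    dp = ds.target_protein
    y = collected[(ds.last_step, dp)] / loaded[(ds.first_step, dp)]
    total = sum(collected[(ds.last_step, p)] for p in ds.proteins)
    purity = collected[(ds.last_step, dp)] / total if total > 0 else None
    return SolutionMetrics(
        loaded=loaded, collected=collected, yield_=y, purity=purity
    )


# -- decision extraction and fixing -------------------------------------------

def _extract_decision(cm_model: ChromatographyModel, values: np.ndarray) -> ProcessDecision:
    ds = cm_model.ds
    out = []
    for s in ds.steps:
        pairs = ds.step_conditions(s)
        zvals = [values[cm_model.z[(s, r, c)]] for r, c in pairs]
        r, c = pairs[int(np.argmax(zvals))]
        T = ds.n_intervals(s)
        start = 1 + int(
            np.argmax([values[cm_model.xs[(s, t)]] for t in range(1, T + 1)])
        )
        finish = 1 + int(
            np.argmax([values[cm_model.xf[(s, t)]] for t in range(1, T + 1)])
        )
        out.append(StepDecision(step=s, resin=r, condition=c,
                                start=start, finish=finish))
    return tuple(out)


def fixed_assignment(
    cm_model: ChromatographyModel, decision: Sequence[StepDecision]
) -> dict[int, float]:
    """Variable fixings pinning the selection binaries to a given decision.

    Only the choice variables (condition and cut-points) are fixed; the
    derived indicators and all mass variables stay free so a subsequent
    solve exercises the constraint system itself.
    """
    ds = cm_model.ds
    fixed: dict[int, float] = {}
    for d in decision:
        for r, c in ds.step_conditions(d.step):
            fixed[cm_model.z[(d.step, r, c)]] = (
                1.0 if (r, c) == (d.resin, d.condition) else 0.0
            )
        for t in range(1, ds.n_intervals(d.step) + 1):
            fixed[cm_model.xs[(d.step, t)]] = 1.0 if t == d.start else 0.0
            fixed[cm_model.xf[(d.step, t)]] = 1.0 if t == d.finish else 0.0
    return fixed


# -- solvers ------------------------------------------------------------------

_WARM_START_LIMIT = 200_000_000


def _window_table(
    ds: HTSDataset, rt: RatioTable, step: str, ratios: bool
) -> tuple[list[tuple[str, str, int, int]], np.ndarray, np.ndarray, np.ndarray]:
    """All (resin, condition, start, finish) options of one step.

    Returns the option list plus per-option window sums (mass if
    ``ratios`` is false, load-collection ratios otherwise, shape
    ``(n_options, n_proteins)``), start-interval salt and finish-interval
    salt.
    """
    T = ds.n_intervals(step)
    eff = np.asarray(ds.effective_salt(step), dtype=float)
    options: list[tuple[str, str, int, int]] = []
    sums: list[np.ndarray] = []
    salt_start: list[float] = []
    salt_finish: list[float] = []
    n_p = len(ds.proteins)
    for r, c in ds.step_conditions(step):
        if ratios:
            arr = rt.ratio[(step, r, c)]
        else:
            arr = ds.records[(step, r, c)].collected_array(ds.proteins, T)
        pre = np.concatenate(
            [np.zeros((n_p, 1)), np.cumsum(arr, axis=1)], axis=1
        )
        for s in range(1, T + 1):
            for f in range(s, T + 1):
                options.append((r, c, s, f))
                sums.append(pre[:, f] - pre[:, s - 1])
                salt_start.append(eff[s - 1])
                salt_finish.append(eff[f - 1])
    return (
        options,
        np.asarray(sums),
        np.asarray(salt_start),
        np.asarray(salt_finish),
    )


def _heuristic_incumbent(
    ds: HTSDataset, rt: RatioTable, eps: float
) -> tuple[ProcessDecision, SolutionMetrics] | None:
    """Best exactly-feasible decision by vectorized enumeration, or ``None``.

    A Dinkelbach warm start: any exactly-feasible decision's ratio is a
    valid lower bound on the optimum, so seeding ``f`` with a good one
    saves MILP iterations.  Implemented for one- and two-step campaigns
    (broadcast window sums across steps); larger campaigns and oversized
    enumeration spaces return ``None`` and the solver starts from f = 0.
    The candidate is re-validated by exact forward simulation before use.
    """
    if len(ds.steps) not in (1, 2):
        return None
    dp_i = ds.proteins.index(ds.target_protein)
    first = ds.first_step
    opt1, mass1, _, fin1 = _window_table(ds, rt, first, ratios=False)
    lm1 = np.array([
        ds.records[(first, r, c)].loaded_mass[ds.target_protein]
        for r, c, _s, _f in opt1
    ])
    if len(ds.steps) == 1:
        num = mass1[:, dp_i]
        tot = mass1.sum(axis=1)
        feas = num >= eps * tot - 1e-9 * np.maximum(1.0, tot)
        if not feas.any():
            return None
        y = np.where(feas, num / lm1, -np.inf)
        i = int(np.argmax(y))
        choice = [opt1[i]]
    else:
        second = ds.last_step
        opt2, ratio2, start2, _ = _window_table(ds, rt, second, ratios=True)
        if mass1.shape[0] * ratio2.shape[0] > _WARM_START_LIMIT:
            return None
        best_y = -np.inf
        best_ij: tuple[int, int] | None = None
        chunk = max(1, _WARM_START_LIMIT // (50 * ratio2.shape[0]))
        for lo in range(0, mass1.shape[0], chunk):
            hi = min(lo + chunk, mass1.shape[0])
            cm2 = mass1[lo:hi, None, :] * ratio2[None, :, :]
            num = cm2[:, :, dp_i]
            tot = cm2.sum(axis=2)
            feas = (num >= eps * tot - 1e-9 * np.maximum(1.0, tot)) & (
                start2[None, :] >= fin1[lo:hi, None] - _SALT_TOL
            )
            y = np.where(feas, num / lm1[lo:hi, None], -np.inf)
            j = int(np.argmax(y))
            if y.flat[j] > best_y:
                best_y = float(y.flat[j])
                best_ij = (lo + j // y.shape[1], j % y.shape[1])
        if best_ij is None or best_y == -np.inf:
            return None
        choice = [opt1[best_ij[0]], opt2[best_ij[1]]]
    decision = tuple(
        StepDecision(step=s, resin=r, condition=c, start=a, finish=b)
        for s, (r, c, a, b) in zip(ds.steps, choice)
    )
    try:
        metrics = evaluate_decision(ds, rt, decision)
    except ValueError:
        return None
    num = metrics.collected[(ds.last_step, ds.target_protein)]
    total = sum(metrics.collected[(ds.last_step, p)] for p in ds.proteins)
    if num < eps * total - 1e-9 * max(1.0, total):
        return None
    return decision, metrics


def _add_nogood_cut(
    cm_model: ChromatographyModel, decision: ProcessDecision
) -> None:
    """Exclude exactly one complete decision from the model.

    Used when the solver returns a decision that is feasible within its
    tolerances but violates a constraint in exact arithmetic; cutting it
    away can never remove a truly feasible decision.  Since exactly one
    condition, start and finish indicator is 1 per step, the decision is
    excluded by requiring their sum to drop below 3 per step.
    """
    terms = []
    for d in decision:
        terms.append((cm_model.z[(d.step, d.resin, d.condition)], 1.0))
        terms.append((cm_model.xs[(d.step, d.start)], 1.0))
        terms.append((cm_model.xf[(d.step, d.finish)], 1.0))
    cm_model.model.add_constraint(
        terms, "<=", 3.0 * len(decision) - 1.0, family="nogood"
    )


def solve_milfp(
    ds: HTSDataset,
    rt: RatioTable,
    eps: float,
    settings: SolverSettings | None = None,
) -> MILFPResult:
    """Maximize yield subject to purity >= ``eps`` by Dinkelbach's algorithm.

    Starts from the ratio of the best heuristically enumerated feasible
    decision when one is available (a valid lower bound on the optimum,
    so the first MILP often certifies convergence outright) and from
    ``f = 0`` otherwise, then iterates until the residual
    ``CM* - f * LM*`` drops to the tolerance ``delta``.  Returns an
    infeasible status when the purity floor is unattainable, and an
    explicit iteration-limit status rather than a silent answer if the
    cap is hit.
    """
    settings = settings or SolverSettings()
    cm_model = build_model(ds, rt, eps, f=0.0)
    trace = DinkelbachTrace()
    f = 0.0
    dp = ds.target_protein
    best: tuple[ProcessDecision, SolutionMetrics] | None = None
    # The first solve runs with solver presolve on and the stock feasibility
    # tolerance: fast, and only used to seed f and the incumbent (both safe,
    # every candidate is re-verified in exact arithmetic below).  Every later
    # solve — and every convergence or infeasibility verdict — uses a
    # presolve-off solve, which this HiGHS build handles reliably (see
    # backend.LinearModel.solve).
    trusted = False
    last_bound_f: float | None = None
    warm = _heuristic_incumbent(ds, rt, eps)
    if warm is not None:
        # an exactly-feasible warm start makes the untrusted MILP seed
        # unnecessary: go straight to trusted solves at its ratio
        best = warm
        f = warm[1].yield_
        trusted = True
    for _ in range(settings.max_iterations):
        cm_model.set_fraction_parameter(f)
        if trusted and f > 0 and f != last_bound_f:
            # valid acceleration: the incumbent achieving ratio f has
            # objective exactly 0, so the optimum of CM - f*LM is >= 0
            # (older rows with smaller f are implied and stay harmless)
            cm_model.model.add_constraint(
                [
                    (cm_model.cm[(ds.last_step, dp)], 1.0),
                    (cm_model.lm[(ds.first_step, dp)], -f),
                ],
                ">=", 0.0, family="dinkelbach_bound",
            )
            last_bound_f = f
        res = cm_model.model.solve(
            mip_gap=settings.mip_gap,
            time_limit=settings.time_limit,
            presolve=not trusted,
            feasibility_tol=(
                settings.feasibility_tol if trusted else 1e-6
            ),
        )
        if res.status == "infeasible":
            if not trusted:
                trusted = True
                continue
            trace.terminal_status = "infeasible"
            if best is not None:
                # can only happen after cuts were added: nothing feasible
                # beats the incumbent's ratio, so the incumbent is optimal
                # (its residual at this f is exactly zero — record it)
                trace.iterations.append((f, 0.0, best[1].yield_))
                trace.terminal_status = "converged"
                return MILFPResult("converged", best[0], best[1], trace)
            return MILFPResult("infeasible", None, None, trace)
        if not res.is_optimal:
            raise SolverFailure(f"MILP solve ended with status {res.status!r}")
        decision = _extract_decision(cm_model, res.values)
        # re-check the decision in exact arithmetic: solver feasibility
        # tolerances can admit knife-edge solutions (purity floor, salt
        # linking) that are not feasible exactly
        try:
            metrics = evaluate_decision(ds, rt, decision)
        except ValueError:
            metrics = None
        if metrics is not None:
            num = metrics.collected[(ds.last_step, dp)]
            den = metrics.loaded[(ds.first_step, dp)]
            total = sum(
                metrics.collected[(ds.last_step, p)] for p in ds.proteins
            )
            exactly_feasible = num >= eps * total - 1e-9 * max(1.0, total)
            residual = num - f * den
            if exactly_feasible:
                # the trace records Dinkelbach iterations proper; re-solves
                # that only discard an exactly-infeasible point are not one
                trace.iterations.append((f, residual, metrics.yield_))
        else:
            exactly_feasible = False
            # the solver's own optimum still upper-bounds the exact one
            residual = res.objective
        if exactly_feasible and (best is None or metrics.yield_ > best[1].yield_):
            # the incumbent is kept across iterations: a solver returning a
            # merely near-optimal point at the final f (residual <= delta,
            # possibly negative) must not displace a better earlier decision
            best = (decision, metrics)
        if trusted and residual <= settings.delta:
            # the solver optimum over the tolerance-relaxed feasible set
            # upper-bounds the exact optimum, so this verdict is sound even
            # when the returned point itself fails the exact re-check
            if best is not None:
                if not exactly_feasible:
                    # the solve that proved convergence produced no exact
                    # iterate of its own; close the trace at the incumbent
                    trace.iterations.append((f, residual, best[1].yield_))
                trace.terminal_status = "converged"
                return MILFPResult("converged", best[0], best[1], trace)
            trace.terminal_status = "infeasible"
            return MILFPResult("infeasible", None, None, trace)
        if trusted and not exactly_feasible:
            # knife-edge: the solver's optimum is infeasible exactly and f
            # cannot advance — exclude that single decision and re-solve
            # (sound: it is infeasible, so no feasible decision is lost)
            _add_nogood_cut(cm_model, decision)
            continue
        trusted = True
        if exactly_feasible and metrics.yield_ > f:
            f = num / den
    trace.terminal_status = "iteration_limit"
    if best is None:
        return MILFPResult("infeasible", None, None, trace)
    return MILFPResult("iteration_limit", best[0], best[1], trace)


def solve_direct_milp(
    ds: HTSDataset,
    rt: RatioTable,
    eps: float,
    settings: SolverSettings | None = None,
) -> MILFPResult:
    """Single-MILP yield maximization for the constant-denominator special case.

    When every first-step calibration experiment loaded the same target-protein
    mass, the yield denominator is a constant, the fractional objective is
    linear, and one MILP maximizing collected target mass solves the problem
    exactly.  Raises ``ValueError`` if the loads are not all equal.
    """
    settings = settings or SolverSettings()
    fs, dp = ds.first_step, ds.target_protein
    loads = {
        ds.records[(fs, r, c)].loaded_mass[dp] for r, c in ds.step_conditions(fs)
    }
    if len(loads) != 1:
        raise ValueError(
            "direct MILP requires identical first-step target loads; "
            f"found {sorted(loads)}"
        )
    cm_model = build_model(ds, rt, eps, f=0.0)
    trace = DinkelbachTrace()
    for _ in range(settings.max_iterations):
        res = cm_model.model.solve(
            mip_gap=settings.mip_gap, time_limit=settings.time_limit,
            presolve=False, feasibility_tol=settings.feasibility_tol,
        )
        if res.status == "infeasible":
            trace.terminal_status = "infeasible"
            return MILFPResult("infeasible", None, None, trace)
        if not res.is_optimal:
            raise SolverFailure(f"MILP solve ended with status {res.status!r}")
        decision = _extract_decision(cm_model, res.values)
        # same exact re-check as solve_milfp: a knife-edge point admitted by
        # the solver tolerances is excluded and the MILP re-solved
        try:
            metrics = evaluate_decision(ds, rt, decision)
        except ValueError:
            metrics = None
        if metrics is not None:
            num = metrics.collected[(ds.last_step, dp)]
            total = sum(
                metrics.collected[(ds.last_step, p)] for p in ds.proteins
            )
            if num >= eps * total - 1e-9 * max(1.0, total):
                trace.iterations.append((0.0, res.objective, metrics.yield_))
                return MILFPResult("converged", decision, metrics, trace)
        _add_nogood_cut(cm_model, decision)
    trace.terminal_status = "iteration_limit"
    return MILFPResult("iteration_limit", None, None, trace)
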