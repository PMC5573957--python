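"""Data model for high-throughput chromatography screening (HTS) experiments.

A screening campaign runs each candidate resin under several operating
conditions on a microscale column, records the protein mass loaded per
protein species, and the mass collected per species in each time interval
of a salt-gradient elution.  This module defines the validated in-memory
containers for those tables (:class:`HTSDataset`), the per-interval
load-collection ratios used to predict later-step behaviour
(:class:`RatioTable`), and the CSV/YAML reader and writer.

Units are fixed: masses in mg, salt concentrations in mM.  Time intervals
are 1-based and labelled ``T1``, ``T2``, ... in all files, matching common
fraction-collector nomenclature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataError",
    "SchemaError",
    "ValidationError",
    "PHASES",
    "GradientSchedule",
    "ConditionRecord",
    "HTSDataset",
    "RatioTable",
    "load_dataset",
    "write_dataset",
    "compute_ratios",
    "effective_salt",
]


class DataError(ValueError):
    """Base class for dataset problems."""


class SchemaError(DataError):
    """A required table, column or record is missing."""


class ValidationError(DataError):
    """A table is present but violates a dataset invariant."""


#: Chromatographic phases in run order.
PHASES = ("load", "wash", "elution", "regeneration")
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}


@dataclass(frozen=True)
class GradientSchedule:
    """Per-interval phase labels and eluent salt concentrations of one step.

    Parameters
    ----------
    step_id:
        Identifier of the chromatographic step this schedule belongs to.
    phases:
        Phase of each interval (entry ``i`` is interval ``T{i+1}``).  Phases
        must appear in run order load, wash, elution, regeneration; each
        block may be empty but blocks may not interleave.
    salt_mM:
        Salt concentration of each interval, ``None`` where the buffer salt
        is not specified (typically load/wash and regeneration).  Elution
        intervals must carry a defined, non-decreasing concentration
        (gradient elution).
    """

    step_id: str
    phases: tuple[str, ...]
    salt_mM: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValidationError(f"step {self.step_id!r}: empty gradient schedule")
        if len(self.phases) != len(self.salt_mM):
            raise ValidationError(
                f"step {self.step_id!r}: {len(self.phases)} phases vs "
                f"{len(self.salt_mM)} salt entries"
            )
        ranks = []
        for t, ph in enumerate(self.phases, start=1):
            if ph not in _PHASE_RANK:
                raise ValidationError(
                    f"step {self.step_id!r} interval T{t}: unknown phase {ph!r}"
                )
            ranks.append(_PHASE_RANK[ph])
        if any(a > b for a, b in zip(ranks, ranks[1:])):
            raise ValidationError(
                f"step {self.step_id!r}: phases out of run order "
                f"(expected load <= wash <= elution <= regeneration)"
            )
        prev = None
        for t, (ph, salt) in enumerate(zip(self.phases, self.salt_mM), start=1):
            if salt is not None and salt < 0:
                raise ValidationError(
                    f"step {self.step_id!r} interval T{t}: negative salt {salt}"
                )
            if ph == "elution":
                if salt is None:
                    raise ValidationError(
                        f"step {self.step_id!r} interval T{t}: elution interval "
                        f"without a salt concentration"
                    )
                if prev is not None and salt < prev:
                    raise ValidationError(
                        f"step {self.step_id!r} interval T{t}: elution salt "
                        f"decreases ({prev} -> {salt} mM)"
                    )
                prev = salt

    @property
    def n_intervals(self) -> int:
        return len(self.phases)

    def intervals_of_phase(self, phase: str) -> list[int]:
        """1-based interval indices belonging to ``phase``."""
        return [t for t, ph in enumerate(self.phases, start=1) if ph == phase]


def effective_salt(g: GradientSchedule) -> np.ndarray:
    """Resolve undefined salt entries to a fully defined per-interval map.

    Load and wash intervals without a stated concentration are assigned
    0 mM (the gradient has not started); regeneration intervals without one
    carry forward the last defined elution concentration.  Defined values
    pass through unchanged.  Returns an array of length ``g.n_intervals``
    (entry ``i`` is interval ``T{i+1}``).
    """
    out = np.zeros(g.n_intervals)
    last_elution = 0.0
    for i, (ph, salt) in enumerate(zip(g.phases, g.salt_mM)):
        if salt is not None:
            out[i] = salt
            if ph == "elution":
                last_elution = salt
        elif ph in ("load", "wash"):
            out[i] = 0.0
        else:  # regeneration (or undefined elution, rejected upstream)
            out[i] = last_elution
    return out


@dataclass(frozen=True)
class ConditionRecord:
    """One microscale experiment: a (step, resin, condition) triple.

    ``loaded_mass`` maps protein id to the mass applied to the column;
    ``collected_mass`` maps ``(protein, interval)`` to the mass recovered in
    that interval.  Missing ``(protein, interval)`` keys mean 0 mg.
    """

    step_id: str
    resin_id: str
    condition_id: str
    loaded_mass: Mapping[str, float]
    collected_mass: Mapping[tuple[str, int], float]

    def validate(self, n_intervals: int, proteins: Sequence[str]) -> None:
        key = f"step={self.step_id} resin={self.resin_id} condition={self.condition_id}"
        for p in proteins:
            if p not in self.loaded_mass:
                raise SchemaError(f"{key}: no loaded mass for protein {p!r}")
            lm = self.loaded_mass[p]
            if not np.isfinite(lm) or lm <= 0:
                raise ValidationError(
                    f"{key}: loaded mass of protein {p!r} must be positive, got {lm}"
                )
        for (p, t), cm in self.collected_mass.items():
            if p not in self.loaded_mass:
                raise SchemaError(f"{key}: collected mass for unknown protein {p!r}")
            if not 1 <= t <= n_intervals:
                raise ValidationError(
                    f"{key}: interval T{t} outside 1..{n_intervals}"
                )
            if not np.isfinite(cm) or cm < 0:
                raise ValidationError(
                    f"{key}: collected mass of {p!r} in T{t} must be >= 0, got {cm}"
                )
        for p in proteins:
            total = sum(
                cm for (q, _t), cm in self.collected_mass.items() if q == p
            )
            if total > self.loaded_mass[p] * (1 + 1e-9):
                raise ValidationError(
                    f"{key}: collected mass of {p!r} ({total:g} mg) exceeds "
                    f"loaded mass ({self.loaded_mass[p]:g} mg)"
                )

    def collected_array(self, proteins: Sequence[str], n_intervals: int) -> np.ndarray:
        """Collected masses as a dense (protein, interval) array, mg."""
        arr = np.zeros((len(proteins), n_intervals))
        index = {p: i for i, p in enumerate(proteins)}
        for (p, t), cm in self.collected_mass.items():
            arr[index[p], t - 1] += cm
        return arr

    def loaded_array(self, proteins: Sequence[str]) -> np.ndarray:
        return np.array([self.loaded_mass[p] for p in proteins])


@dataclass(frozen=True)
class HTSDataset:
    """All experimental inputs of a (possibly multi-step) screening campaign.

    ``steps`` orders the chromatographic sequence; every ``(step, resin,
    condition)`` triple listed in ``conditions`` has exactly one
    :class:`ConditionRecord`.  All records of a step share the step's
    interval count (from its :class:`GradientSchedule`) and the global
    protein set.
    """

    steps: tuple[str, ...]
    resins: Mapping[str, tuple[str, ...]]
    conditions: Mapping[tuple[str, str], tuple[str, ...]]
    proteins: tuple[str, ...]
    target_protein: str
    records: Mapping[tuple[str, str, str], ConditionRecord]
    gradients: Mapping[str, GradientSchedule]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("dataset has no chromatographic steps")
        if len(set(self.steps)) != len(self.steps):
            raise ValidationError("duplicate step ids")
        if self.target_protein not in self.proteins:
            raise ValidationError(
                f"target protein {self.target_protein!r} not among proteins "
                f"{list(self.proteins)}"
            )
        for s in self.steps:
            if s not in self.gradients:
                raise SchemaError(f"no gradient schedule for step {s!r}")
            if s not in self.resins or not self.resins[s]:
                raise SchemaError(f"no resins for step {s!r}")
            T = self.gradients[s].n_intervals
            for r in self.resins[s]:
                conds = self.conditions.get((s, r), ())
                if not conds:
                    raise SchemaError(f"no conditions for step={s} resin={r}")
                for c in conds:
                    rec = self.records.get((s, r, c))
                    if rec is None:
                        raise SchemaError(
                            f"missing experiment record for step={s} resin={r} "
                            f"condition={c}"
                        )
                    max_t = max((t for (_p, t) in rec.collected_mass), default=1)
                    if max_t > T:
                        raise ValidationError(
                            f"step={s} resin={r} condition={c}: interval T{max_t} "
                            f"exceeds the step's {T} intervals"
                        )
                    rec.validate(T, self.proteins)

    # -- convenience accessors -------------------------------------------------

    @property
    def first_step(self) -> str:
        return self.steps[0]

    @property
    def last_step(self) -> str:
        return self.steps[-1]

    def n_intervals(self, step: str) -> int:
        return self.gradients[step].n_intervals

    def step_conditions(self, step: str) -> list[tuple[str, str]]:
        """All (resin, condition) pairs of a step, in declaration order."""
        return [
            (r, c) for r in self.resins[step] for c in self.conditions[(step, r)]
        ]

    def effective_salt(self, step: str) -> np.ndarray:
        return effective_salt(self.gradients[step])

    def subset(self, steps: Sequence[str]) -> "HTSDataset":
        """Restrict the campaign to a contiguous subsequence of steps."""
        steps = tuple(steps)
        for s in steps:
            if s not in self.steps:
                raise KeyError(f"unknown step {s!r}")
        order = [s for s in self.steps if s in steps]
        if tuple(order) != steps:
            raise ValueError(f"steps {steps} not in campaign order {self.steps}")
        return HTSDataset(
            steps=steps,
            resins={s: self.resins[s] for s in steps},
            conditions={
                (s, r): cs for (s, r), cs in self.conditions.items() if s in steps
            },
            proteins=self.proteins,
            target_protein=self.target_protein,
            records={
                k: rec for k, rec in self.records.items() if k[0] in steps
            },
            gradients={s: self.gradients[s] for s in steps},
        )


@dataclass(frozen=True)
class RatioTable:
    """Load-collection ratios lcr = cm / lm per (step, resin, condition).

    ``ratio[(s, r, c)]`` is a dense (protein, interval) array in the
    dataset's protein order; entry ``[i, t-1]`` is the fraction of protein
    ``proteins[i]``'s loaded mass recovered in interval ``T{t}``.  The
    constant-ratio assumption says these fractions carry over to any loaded
    amount, which is what makes multi-step mass prediction linear.
    """

    proteins: tuple[str, ...]
    ratio: Mapping[tuple[str, str, str], np.ndarray]

    def get(self, s: str, r: str, c: str, p: str, t: int) -> float:
        return float(self.ratio[(s, r, c)][self.proteins.index(p), t - 1])

    def window_sum(self, s: str, r: str, c: str, start: int, finish: int) -> np.ndarray:
        """Per-protein ratio summed over intervals ``start..finish`` inclusive."""
        return self.ratio[(s, r, c)][:, start - 1 : finish].sum(axis=1)


def compute_ratios(ds: HTSDataset) -> RatioTable:
    """Derive the load-collection ratio table from the calibration records."""
    out: dict[tuple[str, str, str], np.ndarray] = {}
    for (s, r, c), rec in ds.records.items():
        T = ds.n_intervals(s)
        cm = rec.collected_array(ds.proteins, T)
        lm = rec.loaded_array(ds.proteins)
        bad = (lm <= 0) & (cm.sum(axis=1) > 0)
        if bad.any():
            p = ds.proteins[int(np.argmax(bad))]
            raise ValidationError(
                f"step={s} resin={r} condition={c}: protein {p!r} has zero "
                f"loaded mass but nonzero collected mass; ratio undefined"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            lcr = np.where(lm[:, None] > 0, cm / lm[:, None], 0.0)
        out[(s, r, c)] = lcr
    return RatioTable(proteins=ds.proteins, ratio=out)


# -- file I/O -----------------------------------------------------------------

_CONDITIONS_COLS = ["step", "resin", "condition", "protein", "loaded_mass_mg"]
_COLLECTED_COLS = [
    "step", "resin", "condition", "protein", "interval", "collected_mass_mg",
]
_GRADIENT_COLS = ["step", "interval", "phase", "salt_mM"]


def _parse_interval(label: object) -> int:
    m = re.fullmatch(r"[Tt]?(\d+)", str(label).strip())
    if not m:
        raise SchemaError(f"cannot parse interval label {label!r}")
    t = int(m.group(1))
    if t < 1:
        raise ValidationError(f"interval index must be >= 1, got {label!r}")
    return t


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def load_dataset(directory: str | Path) -> HTSDataset:
    """Read and validate a dataset from its directory.

    Expects ``conditions.csv``, ``collected.csv``, ``gradient.csv`` and
    ``config.yaml`` (see the file-format section of the docs).  Returns a
    fully validated :class:`HTSDataset`; any invariant violation raises
    :class:`SchemaError` or :class:`ValidationError`.
    """
    directory = Path(directory)
    paths = {n: directory / f"{n}.csv" for n in ("conditions", "collected", "gradient")}
    for n, p in paths.items():
        if not p.exists():
            raise SchemaError(f"missing input file {p}")
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise SchemaError(f"missing input file {cfg_path}")
    config = yaml.safe_load(cfg_path.read_text()) or {}

    cond_df = pd.read_csv(paths["conditions"], dtype=str)
    _require_columns(cond_df, _CONDITIONS_COLS, "conditions.csv")
    coll_df = pd.read_csv(paths["collected"], dtype=str)
    _require_columns(coll_df, _COLLECTED_COLS, "collected.csv")
    grad_df = pd.read_csv(paths["gradient"], dtype=str)
    _require_columns(grad_df, _GRADIENT_COLS, "gradient.csv")

    steps_cfg = config.get("steps")
    steps = tuple(str(s) for s in steps_cfg) if steps_cfg else tuple(
        pd.unique(grad_df["step"])
    )
    target = config.get("target_protein")
    if target is None:
        raise SchemaError("config.yaml: target_protein is required")
    target = str(target)

    gradients: dict[str, GradientSchedule] = {}
    for s, grp in grad_df.groupby("step", sort=False):
        grp = grp.assign(_t=grp["interval"].map(_parse_interval)).sort_values("_t")
        ts = grp["_t"].tolist()
        if ts != list(range(1, len(ts) + 1)):
            raise ValidationError(
                f"gradient.csv step {s!r}: interval labels not contiguous from T1"
            )
        salts: list[float | None] = []
        for v in grp["salt_mM"]:
            salts.append(None if (pd.isna(v) or str(v).strip() in ("", "-", "–"))
                         else float(v))
        gradients[str(s)] = GradientSchedule(
            step_id=str(s),
            phases=tuple(str(p).strip().lower() for p in grp["phase"]),
            salt_mM=tuple(salts),
        )
    for s in steps:
        if s not in gradients:
            raise SchemaError(f"gradient.csv: no schedule for step {s!r}")

    proteins = tuple(dict.fromkeys(cond_df["protein"].astype(str)))
    resins: dict[str, tuple[str, ...]] = {}
    conditions: dict[tuple[str, str], tuple[str, ...]] = {}
    loaded: dict[tuple[str, str, str], dict[str, float]] = {}
    for row in cond_df.itertuples(index=False):
        s, r, c, p = str(row.step), str(row.resin), str(row.condition), str(row.protein)
        lm = float(row.loaded_mass_mg)
        loaded.setdefault((s, r, c), {})
        if p in loaded[(s, r, c)]:
            raise ValidationError(
                f"conditions.csv: duplicate row for step={s} resin={r} "
                f"condition={c} protein={p}"
            )
        loaded[(s, r, c)][p] = lm
        if s in resins:
            if r not in resins[s]:
                resins[s] = resins[s] + (r,)
        else:
            resins[s] = (r,)
        key = (s, r)
        if key in conditions:
            if c not in conditions[key]:
                conditions[key] = conditions[key] + (c,)
        else:
            conditions[key] = (c,)

    collected: dict[tuple[str, str, str], dict[tuple[str, int], float]] = {
        k: {} for k in loaded
    }
    for row in coll_df.itertuples(index=False):
        s, r, c, p = str(row.step), str(row.resin), str(row.condition), str(row.protein)
        key = (s, r, c)
        if key not in loaded:
            raise SchemaError(
                f"collected.csv: step={s} resin={r} condition={c} has no "
                f"loaded-mass record in conditions.csv"
            )
        t = _parse_interval(row.interval)
        collected[key][(p, t)] = collected[key].get((p, t), 0.0) + float(
            row.collected_mass_mg
        )

    records = {
        (s, r, c): ConditionRecord(
            step_id=s, resin_id=r, condition_id=c,
            loaded_mass=loaded[(s, r, c)], collected_mass=collected[(s, r, c)],
        )
        for (s, r, c) in loaded
    }
    return HTSDataset(
        steps=steps,
        resins=resins,
        conditions=conditions,
        proteins=proteins,
        target_protein=target,
        records=records,
        gradients=gradients,
    )


def write_dataset(ds: HTSDataset, directory: str | Path,
                  solver_settings: Mapping | None = None) -> None:
    """Write a dataset to ``directory`` in the canonical CSV + YAML layout.

    Inverse of :func:`load_dataset` up to row order and zero collected-mass
    rows (which are omitted and read back as 0).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cond_rows, coll_rows, grad_rows = [], [], []
    for s in ds.steps:
        g = ds.gradients[s]
        for t, (ph, salt) in enumerate(zip(g.phases, g.salt_mM), start=1):
            grad_rows.append(
                {"step": s, "interval": f"T{t}", "phase": ph,
                 "salt_mM": "" if salt is None else repr(float(salt))}
            )
        for r, c in ds.step_conditions(s):
            rec = ds.records[(s, r, c)]
            for p in ds.proteins:
                cond_rows.append(
                    {"step": s, "resin": r, "condition": c, "protein": p,
                     "loaded_mass_mg": repr(float(rec.loaded_mass[p]))}
                )
            for (p, t) in sorted(rec.collected_mass):
                cm = rec.collected_mass[(p, t)]
                if cm != 0.0:
                    coll_rows.append(
                        {"step": s, "resin": r, "condition": c, "protein": p,
                         "interval": f"T{t}", "collected_mass_mg": repr(float(cm))}
                    )
    pd.DataFrame(cond_rows, columns=_CONDITIONS_COLS).to_csv(
        directory / "conditions.csv", index=False
    )
    pd.DataFrame(coll_rows, columns=_COLLECTED_COLS).to_csv(
        directory / "collected.csv", index=False
    )
    pd.DataFrame(grad_rows, columns=_GRADIENT_COLS).to_csv(
        directory / "gradient.csv", index=False
    )
    config = {"target_protein": ds.target_protein, "steps": list(ds.steps)}
    if solver_settings:
        config["solver"] = dict(solver_settings)
    (directory / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
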