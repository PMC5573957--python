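"""Seeded generator of HTS-like chromatography screening datasets.

The real screening masses behind the motivating case study are
confidential, so everything downstream is exercised on generated data that
reproduces their *structure*: a two-step campaign (cation exchange then
mixed mode), a three-species feed (target monomer plus aggregate and
fragment impurities at 86.2 / 10.6 / 3.2% of the load), stepwise salt
gradients, and one record per (step, resin, condition).

The elution model is the standard idealization of gradient elution: each
protein leaves the column as a Gaussian band in eluent salt concentration,
discretized onto the step's intervals and scaled so the recovered fraction
of the load is fixed.  Resin and condition identity perturb each protein's
band center and width multiplicatively (seeded), so no condition dominates
by construction.  A small flow-through fraction can be placed in the
load/wash intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .hts_data import (
    ConditionRecord,
    GradientSchedule,
    HTSDataset,
    effective_salt,
)

__all__ = [
    "ProteinSpec",
    "StepSpec",
    "SyntheticSpec",
    "generate",
    "paper_preset",
    "toy_preset",
    "random_spec",
    "separability_knob",
    "constant_ratio_demo_dataset",
    "cex_gradient",
    "mm_gradient",
]

#: Feed composition of the emulated case study: monomer / aggregate / fragment.
DEFAULT_LOAD_FRACTIONS = {"monomer": 0.862, "aggregate": 0.106, "fragment": 0.032}


def cex_gradient(step_id: str = "CEX") -> GradientSchedule:
    """17-interval cation-exchange schedule: NaCl 0 -> 300 mM over elution."""
    elution = [0, 0, 50, 50, 100, 100, 150, 150, 200, 200, 250, 250, 300, 300]
    return GradientSchedule(
        step_id=step_id,
        phases=("load", "load", "wash") + ("elution",) * 14,
        salt_mM=(None, None, None) + tuple(float(v) for v in elution),
    )


def mm_gradient(step_id: str = "MM") -> GradientSchedule:
    """29-interval mixed-mode schedule: NaCl 0 -> 1000 mM, then regeneration."""
    elution = [0, 0, 50, 50, 100, 100, 200, 200, 300, 300, 400, 400,
               500, 500, 600, 600, 700, 700, 800, 800, 900, 900, 1000, 1000]
    return GradientSchedule(
        step_id=step_id,
        phases=("load", "load", "wash") + ("elution",) * 24 + ("regeneration",) * 2,
        salt_mM=(None, None, None) + tuple(float(v) for v in elution) + (None, None),
    )


@dataclass(frozen=True)
class ProteinSpec:
    """One species in the feed: its load fraction and per-step band shape.

    ``center_mM`` / ``width_mM`` map step id to the mean elution salt and
    the Gaussian band width (one standard deviation, in mM).
    """

    name: str
    load_fraction: float
    center_mM: Mapping[str, float]
    width_mM: Mapping[str, float]


@dataclass(frozen=True)
class StepSpec:
    """One chromatographic step: candidate resins x conditions and its gradient."""

    gradient: GradientSchedule
    n_resins: int
    conditions_per_resin: tuple[int, ...]

    @property
    def step_id(self) -> str:
        return self.gradient.step_id

    def __post_init__(self) -> None:
        if self.n_resins < 1:
            raise ValueError("need at least one resin")
        if len(self.conditions_per_resin) != self.n_resins:
            raise ValueError(
                f"conditions_per_resin has {len(self.conditions_per_resin)} "
                f"entries for {self.n_resins} resins"
            )
        if any(n < 1 for n in self.conditions_per_resin):
            raise ValueError("every resin needs at least one condition")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a generated screening campaign.

    ``recovery`` is the fraction of each protein's load recovered over the
    elution intervals; ``flowthrough`` the fraction appearing unretained in
    load/wash intervals; their sum must not exceed 1 (no mass creation).
    ``center_jitter_rel`` / ``width_jitter_rel`` are the relative standard
    deviations of the per-(resin, condition) multiplicative perturbations.
    """

    steps: tuple[StepSpec, ...]
    proteins: tuple[ProteinSpec, ...]
    target_protein: str
    total_load_mg: float = 10.0
    recovery: float = 0.95
    flowthrough: float = 0.02
    center_jitter_rel: float = 0.05
    width_jitter_rel: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("spec needs at least one step")
        fractions = [p.load_fraction for p in self.proteins]
        if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"load fractions must be positive and sum to 1, got {fractions}"
            )
        if self.target_protein not in {p.name for p in self.proteins}:
            raise ValueError(f"unknown target protein {self.target_protein!r}")
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery must lie in (0, 1]")
        if self.flowthrough < 0 or self.recovery + self.flowthrough > 1 + 1e-12:
            raise ValueError("recovery + flowthrough must not exceed 1")
        if self.total_load_mg <= 0:
            raise ValueError("total load must be positive")


def generate(spec: SyntheticSpec) -> HTSDataset:
    """Materialize a validated :class:`HTSDataset` from a spec, deterministically.

    The RNG stream is a function of the seed only, so identical specs give
    byte-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    protein_names = tuple(p.name for p in spec.proteins)

    steps: list[str] = []
    resins: dict[str, tuple[str, ...]] = {}
    conditions: dict[tuple[str, str], tuple[str, ...]] = {}
    records: dict[tuple[str, str, str], ConditionRecord] = {}
    gradients: dict[str, GradientSchedule] = {}

    for st in spec.steps:
        s = st.step_id
        steps.append(s)
        gradients[s] = st.gradient
        salt = effective_salt(st.gradient)
        elution_idx = [t - 1 for t in st.gradient.intervals_of_phase("elution")]
        lw_idx = [
            t - 1
            for ph in ("load", "wash")
            for t in st.gradient.intervals_of_phase(ph)
        ]
        resin_ids = tuple(f"R{s}{i}" for i in range(1, st.n_resins + 1))
        resins[s] = resin_ids
        for r_i, r in enumerate(resin_ids, start=1):
            n_cond = st.conditions_per_resin[r_i - 1]
            cond_ids = tuple(f"C{s}{r_i}-{j}" for j in range(1, n_cond + 1))
            conditions[(s, r)] = cond_ids
            for c in cond_ids:
                loaded: dict[str, float] = {}
                collected: dict[tuple[str, int], float] = {}
                for prot in spec.proteins:
                    lm = spec.total_load_mg * prot.load_fraction
                    loaded[prot.name] = lm
                    center = prot.center_mM[s] * math.exp(
                        rng.normal(0.0, spec.center_jitter_rel)
                    )
                    width = max(
                        prot.width_mM[s]
                        * math.exp(rng.normal(0.0, spec.width_jitter_rel)),
                        1e-6,
                    )
                    if elution_idx:
                        weights = np.exp(
                            -0.5 * ((salt[elution_idx] - center) / width) ** 2
                        )
                        total_w = weights.sum()
                        if total_w < 1e-12:
                            # band entirely outside the gradient: dump the
                            # recovered mass in the nearest-salt interval
                            weights = np.zeros(len(elution_idx))
                            weights[
                                int(np.argmin(np.abs(salt[elution_idx] - center)))
                            ] = 1.0
                            total_w = 1.0
                        masses = spec.recovery * lm * weights / total_w
                        for j, t0 in enumerate(elution_idx):
                            if masses[j] > 0:
                                collected[(prot.name, t0 + 1)] = float(masses[j])
                    if lw_idx and spec.flowthrough > 0:
                        ft = spec.flowthrough * lm / len(lw_idx)
                        for t0 in lw_idx:
                            collected[(prot.name, t0 + 1)] = (
                                collected.get((prot.name, t0 + 1), 0.0) + ft
                            )
                records[(s, r, c)] = ConditionRecord(
                    step_id=s, resin_id=r, condition_id=c,
                    loaded_mass=loaded, collected_mass=collected,
                )
    return HTSDataset(
        steps=tuple(steps),
        resins=resins,
        conditions=conditions,
        proteins=protein_names,
        target_protein=spec.target_protein,
        records=records,
        gradients=gradients,
    )


def paper_preset(seed: int = 0) -> SyntheticSpec:
    """Campaign with the case study's structure: CEX (8 resins x 2
    conditions, 17 intervals) into MM (3 resins x 7/8/12 conditions, 29
    intervals), three species at 86.2 / 10.6 / 3.2% of a 10 mg load."""
    proteins = (
        ProteinSpec("monomer", 0.862,
                    {"CEX": 150.0, "MM": 450.0}, {"CEX": 40.0, "MM": 120.0}),
        ProteinSpec("aggregate", 0.106,
                    {"CEX": 230.0, "MM": 700.0}, {"CEX": 40.0, "MM": 120.0}),
        ProteinSpec("fragment", 0.032,
                    {"CEX": 70.0, "MM": 220.0}, {"CEX": 40.0, "MM": 120.0}),
    )
    return SyntheticSpec(
        steps=(
            StepSpec(cex_gradient(), n_resins=8, conditions_per_resin=(2,) * 8),
            StepSpec(mm_gradient(), n_resins=3, conditions_per_resin=(7, 8, 12)),
        ),
        proteins=proteins,
        target_protein="monomer",
        seed=seed,
    )


def _ramp_gradient(step_id: str, n_intervals: int, max_salt: float) -> GradientSchedule:
    """One load interval, then a linear stepwise elution ramp to ``max_salt``."""
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    n_el = n_intervals - 1
    salts = tuple(
        float(np.round(max_salt * k / max(n_el - 1, 1), 6)) for k in range(n_el)
    )
    return GradientSchedule(
        step_id=step_id,
        phases=("load",) + ("elution",) * n_el,
        salt_mM=(None,) + salts,
    )


def toy_preset(
    seed: int = 0,
    n_steps: int = 2,
    n_resins: int = 2,
    conditions_per_resin: int = 2,
    n_intervals: int = 8,
) -> SyntheticSpec:
    """Small deterministic campaign for tests and worked examples."""
    return random_spec(
        seed, n_steps=n_steps, n_resins=n_resins,
        conditions_per_resin=conditions_per_resin, n_intervals=n_intervals,
    )


def random_spec(
    seed: int,
    n_steps: int = 2,
    n_resins: int = 2,
    conditions_per_resin: int = 2,
    n_intervals: int = 8,
) -> SyntheticSpec:
    """Seeded random small campaign: ramp gradients with increasing ceilings
    across steps (so salt linking stays satisfiable) and band centers drawn
    within each gradient's span.

    The three-species feed composition and recovery defaults match
    :func:`paper_preset`; only the geometry is randomized.
    """
    rng = np.random.default_rng(seed)
    steps = []
    ceilings = []
    for k in range(n_steps):
        ceiling = 300.0 * (k + 1) + float(np.round(rng.uniform(0, 100), 3))
        ceilings.append(ceiling)
        steps.append(
            StepSpec(
                _ramp_gradient(f"S{k + 1}", n_intervals, ceiling),
                n_resins=n_resins,
                conditions_per_resin=(conditions_per_resin,) * n_resins,
            )
        )
    names = ("monomer", "aggregate", "fragment")
    proteins = tuple(
        ProteinSpec(
            name,
            DEFAULT_LOAD_FRACTIONS[name],
            {
                f"S{k + 1}": float(np.round(rng.uniform(0.2, 0.9) * ceilings[k], 3))
                for k in range(n_steps)
            },
            {
                f"S{k + 1}": float(
                    np.round(rng.uniform(0.08, 0.25) * ceilings[k], 3)
                )
                for k in range(n_steps)
            },
        )
        for name in names
    )
    return SyntheticSpec(
        steps=tuple(steps),
        proteins=proteins,
        target_protein="monomer",
        center_jitter_rel=0.08,
        width_jitter_rel=0.08,
        seed=seed,
    )


def constant_ratio_demo_dataset() -> HTSDataset:
    """Handcrafted two-step dataset illustrating constant-ratio mass prediction.

    All masses are powers of two, so the ratio arithmetic
    ``M = (cm / lm) * LM`` is floating-point exact.  Pooling T2-T3 at the
    first step delivers exactly twice the target's second-step calibration
    load (32 mg vs 16 mg) and half the impurity's (16 mg vs 32 mg), so the
    predicted per-interval collected masses at the second step are exactly
    ``2 * cm`` for the target and ``0.5 * cm`` for the impurity.
    """
    g1 = GradientSchedule(
        step_id="S1",
        phases=("load", "elution", "elution", "elution"),
        salt_mM=(None, 0.0, 50.0, 100.0),
    )
    g2 = GradientSchedule(
        step_id="S2",
        phases=("load", "elution", "elution", "elution"),
        salt_mM=(None, 100.0, 200.0, 300.0),
    )
    rec1 = ConditionRecord(
        step_id="S1", resin_id="R1", condition_id="C1",
        loaded_mass={"target": 32.0, "impurity": 32.0},
        collected_mass={
            ("target", 2): 16.0, ("target", 3): 16.0,
            ("impurity", 2): 8.0, ("impurity", 3): 8.0,
        },
    )
    rec2 = ConditionRecord(
        step_id="S2", resin_id="R1", condition_id="C1",
        loaded_mass={"target": 16.0, "impurity": 32.0},
        collected_mass={
            ("target", 2): 4.0, ("target", 3): 2.0, ("target", 4): 1.0,
            ("impurity", 2): 8.0, ("impurity", 3): 4.0, ("impurity", 4): 2.0,
        },
    )
    return HTSDataset(
        steps=("S1", "S2"),
        resins={"S1": ("R1",), "S2": ("R1",)},
        conditions={("S1", "R1"): ("C1",), ("S2", "R1"): ("C1",)},
        proteins=("target", "impurity"),
        target_protein="target",
        records={("S1", "R1", "C1"): rec1, ("S2", "R1", "C1"): rec2},
        gradients={"S1": g1, "S2": g2},
    )


def separability_knob(spec: SyntheticSpec, delta_salt: float) -> SyntheticSpec:
    """Re-center every impurity band ``delta_salt`` mM away from the target's.

    Impurity bands are made congruent to the target's (same width) and
    placed ``delta_salt`` mM away, alternating sides and clipped at 0 mM.
    ``delta_salt = 0`` therefore makes all species elute identically (with
    jitter disabled, purity can never exceed the feed's target fraction);
    larger values separate the bands and can only improve the attainable
    purity.
    """
    if delta_salt < 0:
        raise ValueError("delta_salt must be >= 0")
    target = next(p for p in spec.proteins if p.name == spec.target_protein)
    new_proteins = []
    side = +1
    for p in spec.proteins:
        if p.name == spec.target_protein:
            new_proteins.append(p)
            continue
        centers = {
            s: max(c + side * delta_salt, 0.0)
            for s, c in target.center_mM.items()
        }
        new_proteins.append(
            replace(p, center_mM=centers, width_mM=dict(target.width_mM))
        )
        side = -side
    return replace(spec, proteins=tuple(new_proteins))
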