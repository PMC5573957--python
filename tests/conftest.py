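"""Shared fixtures: small generated campaigns and handcrafted datasets."""

from __future__ import annotations

import numpy as np
import pytest

from resinopt.hts_data import (
    ConditionRecord,
    GradientSchedule,
    HTSDataset,
    compute_ratios,
)
from resinopt.synthetic_hts import generate, paper_preset, random_spec


@pytest.fixture(scope="session")
def toy_ds():
    """Two-step campaign, 2 resins x 2 conditions x 8 intervals per step."""
    return generate(random_spec(7))


@pytest.fixture(scope="session")
def toy_rt(toy_ds):
    return compute_ratios(toy_ds)


@pytest.fixture(scope="session")
def paper_ds():
    """Campaign with the emulated case study's full structure."""
    return generate(paper_preset(1))


@pytest.fixture(scope="session")
def paper_rt(paper_ds):
    return compute_ratios(paper_ds)


def make_minimal_dataset() -> HTSDataset:
    """Single step, one resin, one condition, one protein, three intervals."""
    g = GradientSchedule(
        step_id="S1",
        phases=("load", "elution", "elution"),
        salt_mM=(None, 0.0, 100.0),
    )
    rec = ConditionRecord(
        step_id="S1", resin_id="R1", condition_id="C1",
        loaded_mass={"p1": 10.0},
        collected_mass={("p1", 2): 5.0, ("p1", 3): 3.0},
    )
    return HTSDataset(
        steps=("S1",),
        resins={"S1": ("R1",)},
        conditions={("S1", "R1"): ("C1",)},
        proteins=("p1",),
        target_protein="p1",
        records={("S1", "R1", "C1"): rec},
        gradients={"S1": g},
    )


@pytest.fixture
def minimal_ds() -> HTSDataset:
    return make_minimal_dataset()


def make_tiny_two_step(
    cm2_per_cond: dict[str, dict[tuple[str, int], float]] | None = None,
    n_conditions_s2: int = 1,
) -> HTSDataset:
    """Tiny two-step dataset (1 resin/step, T=4) for exhaustive MILP checks."""
    g1 = GradientSchedule(
        step_id="A", phases=("load",) + ("elution",) * 3,
        salt_mM=(None, 0.0, 100.0, 200.0),
    )
    g2 = GradientSchedule(
        step_id="B", phases=("load",) + ("elution",) * 3,
        salt_mM=(None, 100.0, 300.0, 500.0),
    )
    rec_a = ConditionRecord(
        step_id="A", resin_id="R1", condition_id="C1",
        loaded_mass={"tgt": 8.0, "imp": 4.0},
        collected_mass={
            ("tgt", 2): 2.0, ("tgt", 3): 4.0, ("tgt", 4): 1.0,
            ("imp", 2): 1.0, ("imp", 3): 0.5, ("imp", 4): 2.0,
        },
    )
    conds = tuple(f"C{j}" for j in range(1, n_conditions_s2 + 1))
    records = {("A", "R1", "C1"): rec_a}
    rng = np.random.default_rng(11)
    for c in conds:
        if cm2_per_cond and c in cm2_per_cond:
            cm = cm2_per_cond[c]
        else:
            vals = rng.uniform(0.05, 0.3, size=6)
            cm = {
                ("tgt", 2): vals[0] * 8, ("tgt", 3): vals[1] * 8,
                ("tgt", 4): vals[2] * 8,
                ("imp", 2): vals[3] * 4, ("imp", 3): vals[4] * 4,
                ("imp", 4): vals[5] * 4,
            }
        records[("B", "R1", c)] = ConditionRecord(
            step_id="B", resin_id="R1", condition_id=c,
            loaded_mass={"tgt": 8.0, "imp": 4.0}, collected_mass=cm,
        )
    return HTSDataset(
        steps=("A", "B"),
        resins={"A": ("R1",), "B": ("R1",)},
        conditions={("A", "R1"): ("C1",), ("B", "R1"): conds},
        proteins=("tgt", "imp"),
        target_protein="tgt",
        records=records,
        gradients={"A": g1, "B": g2},
    )
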