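"""Forward simulation semantics and the Dinkelbach fractional solver."""

from __future__ import annotations

import numpy as np
import pytest

from resinopt.exhaustive_oracle import oracle_max_yield
from resinopt.fractional_solver import (
    SolverSettings,
    StepDecision,
    evaluate_decision,
    solve_direct_milp,
    solve_milfp,
)
from resinopt.hts_data import (
    ConditionRecord,
    HTSDataset,
    compute_ratios,
)
from resinopt.synthetic_hts import (
    constant_ratio_demo_dataset,
    generate,
    random_spec,
    separability_knob,
)

from conftest import make_minimal_dataset


class TestEvaluateDecision:
    def test_doubled_load_doubles_predicted_interval_mass(self):
        """Constant-ratio assumption: twice the load, twice the collected mass."""
        ds = constant_ratio_demo_dataset()
        rt = compute_ratios(ds)
        cm2 = ds.records[("S2", "R1", "C1")].collected_array(ds.proteins, 4)
        tgt = ds.proteins.index("target")
        for t in (2, 3, 4):
            decision = (
                StepDecision("S1", "R1", "C1", start=2, finish=3),
                StepDecision("S2", "R1", "C1", start=t, finish=t),
            )
            metrics = evaluate_decision(ds, rt, decision)
            # first step delivers 32 mg target = 2 x the 16 mg calibration load
            assert metrics.loaded[("S2", "target")] == 32.0
            assert metrics.collected[("S2", "target")] == 2.0 * cm2[tgt, t - 1]

    def test_halved_load_halves_predicted_interval_mass(self):
        ds = constant_ratio_demo_dataset()
        rt = compute_ratios(ds)
        cm2 = ds.records[("S2", "R1", "C1")].collected_array(ds.proteins, 4)
        imp = ds.proteins.index("impurity")
        for t in (2, 3, 4):
            decision = (
                StepDecision("S1", "R1", "C1", start=2, finish=3),
                StepDecision("S2", "R1", "C1", start=t, finish=t),
            )
            metrics = evaluate_decision(ds, rt, decision)
            # first step delivers 16 mg impurity = 0.5 x the 32 mg calibration
            assert metrics.loaded[("S2", "impurity")] == 16.0
            assert metrics.collected[("S2", "impurity")] == 0.5 * cm2[imp, t - 1]

    def test_full_window_with_total_recovery_gives_unit_yield(self):
        ds = make_minimal_dataset()  # collects 8 of 10 mg over T2-T3
        rec = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C1",
            loaded_mass={"p1": 10.0},
            collected_mass={("p1", 2): 6.0, ("p1", 3): 4.0},
        )
        ds = HTSDataset(
            steps=("S1",), resins={"S1": ("R1",)},
            conditions={("S1", "R1"): ("C1",)}, proteins=("p1",),
            target_protein="p1", records={("S1", "R1", "C1"): rec},
            gradients=dict(ds.gradients),
        )
        rt = compute_ratios(ds)
        m = evaluate_decision(ds, rt, (StepDecision("S1", "R1", "C1", 1, 3),))
        assert m.yield_ == 1.0
        assert m.purity == 1.0  # single protein: everything collected is target

    def test_empty_collection_flags_undefined_purity(self, minimal_ds):
        rt = compute_ratios(minimal_ds)
        m = evaluate_decision(
            minimal_ds, rt, (StepDecision("S1", "R1", "C1", 1, 1),)
        )  # nothing elutes in the load interval
        assert m.yield_ == 0.0
        assert m.purity is None
        assert m.empty_collection

    def test_salt_linking_violation_is_contract_error(self):
        ds = constant_ratio_demo_dataset()
        rt = compute_ratios(ds)
        with pytest.raises(ValueError, match="salt linking"):
            evaluate_decision(
                ds, rt,
                (
                    StepDecision("S1", "R1", "C1", 4, 4),   # 100 mM finish
                    StepDecision("S2", "R1", "C1", 1, 4),   # 0 mM start (load)
                ),
            )

    def test_window_must_be_ordered(self):
        with pytest.raises(ValueError, match="invalid window"):
            StepDecision("S1", "R1", "C1", start=3, finish=2)

    @pytest.mark.parametrize("factor", [0.25, 4.0])
    def test_yield_and_purity_invariant_under_feed_scaling(self, factor, toy_ds):
        """Scaling all first-step loaded and collected masses by a common
        factor leaves both criteria unchanged (the model is homogeneous)."""
        fs = toy_ds.first_step
        records = {}
        for key, rec in toy_ds.records.items():
            if key[0] != fs:
                records[key] = rec
                continue
            records[key] = ConditionRecord(
                step_id=rec.step_id, resin_id=rec.resin_id,
                condition_id=rec.condition_id,
                loaded_mass={p: factor * v for p, v in rec.loaded_mass.items()},
                collected_mass={
                    k: factor * v for k, v in rec.collected_mass.items()
                },
            )
        scaled = HTSDataset(
            steps=toy_ds.steps, resins=toy_ds.resins,
            conditions=toy_ds.conditions, proteins=toy_ds.proteins,
            target_protein=toy_ds.target_protein, records=records,
            gradients=toy_ds.gradients,
        )
        decision = (
            StepDecision("S1", "RS11", "CS11-1", 3, 6),
            StepDecision("S2", "RS21", "CS21-2", 5, 8),
        )
        m0 = evaluate_decision(toy_ds, compute_ratios(toy_ds), decision)
        m1 = evaluate_decision(scaled, compute_ratios(scaled), decision)
        assert m1.yield_ == pytest.approx(m0.yield_, rel=1e-12)
        assert m1.purity == pytest.approx(m0.purity, rel=1e-12)


class TestSolveMILFP:
    def test_unconstrained_solve_matches_exhaustive_maximum(self, toy_ds, toy_rt):
        res = solve_milfp(toy_ds, toy_rt, eps=0.0)
        assert res.status == "converged"
        oracle = oracle_max_yield(toy_ds, toy_rt, eps=0.0)
        assert res.metrics.yield_ == pytest.approx(
            oracle[1].yield_, abs=1e-9
        )

    def test_unattainable_purity_is_infeasible(self):
        """With all species co-eluting, every interval of every condition
        carries impurity mass, so a purity floor of 1 cannot be met."""
        spec = separability_knob(random_spec(5, n_steps=1, n_intervals=6), 0.0)
        ds = generate(spec)
        rt = compute_ratios(ds)
        res = solve_milfp(ds, rt, eps=1.0)
        assert res.status == "infeasible"
        assert res.decision is None

    @pytest.mark.parametrize("seed", [2, 9])
    def test_dinkelbach_iterates_increase_and_residual_decreases(self, seed):
        ds = generate(random_spec(seed))
        rt = compute_ratios(ds)
        res = solve_milfp(ds, rt, eps=0.9)
        assert res.status == "converged"
        fs = [f for f, _r, _y in res.trace.iterations]
        residuals = [r for _f, r, _y in res.trace.iterations]
        assert all(a < b for a, b in zip(fs, fs[1:]))
        assert all(r >= -1e-9 for r in residuals)
        assert all(a >= b - 1e-12 for a, b in zip(residuals, residuals[1:]))
        assert res.trace.n_iterations <= 50
        assert residuals[-1] <= 1e-6
        # returned metrics equal the forward simulation of the decision
        m = evaluate_decision(ds, rt, res.decision)
        assert m.yield_ == res.metrics.yield_
        assert m.purity == res.metrics.purity

    def test_settings_validation(self):
        with pytest.raises(ValueError, match="delta"):
            SolverSettings(delta=0.0)
        with pytest.raises(ValueError, match="max_iterations"):
            SolverSettings(max_iterations=0)


class TestDirectMILP:
    def test_requires_identical_first_step_loads(self):
        ds = constant_ratio_demo_dataset()
        rt = compute_ratios(ds)
        records = dict(ds.records)
        rec = records[("S1", "R1", "C1")]
        # a second condition with a different target load breaks the special case
        records[("S1", "R1", "C2")] = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C2",
            loaded_mass={"target": 64.0, "impurity": 32.0},
            collected_mass=dict(rec.collected_mass),
        )
        conditions = dict(ds.conditions)
        conditions[("S1", "R1")] = ("C1", "C2")
        ds2 = HTSDataset(
            steps=ds.steps, resins=ds.resins, conditions=conditions,
            proteins=ds.proteins, target_protein=ds.target_protein,
            records=records, gradients=ds.gradients,
        )
        with pytest.raises(ValueError, match="identical first-step"):
            solve_direct_milp(ds2, compute_ratios(ds2), eps=0.5)

    def test_matches_dinkelbach_on_uniform_load_instance(self, toy_ds, toy_rt):
        direct = solve_direct_milp(toy_ds, toy_rt, eps=0.9)
        dink = solve_milfp(toy_ds, toy_rt, eps=0.9)
        assert direct.status == dink.status == "converged"
        assert direct.metrics.yield_ == pytest.approx(
            dink.metrics.yield_, abs=1e-9
        )
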