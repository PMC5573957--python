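"""Dataset containers, validation, ratio computation and file round trips."""

from __future__ import annotations

import numpy as np
import pytest

from resinopt.hts_data import (
    ConditionRecord,
    GradientSchedule,
    HTSDataset,
    SchemaError,
    ValidationError,
    compute_ratios,
    effective_salt,
    load_dataset,
    write_dataset,
)
from resinopt.synthetic_hts import (
    cex_gradient,
    generate,
    mm_gradient,
    paper_preset,
    random_spec,
)

from conftest import make_minimal_dataset


class TestGradientSchedule:
    def test_phases_must_follow_run_order(self):
        with pytest.raises(ValidationError, match="out of run order"):
            GradientSchedule("S", ("elution", "load"), (0.0, None))

    def test_elution_salt_must_be_defined_and_non_decreasing(self):
        with pytest.raises(ValidationError, match="without a salt"):
            GradientSchedule("S", ("elution", "elution"), (0.0, None))
        with pytest.raises(ValidationError, match="decreases"):
            GradientSchedule("S", ("elution", "elution"), (100.0, 50.0))

    def test_negative_salt_rejected(self):
        with pytest.raises(ValidationError, match="negative salt"):
            GradientSchedule("S", ("elution",), (-1.0,))


class TestEffectiveSalt:
    def test_cex_schedule_fills_load_wash_with_zero(self):
        salt = effective_salt(cex_gradient())
        assert salt[0] == salt[1] == salt[2] == 0.0   # T1-T3 (load/wash)
        assert salt[3] == 0.0                          # T4, first elution
        assert salt[15] == salt[16] == 300.0           # T16-T17

    def test_mm_regeneration_carries_last_elution_value(self):
        salt = effective_salt(mm_gradient())
        assert salt[26] == 1000.0                      # T27, last elution
        assert salt[27] == salt[28] == 1000.0          # T28-T29 (regeneration)

    def test_all_elution_defined_schedule_is_identity(self):
        g = GradientSchedule("S", ("elution",) * 3, (10.0, 20.0, 30.0))
        assert effective_salt(g).tolist() == [10.0, 20.0, 30.0]

    @pytest.mark.parametrize("g", [cex_gradient(), mm_gradient()])
    def test_non_decreasing_through_elution(self, g):
        salt = effective_salt(g)
        n_pre = len(
            [p for p in g.phases if p in ("load", "wash", "elution")]
        )
        assert (np.diff(salt[:n_pre]) >= 0).all()


class TestDatasetValidation:
    def test_minimal_dataset_is_valid(self, minimal_ds):
        assert minimal_ds.steps == ("S1",)
        assert minimal_ds.n_intervals("S1") == 3

    def test_paper_shaped_dataset_has_case_study_dimensions(self, paper_ds):
        assert len(paper_ds.resins["CEX"]) == 8
        assert len(paper_ds.step_conditions("CEX")) == 16
        assert paper_ds.n_intervals("CEX") == 17
        assert len(paper_ds.resins["MM"]) == 3
        assert len(paper_ds.step_conditions("MM")) == 27  # 7 + 8 + 12
        assert paper_ds.n_intervals("MM") == 29

    def test_overcollection_rejected(self, minimal_ds):
        rec = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C1",
            loaded_mass={"p1": 10.0},
            collected_mass={("p1", 2): 9.0, ("p1", 3): 3.0},
        )
        with pytest.raises(ValidationError, match="exceeds"):
            HTSDataset(
                steps=("S1",), resins={"S1": ("R1",)},
                conditions={("S1", "R1"): ("C1",)}, proteins=("p1",),
                target_protein="p1", records={("S1", "R1", "C1"): rec},
                gradients={"S1": minimal_ds.gradients["S1"]},
            )

    def test_missing_record_names_the_tuple(self, minimal_ds):
        with pytest.raises(SchemaError, match="step=S1 resin=R1 condition=C2"):
            HTSDataset(
                steps=("S1",), resins={"S1": ("R1",)},
                conditions={("S1", "R1"): ("C1", "C2")}, proteins=("p1",),
                target_protein="p1",
                records=dict(minimal_ds.records),
                gradients=dict(minimal_ds.gradients),
            )

    def test_negative_mass_rejected(self, minimal_ds):
        rec = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C1",
            loaded_mass={"p1": 10.0}, collected_mass={("p1", 2): -1.0},
        )
        with pytest.raises(ValidationError, match=">= 0"):
            HTSDataset(
                steps=("S1",), resins={"S1": ("R1",)},
                conditions={("S1", "R1"): ("C1",)}, proteins=("p1",),
                target_protein="p1", records={("S1", "R1", "C1"): rec},
                gradients=dict(minimal_ds.gradients),
            )

    def test_interval_beyond_schedule_rejected(self, minimal_ds):
        rec = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C1",
            loaded_mass={"p1": 10.0}, collected_mass={("p1", 9): 1.0},
        )
        with pytest.raises(ValidationError, match="T9"):
            HTSDataset(
                steps=("S1",), resins={"S1": ("R1",)},
                conditions={("S1", "R1"): ("C1",)}, proteins=("p1",),
                target_protein="p1", records={("S1", "R1", "C1"): rec},
                gradients=dict(minimal_ds.gradients),
            )

    def test_subset_preserves_order_and_content(self, toy_ds):
        sub = toy_ds.subset(["S2"])
        assert sub.steps == ("S2",)
        assert sub.first_step == sub.last_step == "S2"
        with pytest.raises(KeyError):
            toy_ds.subset(["nope"])


class TestRatios:
    def test_direct_division(self):
        ds = make_minimal_dataset()
        rt = compute_ratios(ds)
        arr = rt.ratio[("S1", "R1", "C1")]
        assert arr.tolist() == [[0.0, 0.5, 0.3]]

    def test_all_zero_collection_gives_zero_ratios(self, minimal_ds):
        rec = ConditionRecord(
            step_id="S1", resin_id="R1", condition_id="C1",
            loaded_mass={"p1": 10.0}, collected_mass={},
        )
        ds = HTSDataset(
            steps=("S1",), resins={"S1": ("R1",)},
            conditions={("S1", "R1"): ("C1",)}, proteins=("p1",),
            target_protein="p1", records={("S1", "R1", "C1"): rec},
            gradients=dict(minimal_ds.gradients),
        )
        assert compute_ratios(ds).ratio[("S1", "R1", "C1")].sum() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_ratio_roundtrip_and_bounds(self, seed):
        """cm = ratio * lm recovers the table; entries and sums lie in [0, 1]."""
        ds = generate(random_spec(seed))
        rt = compute_ratios(ds)
        for (s, r, c), lcr in rt.ratio.items():
            rec = ds.records[(s, r, c)]
            cm = rec.collected_array(ds.proteins, ds.n_intervals(s))
            lm = rec.loaded_array(ds.proteins)
            np.testing.assert_allclose(lcr * lm[:, None], cm, rtol=1e-12)
            assert ((lcr >= 0) & (lcr <= 1)).all()
            assert (lcr.sum(axis=1) <= 1 + 1e-9).all()


class TestFileRoundTrip:
    @pytest.mark.parametrize("preset", ["paper", "toy"])
    def test_write_then_load_reproduces_dataset(self, tmp_path, preset):
        spec = paper_preset(3) if preset == "paper" else random_spec(3)
        ds = generate(spec)
        write_dataset(ds, tmp_path)
        ds2 = load_dataset(tmp_path)
        assert ds2.steps == ds.steps
        assert ds2.proteins == ds.proteins
        assert ds2.target_protein == ds.target_protein
        assert dict(ds2.resins) == dict(ds.resins)
        assert dict(ds2.conditions) == dict(ds.conditions)
        for s in ds.steps:
            g, g2 = ds.gradients[s], ds2.gradients[s]
            assert g2.phases == g.phases
            assert g2.salt_mM == g.salt_mM
        for key, rec in ds.records.items():
            rec2 = ds2.records[key]
            assert dict(rec2.loaded_mass) == dict(rec.loaded_mass)
            cm = rec.collected_array(ds.proteins, ds.n_intervals(key[0]))
            cm2 = rec2.collected_array(ds.proteins, ds.n_intervals(key[0]))
            np.testing.assert_array_equal(cm, cm2)

    def test_missing_file_is_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="missing input file"):
            load_dataset(tmp_path)

    def test_overcollection_in_files_is_rejected(self, tmp_path):
        ds = make_minimal_dataset()
        write_dataset(ds, tmp_path)
        coll = tmp_path / "collected.csv"
        coll.write_text(
            "step,resin,condition,protein,interval,collected_mass_mg\n"
            "S1,R1,C1,p1,T2,9.0\nS1,R1,C1,p1,T3,3.0\n"
        )
        with pytest.raises(ValidationError, match="exceeds"):
            load_dataset(tmp_path)
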