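"""Dietary computations: sum variables, unit rescaling, breastfed energy
imputation, nutrient density, early-intake means, sensitivity exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fajoint.nutrients import (EnergyRequirement, breastmilk_amount,
                               energy_adjust, exclude_prediagnosis_records,
                               impute_breastfed_energy, mean_early_intake)
from fajoint.variables import (LC_N3_COMPONENTS, VARIABLES, Unit,
                               compose_sum_variable, rescale_intake)


class TestSumVariable:
    LC = VARIABLES["lc_n3_pufa"]

    def test_component_addition(self):
        intakes = dict(zip(LC_N3_COMPONENTS, [0.3, 0.2, 0.0, 0, 0, 0.04, 0.01]))
        assert np.isclose(compose_sum_variable(intakes, self.LC), 0.55)

    def test_empty_map_warns_zero(self):
        with pytest.warns(UserWarning):
            assert compose_sum_variable({}, self.LC) == 0.0

    def test_matches_brute_force_on_generated_records(self, small_cohort):
        _, _, rec = small_cohort
        got = compose_sum_variable(rec, self.LC)
        brute = sum(rec[c] for c in LC_N3_COMPONENTS)
        assert np.allclose(got, brute)

    @given(st.permutations(list(range(7))))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        vals = [0.1, 0.25, 0.03, 0.0, 0.5, 0.07, 0.11]
        intakes = {LC_N3_COMPONENTS[i]: vals[i] for i in perm}
        assert np.isclose(compose_sum_variable(intakes, self.LC), sum(vals))


class TestRescale:
    def test_printed_unit_examples(self):
        # 1.04 g/day on the 100 mg scale -> 10.4; 0.038 g/day on 10 mg -> 3.8
        assert np.isclose(rescale_intake(1.04, Unit("mg100_per_day")), 10.4)
        assert np.isclose(rescale_intake(0.038, Unit("mg10_per_day")), 3.8)
        assert rescale_intake(0.0, Unit("g_per_day")) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rescale_intake(-0.1, Unit("g_per_day"))
        with pytest.raises(ValueError):
            Unit("kg_per_day")


class TestBreastfedEnergy:
    REQ = EnergyRequirement.default()

    def test_requirement_monotone_in_weight(self):
        assert self.REQ.requirement(0.25, 7.0) > self.REQ.requirement(0.25, 6.0)
        assert self.REQ.requirement(0.25, 6.0) > 0

    def test_shortfall_is_breastmilk_energy(self):
        req = self.REQ.requirement(0.25, 6.1)
        total, bm = impute_breastfed_energy(req - 0.8, 0.25, True, self.REQ,
                                            weight_kg=6.1)
        assert np.isclose(total, req) and np.isclose(bm, 0.8)

    def test_overreported_food_floors_at_zero(self):
        total, bm = impute_breastfed_energy(9.9, 0.25, True, self.REQ,
                                            weight_kg=6.1)
        assert bm == 0.0 and np.isclose(total, self.REQ.requirement(0.25, 6.1))

    def test_non_breastfed_passthrough(self):
        total, bm = impute_breastfed_energy(2.2, 0.5, False, self.REQ)
        assert (total, bm) == (2.2, 0.0)

    def test_missing_weight_uses_default_table(self):
        total, _ = impute_breastfed_energy(1.0, 0.25, True, self.REQ)
        assert np.isclose(total, self.REQ.requirement(
            0.25, self.REQ.default_weight(0.25)))

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            self.REQ.requirement(0.25, float("nan"))


class TestBreastmilkAmount:
    def test_energy_to_grams(self):
        # 0.8 MJ/day at 2.8 kJ/g -> 285.714 g/day
        assert np.isclose(breastmilk_amount(0.8, 2.8), 800 / 2.8)
        assert breastmilk_amount(0.0, 2.8) == 0.0

    def test_density_proportionality(self):
        assert np.isclose(breastmilk_amount(0.8, 5.6),
                          breastmilk_amount(0.8, 2.8) / 2)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            breastmilk_amount(0.8, 0.0)


class TestEnergyAdjust:
    def test_density_definition(self):
        assert energy_adjust(5.0, 5.0) == 1.0
        assert np.isclose(energy_adjust(10.4, 4.0), 2.6)

    def test_roundtrip_identity(self, rng):
        intake = rng.uniform(0.1, 50, 100)
        energy = rng.uniform(1, 8, 100)
        assert np.allclose(energy_adjust(intake, energy) * energy, intake)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_adjust(5.0, 0.0)


class TestMeanEarlyIntake:
    def _records(self, ages, vals, energies):
        return pd.DataFrame({"age": ages, "total_fat": vals,
                             "energy_mj": energies})

    def test_mean_of_both_visits(self):
        r = self._records([0.25, 0.5], [4.0, 9.0], [2.0, 3.0])
        assert mean_early_intake(r, "total_fat") == 2.5
        assert mean_early_intake(r, "total_fat", energy_adjusted=False) == 6.5

    def test_single_visit(self):
        r = self._records([0.25, 2.0], [4.0, 9.0], [2.0, 3.0])
        assert mean_early_intake(r, "total_fat") == 2.0

    def test_absent_sentinel(self):
        r = self._records([1.0, 2.0], [4.0, 9.0], [2.0, 3.0])
        assert np.isnan(mean_early_intake(r, "total_fat"))


class TestPrediagnosisExclusion:
    def _cohort(self):
        children = pd.DataFrame({
            "child_id": ["a", "b"],
            "t1d_status": [1, 0],
            "t1d_age": [4.0, np.nan],
        })
        records = pd.DataFrame({
            "child_id": ["a"] * 3 + ["b"] * 3,
            "age": [2.0, 3.0, 4.0, 2.0, 3.0, 4.0],
        })
        return children, records

    def test_threshold_keeps_only_early_records(self):
        children, records = self._cohort()
        kept, dropped = exclude_prediagnosis_records(records, children, 1.5)
        assert dropped == 2
        assert list(kept[kept.child_id == "a"].age) == [2.0]
        assert list(kept[kept.child_id == "b"].age) == [2.0, 3.0, 4.0]

    def test_idempotent(self):
        children, records = self._cohort()
        once, _ = exclude_prediagnosis_records(records, children)
        twice, d2 = exclude_prediagnosis_records(once, children)
        assert d2 == 0 and once.equals(twice)

    def test_count_matches_brute_force_on_cohort(self, small_cohort):
        _, ch, rec = small_cohort
        kept, dropped = exclude_prediagnosis_records(rec, ch, 1.5)
        t1d_age = ch.set_index("child_id").t1d_age
        brute = sum(
            1 for _, r in rec.iterrows()
            if r.child_id in t1d_age.index
            and pd.notna(t1d_age[r.child_id])
            and r.age > t1d_age[r.child_id] - 1.5)
        assert dropped == brute and len(kept) == len(rec) - brute

    def test_negative_window_rejected(self):
        children, records = self._cohort()
        with pytest.raises(ValueError):
            exclude_prediagnosis_records(records, children, -1.0)
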