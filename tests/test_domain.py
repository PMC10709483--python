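import dataclasses
import itertools

import pytest

from bedplan.domain import (
    Bed,
    Plan,
    candidate_beds,
    candidate_patients,
    restrict_scope,
    room_day_state,
    validate_instance,
)
from bedplan.synthetic import generate_tiny_instance

from conftest import make_instance, make_patient


class TestValidateInstance:
    def test_well_formed_toy_is_clean(self, toy_instance):
        assert validate_instance(toy_instance) == []

    def test_duplicate_bed_id_is_reported(self, toy_instance):
        beds = toy_instance.beds + (Bed(1, 1),)
        bad = dataclasses.replace(toy_instance, beds=beds)
        assert any("duplicate bed id" in v and "bed 1" in v
                   for v in validate_instance(bad))

    @pytest.mark.parametrize("field,value,fragment", [
        ("gender", 0, "gender"),
        ("age", 150, "age"),
        ("los", 0, "length of stay"),
        ("department", 99, "department"),
    ])
    def test_patient_domain_rules(self, field, value, fragment):
        patient = dataclasses.replace(make_patient(1), **{field: value})
        inst = make_instance([patient])
        report = validate_instance(inst)
        assert any(fragment in v for v in report)


class TestRoomDayState:
    def test_empty_room_convention(self, toy_instance, empty_plan):
        state = room_day_state(2, 1, empty_plan, toy_instance)
        assert (state.a_max, state.a_min, state.empty) == (0, 120, True)

    def test_single_prior_occupant(self, toy_instance):
        plan = Plan(fixed={1: 1})
        state = room_day_state(1, 1, plan, toy_instance)
        assert (state.a_max, state.a_min, state.empty) == (70, 70, False)
        assert state.department == 1

    def test_department_homogeneous_priors(self):
        inst = make_instance([make_patient(1, department=2, los=2),
                              make_patient(2, department=2, los=2)])
        plan = Plan(fixed={1: 1, 2: 2})
        assert room_day_state(1, 1, plan, inst).department == 2

    def test_mixed_departments_give_no_common_id(self):
        inst = make_instance([make_patient(1, department=2, los=2),
                              make_patient(2, department=5, los=2)])
        plan = Plan(fixed={1: 1, 2: 2})
        assert room_day_state(1, 1, plan, inst).department is None

    def test_unknown_room_raises(self, toy_instance, empty_plan):
        with pytest.raises(KeyError):
            room_day_state(99, 1, empty_plan, toy_instance)

    def test_pure_function_of_inputs(self, toy_instance):
        plan = Plan(fixed={1: 1})
        a = room_day_state(1, 1, plan, toy_instance)
        b = room_day_state(1, 1, plan, toy_instance)
        assert a == b


class TestCandidateBeds:
    def test_empty_hospital_all_beds(self, toy_instance, empty_plan):
        p = toy_instance.patient_by_id[1]
        assert candidate_beds(p, empty_plan, toy_instance) == {1, 2, 3, 4}

    def test_gender_conflict_excludes_room(self):
        male = make_patient(1, gender=-1, los=2)
        female = make_patient(2, gender=1, los=2)
        inst = make_instance([male, female])
        plan = Plan(fixed={1: 1})  # male occupies bed 1 (room 1)
        assert candidate_beds(female, plan, inst) == {3, 4}

    def test_missing_infrastructure_excludes_bed(self, toy_instance):
        p = make_patient(9, requirements={"telemetry"})
        assert candidate_beds(p, Plan(), toy_instance) == set()

    def test_blocked_day_excludes_bed(self):
        inst = make_instance([make_patient(1, los=2)])
        blocked = dataclasses.replace(inst.beds[0], blocked_days=frozenset({2}))
        inst = dataclasses.replace(inst, beds=(blocked,) + inst.beds[1:])
        p = inst.patient_by_id[1]
        assert 1 not in candidate_beds(p, Plan(), inst)

    def test_isolating_patient_needs_empty_room(self):
        iso = make_patient(2, isolation=True, los=2)
        inst = make_instance([make_patient(1, los=2), iso])
        plan = Plan(fixed={1: 1})
        assert candidate_beds(iso, plan, inst) == {3, 4}

    def test_nobody_joins_isolated_prior(self):
        iso = make_patient(1, isolation=True, los=2)
        newcomer = make_patient(2, los=2)
        inst = make_instance([iso, newcomer])
        plan = Plan(fixed={1: 1})
        assert candidate_beds(newcomer, plan, inst) == {3, 4}


class TestCandidatePatients:
    def test_occupied_bed_has_no_candidates(self, toy_instance):
        plan = Plan(fixed={1: 1})
        assert candidate_patients(1, 1, plan, toy_instance) == set()

    def test_compatible_patient_on_stay_day(self, toy_instance, empty_plan):
        assert 1 in candidate_patients(1, 2, empty_plan, toy_instance)

    def test_duality_with_candidate_beds(self):
        """p in P_{b,t}  <=>  b in B_p and t in p's stay (exhaustive)."""
        for seed in range(8):
            inst = generate_tiny_instance(n_beds=5, n_patients=5, horizon=2,
                                          seed=seed)
            plan = Plan()
            bp = {p.id: candidate_beds(p, plan, inst) for p in inst.patients}
            for bed, t in itertools.product(inst.beds, inst.horizon):
                pbt = candidate_patients(bed.id, t, plan, inst)
                for p in inst.patients:
                    expected = bed.id in bp[p.id] and p.present(t)
                    assert (p.id in pbt) == expected


class TestRestrictScope:
    def test_free_hospital_keeps_everything(self, toy_instance, empty_plan):
        beds, patients = restrict_scope(toy_instance, empty_plan)
        assert set(beds) == {1, 2, 3, 4}
        assert patients == [1]

    def test_bed_occupied_past_horizon_is_dropped(self):
        lingerer = make_patient(1, los=5)  # stays past the 2-day horizon
        inst = make_instance([lingerer, make_patient(2)])
        beds, patients = restrict_scope(inst, Plan(fixed={1: 1}))
        assert 1 not in beds
        assert patients == [2]

    def test_overflow_patient_is_open(self):
        waiting = make_patient(1, overflow_entry=-1, los=2)
        inst = make_instance([waiting])
        _beds, patients = restrict_scope(inst, Plan())
        assert patients == [1]

    def test_never_drops_a_patient_needing_a_bed(self):
        for seed in range(10):
            inst = generate_tiny_instance(n_beds=6, n_patients=6, horizon=3,
                                          seed=100 + seed)
            _beds, patients = restrict_scope(inst, Plan())
            needing = {p.id for p in inst.patients
                       if any(t in inst.horizon for t in p.stay_days())}
            assert needing <= set(patients)
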