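import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedplan.domain import Params, Plan
from bedplan.synthetic import generate_tiny_instance
from bedplan.utility import (
    department_homogeneity,
    feasibility_violations,
    marginal_utility,
    overflow_bonus,
    patient_assignment_utility,
    q_weight,
    room_age_spread,
    total_utility,
    ward_overload,
)

from conftest import make_instance, make_patient


class TestQWeight:
    @pytest.mark.parametrize("t,q,expected", [
        (1, 0.01, 0.99),
        (2, 0.01, 0.9801),
        (3, 0.0, 1.0),
    ])
    def test_printed_values(self, t, q, expected):
        assert q_weight(t, q) == pytest.approx(expected, abs=1e-12)

    def test_rejects_day_before_horizon(self):
        with pytest.raises(ValueError):
            q_weight(0, 0.01)

    @given(q=st.floats(0.001, 0.999), t=st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_and_in_unit_interval(self, q, t):
        assert 0 < q_weight(t + 1, q) < q_weight(t, q) <= 1.0


class TestOverflowBonus:
    def test_never_in_overflow_is_zero(self):
        assert overflow_bonus(make_patient(1), current_day=1) == 0.0

    def test_linear_in_waiting_days(self):
        p = make_patient(1, overflow_entry=-1)
        assert overflow_bonus(p, current_day=1, omega=1.0) == 2.0
        assert overflow_bonus(p, current_day=2) > overflow_bonus(p, current_day=1)

    def test_negative_wait_is_an_error(self):
        p = make_patient(1, overflow_entry=5)
        with pytest.raises(ValueError):
            overflow_bonus(p, current_day=1)


class TestTermContributions:
    def test_elective_two_day_stay(self, toy_instance, empty_plan):
        p = toy_instance.patient_by_id[1]
        u = patient_assignment_utility(p, 1, empty_plan, toy_instance)
        assert u == pytest.approx(10 * (0.99 + 0.9801))  # 19.701

    def test_blocked_stay_day_zeroes_term(self, toy_instance):
        blocked = dataclasses.replace(toy_instance.beds[0],
                                      blocked_days=frozenset({2}))
        inst = dataclasses.replace(toy_instance,
                                   beds=(blocked,) + toy_instance.beds[1:])
        p = inst.patient_by_id[1]
        assert patient_assignment_utility(p, 1, Plan(), inst) == 0.0

    def test_anticipated_one_day(self):
        p = make_patient(1, ptype="anticipated", los=1)
        inst = make_instance([p])
        u = patient_assignment_utility(p, 1, Plan(), inst)
        assert u == pytest.approx(4 * 0.99)

    def test_age_spread_cases(self):
        inst = make_instance([make_patient(1, age=70, los=2),
                              make_patient(2, age=80, los=2)])
        plan = Plan(assignments={1: 1, 2: 2})
        assert room_age_spread(1, 1, plan, inst) == 10.0
        assert room_age_spread(1, 1, Plan(assignments={1: 1}), inst) == 0.0
        assert room_age_spread(2, 1, plan, inst) == 0.0  # empty room

    def test_department_homogeneity_semantics(self):
        inst = make_instance([make_patient(1, department=3, los=1),
                              make_patient(2, department=3, los=1),
                              make_patient(3, department=2, los=1),
                              make_patient(4, department=5, los=1)])
        # empty room, two same-department assignees
        assert department_homogeneity(1, 1, Plan(assignments={1: 1, 2: 2}), inst) == 1
        # empty room, no assignee
        assert department_homogeneity(1, 1, Plan(), inst) == 0
        # room pre-occupied by dept 2, assignee dept 5
        plan = Plan(fixed={3: 1}, assignments={4: 2})
        assert department_homogeneity(1, 1, plan, inst) == 0

    def test_ward_overload_cases(self):
        inst = make_instance([make_patient(i, care=1.0, los=1) for i in (1, 2, 3)],
                             capacity=2.0, n_rooms=2, beds_per_room=2)
        plan = Plan(assignments={1: 1, 2: 2, 3: 3})
        assert ward_overload(1, 1, plan, inst) == 1.0
        assert ward_overload(1, 1, Plan(assignments={1: 1}), inst) == 0.0
        zero_cap = make_instance([make_patient(1, care=1.0, los=1)], capacity=0.0)
        assert ward_overload(1, 1, Plan(assignments={1: 1}), zero_cap) == 1.0


class TestTotalUtility:
    def test_empty_plan_is_zero(self, toy_instance):
        assert total_utility(Plan(), toy_instance).total == 0.0

    def test_single_elective_alone(self, toy_instance):
        # term1 = 10*(0.99+0.9801); department bonus on both stay days
        u = total_utility(Plan(assignments={1: 1}), toy_instance)
        assert u.term1 == pytest.approx(19.701)
        assert u.term3 == 2
        assert u.total == pytest.approx(19.701 + 2 * 2)

    def test_roommate_adds_term1_and_age_penalty(self, toy_instance):
        mate = make_patient(2, age=80, department=1, los=2)
        inst = dataclasses.replace(toy_instance,
                                   patients=toy_instance.patients + (mate,))
        u = total_utility(Plan(assignments={1: 1, 2: 2}), inst)
        assert u.term1 == pytest.approx(2 * 19.701)
        assert u.term2 == pytest.approx(10 * 2)  # spread 10 on both days
        assert u.total == pytest.approx(2 * 19.701 - 0.1 * 20 + 2 * 2)

    def test_infeasible_plan_raises(self, toy_instance):
        with pytest.raises(ValueError, match="double booking"):
            mate = make_patient(2, los=2)
            inst = dataclasses.replace(toy_instance,
                                       patients=toy_instance.patients + (mate,))
            total_utility(Plan(assignments={1: 1, 2: 1}), inst)


class TestMarginalUtility:
    def test_first_assignment_equals_total(self, toy_instance):
        p = toy_instance.patient_by_id[1]
        m = marginal_utility(p, 1, Plan(), toy_instance)
        assert m == pytest.approx(total_utility(Plan(assignments={1: 1}),
                                                toy_instance).total)

    def test_infeasible_pair_is_zero(self, toy_instance):
        p = toy_instance.patient_by_id[1]
        assert marginal_utility(p, 1, Plan(fixed={1: 1}), toy_instance) == 0.0

    def test_matches_from_scratch_difference(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 200:
            inst = generate_tiny_instance(n_beds=5, n_patients=5, horizon=2,
                                          seed=int(rng.integers(2 ** 31)))
            plan = Plan()
            for p in inst.patients:
                beds = sorted(b.id for b in inst.beds)
                bid = int(rng.choice(beds))
                before = total_utility(plan, inst, check_feasible=False).total
                m = marginal_utility(p, bid, plan, inst)
                if m == 0.0:
                    continue
                plan.assignments[p.id] = bid
                after = total_utility(plan, inst, check_feasible=False).total
                assert m == pytest.approx(after - before, abs=1e-9)
                checked += 1


class TestFeasibilityViolations:
    def test_feasible_toy_plan_is_clean(self, toy_instance):
        assert feasibility_violations(Plan(assignments={1: 1}), toy_instance) == []

    def test_gender_mixing_is_reported(self):
        inst = make_instance([make_patient(1, gender=-1, los=1),
                              make_patient(2, gender=1, los=1)])
        report = feasibility_violations(Plan(assignments={1: 1, 2: 2}), inst)
        assert any("mixed-gender" in v for v in report)

    def test_double_booking_is_reported(self):
        inst = make_instance([make_patient(1, los=1), make_patient(2, los=1)])
        report = feasibility_violations(Plan(assignments={1: 1, 2: 1}), inst)
        assert any("double booking" in v for v in report)

    def test_overload_conservation(self):
        """Sum of per-ward-day overloads equals brute-force max(0, load - C)."""
        rng = np.random.default_rng(3)
        for seed in range(5):
            inst = generate_tiny_instance(n_beds=6, n_patients=6, horizon=2,
                                          seed=seed)
            plan = Plan()
            for p in inst.patients:
                bid = int(rng.choice([b.id for b in inst.beds]))
                if marginal_utility(p, bid, plan, inst) != 0.0:
                    plan.assignments[p.id] = bid
            u = total_utility(plan, inst, check_feasible=False)
            expected = 0.0
            for w in inst.wards:
                ward_beds = {b for r in w.room_ids
                             for b in inst.beds_in_room(r)}
                for t in inst.horizon:
                    load = sum(inst.patient_by_id[pid].care_level
                               for pid, b in plan.assigned_patients().items()
                               if b in ward_beds and inst.patient_by_id[pid].present(t))
                    expected += max(0.0, load - w.capacity(t))
            assert u.term4 == pytest.approx(expected)
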