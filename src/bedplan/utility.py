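"""Objective evaluation and feasibility for patient-bed assignment.

The total utility of a plan combines four weighted stakeholder terms:

``U = alpha*T1 - beta*T2 + gamma*T3 - delta*T4``

* T1 -- basic patient utility: for every assigned patient,
  ``OF_p + Xi_p * sum(Q_t)`` over the in-horizon days of the stay, where
  ``Q_t = (1-q)**t`` discounts far-future days and ``OF_p`` rewards patients
  who already waited in overflow.
* T2 -- patient compatibility: per room-day age spread (max age - min age)
  over everyone present; empty and single-occupant room-days contribute 0.
* T3 -- doctor walking distance: +1 per room-day where at least one patient
  is newly assigned and the room is department-homogeneous (for pre-occupied
  rooms, all assignees must match the prior occupants' common department).
* T4 -- nurse workload: per ward-day care overload
  ``max(0, sum c_p of newly assigned present patients - C_{w,t})``.

Feasibility mirrors the hard model constraints: at most one bed per patient,
one patient per bed-day, single-gender rooms, infrastructure and isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .domain import (
    Instance,
    Params,
    Patient,
    Plan,
    candidate_beds,
    new_occupants,
    prior_occupants,
)


def q_weight(t: int, q: float) -> float:
    """Time-relevance weight Q_t = (1-q)**t, strictly decreasing for q in (0,1)."""
    if t < 1:
        raise ValueError(f"day index must be >= 1, got {t}")
    if not 0 <= q < 1:
        raise ValueError(f"decay q must be in [0, 1), got {q}")
    return (1.0 - q) ** t


def overflow_bonus(patient: Patient, current_day: int, omega: float = 1.0) -> float:
    """OF_p: omega per whole day the patient has already spent in overflow."""
    if patient.overflow_entry_day is None:
        return 0.0
    waited = current_day - patient.overflow_entry_day
    if waited < 0:
        raise ValueError(
            f"patient {patient.id}: overflow entry day {patient.overflow_entry_day} "
            f"after current day {current_day}"
        )
    return omega * waited


def patient_assignment_utility(patient: Patient, bed_id: int, plan: Plan,
                               instance: Instance, params: Optional[Params] = None) -> float:
    """First-term contribution of assigning this patient to this bed.

    Zero if any in-horizon stay day is infeasible for the bed (blocked or
    pre-occupied), mirroring the candidate-set restriction.
    """
    params = params or instance.params
    if bed_id not in candidate_beds(patient, plan, instance):
        return 0.0
    current = instance.horizon[0]
    total_q = sum(q_weight(t, params.q) for t in patient.stay_days() if t in instance.horizon)
    return overflow_bonus(patient, current, params.overflow_rate) + params.xi(patient) * total_q


def _people_present(room_id: int, day: int, plan: Plan, instance: Instance):
    return (prior_occupants(room_id, day, plan, instance),
            new_occupants(room_id, day, plan, instance))


def room_age_spread(room_id: int, day: int, plan: Plan, instance: Instance) -> float:
    """Age spread over everyone in the room that day; 0 for <= 1 person."""
    prior, new = _people_present(room_id, day, plan, instance)
    ages = [p.age for p in prior + new]
    if len(ages) <= 1:
        return 0.0
    return float(max(ages) - min(ages))


def department_homogeneity(room_id: int, day: int, plan: Plan, instance: Instance) -> int:
    """Department bonus indicator for this room-day (y or z semantics).

    Initially empty room: 1 iff >= 1 patient is newly assigned and all
    assignees share one department.  Pre-occupied room: 1 iff >= 1 patient is
    newly assigned, prior occupants are department-homogeneous, and every
    assignee matches that department.
    """
    prior, new = _people_present(room_id, day, plan, instance)
    if not new:
        return 0
    new_depts = {p.department for p in new}
    if not prior:
        return int(len(new_depts) == 1)
    prior_depts = {p.department for p in prior}
    return int(len(prior_depts) == 1 and new_depts == prior_depts)


def ward_overload(ward_id: int, day: int, plan: Plan, instance: Instance) -> float:
    """o+_{w,t}: care load of newly assigned patients above spare capacity."""
    ward = instance.ward_by_id[ward_id]
    load = 0.0
    assigned = plan.assigned_patients()
    for pid, bid in assigned.items():
        if instance.ward_of_bed(bid).id != ward_id:
            continue
        if instance.patient_by_id[pid].present(day):
            load += instance.patient_by_id[pid].care_level
    return max(0.0, load - ward.capacity(day))


@dataclass
class UtilityBreakdown:
    term1: float
    term2: float
    term3: float
    term4: float
    total: float
    room_day: dict = field(default_factory=dict)  # (room, day) -> (spread, homog)
    ward_day: dict = field(default_factory=dict)  # (ward, day) -> overload

    def as_dict(self) -> dict:
        return {
            "term1_patient_utility": self.term1,
            "term2_age_spread": self.term2,
            "term3_department_bonus": self.term3,
            "term4_ward_overload": self.term4,
            "total": self.total,
            "room_day": {f"{r}@{t}": v for (r, t), v in self.room_day.items()},
            "ward_day": {f"{w}@{t}": v for (w, t), v in self.ward_day.items()},
        }


def total_utility(plan: Plan, instance: Instance,
                  params: Optional[Params] = None,
                  check_feasible: bool = True) -> UtilityBreakdown:
    """Assemble the four objective terms for a (feasible) plan."""
    params = params or instance.params
    if check_feasible:
        violations = feasibility_violations(plan, instance)
        if violations:
            raise ValueError("infeasible plan: " + "; ".join(violations))
    t1 = sum(
        patient_assignment_utility(instance.patient_by_id[pid], bid, plan, instance, params)
        for pid, bid in plan.assigned_patients().items()
    )
    t2 = t3 = t4 = 0.0
    room_day = {}
    for room in instance.rooms:
        for t in instance.horizon:
            spread = room_age_spread(room.id, t, plan, instance)
            homog = department_homogeneity(room.id, t, plan, instance)
            if spread or homog:
                room_day[(room.id, t)] = (spread, homog)
            t2 += spread
            t3 += homog
    ward_day = {}
    for ward in instance.wards:
        for t in instance.horizon:
            o = ward_overload(ward.id, t, plan, instance)
            if o:
                ward_day[(ward.id, t)] = o
            t4 += o
    total = params.alpha * t1 - params.beta * t2 + params.gamma * t3 - params.delta * t4
    return UtilityBreakdown(t1, t2, t3, t4, total, room_day, ward_day)


# ---------------------------------------------------------------------------
# assignment feasibility & marginal utility
# ---------------------------------------------------------------------------

def assignment_feasible(patient: Patient, bed_id: int, plan: Plan, instance: Instance,
                        bp: Optional[set] = None) -> bool:
    """Can `patient` be assigned to `bed_id` given the current partial plan?

    `bp` may carry a precomputed candidate-bed set B_p (priors only) to avoid
    recomputation inside solver loops.
    """
    if patient.id in plan.assignments or patient.id in plan.fixed:
        return False
    if bp is None:
        bp = candidate_beds(patient, plan, instance)
    if bed_id not in bp:
        return False
    days = [t for t in patient.stay_days() if t in instance.horizon]
    room = instance.room_of_bed(bed_id)
    assigned = plan.assigned_patients()
    room_beds = set(room.bed_ids)
    for qid, qbid in assigned.items():
        other = instance.patient_by_id[qid]
        overlap = any(other.present(t) for t in days)
        if not overlap:
            continue
        if qbid == bed_id:
            return False  # bed-day already taken this run
        if qbid in room_beds:
            if other.gender != patient.gender:
                return False
            if other.isolation or patient.isolation:
                return False
    return True


def marginal_utility(patient: Patient, bed_id: int, plan: Plan, instance: Instance,
                     params: Optional[Params] = None,
                     bp: Optional[set] = None) -> float:
    """U_{b,p}: added total utility of one extra assignment; 0 if infeasible.

    Computed as a local delta over the affected room-days and ward-days,
    which equals the from-scratch total-utility difference.
    """
    params = params or instance.params
    if not assignment_feasible(patient, bed_id, plan, instance, bp=bp):
        return 0.0
    t1 = patient_assignment_utility(patient, bed_id, plan, instance, params)
    room = instance.room_of_bed(bed_id)
    ward = instance.ward_of_bed(bed_id)
    days = [t for t in patient.stay_days() if t in instance.horizon]

    after = plan.copy()
    after.assignments[patient.id] = bed_id
    d2 = d3 = d4 = 0.0
    for t in days:
        d2 += (room_age_spread(room.id, t, after, instance)
               - room_age_spread(room.id, t, plan, instance))
        d3 += (department_homogeneity(room.id, t, after, instance)
               - department_homogeneity(room.id, t, plan, instance))
        d4 += (ward_overload(ward.id, t, after, instance)
               - ward_overload(ward.id, t, plan, instance))
    return params.alpha * t1 - params.beta * d2 + params.gamma * d3 - params.delta * d4


# ---------------------------------------------------------------------------
# feasibility
# ---------------------------------------------------------------------------

def feasibility_violations(plan: Plan, instance: Instance) -> list:
    """Empty list iff the plan satisfies all hard constraints."""
    violations = []
    for pid in plan.assignments:
        if pid in plan.fixed:
            violations.append(f"patient {pid}: assigned while already in a fixed bed")
    for source in ("fixed", "assignments"):
        for pid, bid in getattr(plan, source).items():
            if pid not in instance.patient_by_id:
                violations.append(f"patient {pid}: unknown patient in plan")
            if bid != "OVERFLOW" and bid is not None and bid not in instance.bed_by_id:
                violations.append(f"bed {bid}: unknown bed in plan (patient {pid})")
    if violations:
        return violations

    # one patient per bed-day; blocked days respected
    cal = {}
    everyone = dict(plan.fixed)
    everyone.update(plan.assigned_patients())
    for pid, bid in everyone.items():
        patient = instance.patient_by_id[pid]
        bed = instance.bed_by_id[bid]
        for t in patient.stay_days():
            if t not in instance.horizon:
                continue
            if t in bed.blocked_days:
                violations.append(f"bed {bid} day {t}: occupied by patient {pid} while blocked")
            key = (bid, t)
            if key in cal:
                violations.append(
                    f"bed {bid} day {t}: double booking (patients {cal[key]} and {pid})")
            cal[key] = pid

    # infrastructure (new assignments only; fixed occupancy is historical fact)
    for pid, bid in plan.assigned_patients().items():
        patient = instance.patient_by_id[pid]
        if not patient.requirements <= instance.bed_by_id[bid].features:
            missing = set(patient.requirements) - set(instance.bed_by_id[bid].features)
            violations.append(f"patient {pid}: bed {bid} lacks required {sorted(missing)}")

    # room-day gender homogeneity and isolation
    for room in instance.rooms:
        for t in instance.horizon:
            prior = prior_occupants(room.id, t, plan, instance)
            new = new_occupants(room.id, t, plan, instance)
            people = prior + new
            if len(people) <= 1:
                continue
            if len({p.gender for p in people}) > 1:
                violations.append(f"room {room.id} day {t}: mixed-gender occupancy")
            if any(p.isolation for p in people):
                violations.append(f"room {room.id} day {t}: isolation patient not alone")
    return violations
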