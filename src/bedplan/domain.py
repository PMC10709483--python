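"""Core domain model for operational patient-bed assignment (PBA).

A hospital instance is a ward/room/bed topology plus a set of inpatients to
be placed over a short planning horizon of days ``t = 1..|T|``.  A patient's
stay is the half-open day interval ``[arrival, arrival + los)``; discharge-day
bed reuse follows from the half-open convention.  Patients that cannot be
given a bed wait in an overflow buffer (hallways, treatment rooms) and are
reconsidered at the next planning run.

The module distinguishes *prior occupants* -- patients already fixed in a bed
before the current planning run -- from the open patients the solvers decide
on.  Candidate-set computation (which beds fit which patient and vice versa)
encodes the hard compatibility rules: bed availability, required bed
infrastructure, single-gender rooms, and medical isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

OVERFLOW = "OVERFLOW"

ELECTIVE = "elective"
EMERGENCY = "emergency"
ANTICIPATED = "anticipated"

PATIENT_TYPES = (ELECTIVE, EMERGENCY, ANTICIPATED)


@dataclass(frozen=True)
class Params:
    """Objective weights and model constants.

    Defaults mirror the weights applied operationally in a large maximum-care
    hospital: ``alpha=1`` (basic patient utility), ``beta=0.1`` (age-spread
    penalty), ``gamma=2`` (department-homogeneity bonus for doctors),
    ``delta=2`` (ward care-overload penalty for nurses), day-relevance decay
    ``q=0.01`` with ``Q_t = (1-q)**t``, and patient-type weights
    ``Xi = 10 / 9 / 4`` for elective / emergency / anticipated patients.

    ``overflow_rate`` (omega) is the utility bonus per whole day a patient
    has already waited in overflow, prioritising long-waiting patients.
    """

    alpha: float = 1.0
    beta: float = 0.1
    gamma: float = 2.0
    delta: float = 2.0
    q: float = 0.01
    xi_elective: float = 10.0
    xi_emergency: float = 9.0
    xi_anticipated: float = 4.0
    overflow_rate: float = 1.0
    max_age: int = 120
    big_m: Optional[int] = None

    def xi(self, patient: "Patient") -> float:
        if patient.weight is not None:
            return patient.weight
        return {
            ELECTIVE: self.xi_elective,
            EMERGENCY: self.xi_emergency,
            ANTICIPATED: self.xi_anticipated,
        }[patient.ptype]


@dataclass(frozen=True)
class Bed:
    id: int
    room_id: int
    features: frozenset = frozenset()
    blocked_days: frozenset = frozenset()


@dataclass(frozen=True)
class Room:
    id: int
    ward_id: int
    bed_ids: tuple


@dataclass(frozen=True)
class Ward:
    id: int
    room_ids: tuple
    #: spare care capacity C_{w,t} for *further* (newly assigned) patients
    spare_capacity: Mapping[int, float] = field(default_factory=dict)

    def capacity(self, day: int) -> float:
        return self.spare_capacity.get(day, 0.0)


@dataclass(frozen=True)
class Patient:
    id: int
    gender: int  # -1 male, +1 female
    age: int
    department: int
    care_level: float = 1.0
    ptype: str = ELECTIVE
    registration_day: int = 1
    arrival_day: int = 1
    los: int = 1
    overflow_entry_day: Optional[int] = None
    requirements: frozenset = frozenset()
    isolation: bool = False
    weight: Optional[float] = None  # overrides the type default Xi_p

    def stay_days(self) -> range:
        """Half-open occupied-day interval [arrival, arrival + los)."""
        return range(self.arrival_day, self.arrival_day + self.los)

    def present(self, day: int) -> bool:
        return self.arrival_day <= day < self.arrival_day + self.los


@dataclass(frozen=True)
class Instance:
    wards: tuple
    rooms: tuple
    beds: tuple
    departments: tuple
    patients: tuple
    horizon: range  # 1..|T|
    params: Params = Params()

    def __post_init__(self):
        object.__setattr__(self, "bed_by_id", {b.id: b for b in self.beds})
        object.__setattr__(self, "room_by_id", {r.id: r for r in self.rooms})
        object.__setattr__(self, "ward_by_id", {w.id: w for w in self.wards})
        object.__setattr__(self, "patient_by_id", {p.id: p for p in self.patients})

    # -- topology lookups -------------------------------------------------
    def room_of_bed(self, bed_id: int) -> Room:
        return self.room_by_id[self.bed_by_id[bed_id].room_id]

    def ward_of_bed(self, bed_id: int) -> Ward:
        return self.ward_by_id[self.room_of_bed(bed_id).ward_id]

    def beds_in_room(self, room_id: int) -> tuple:
        return self.room_by_id[room_id].bed_ids

    def big_m(self) -> int:
        if self.params.big_m is not None:
            return self.params.big_m
        return max(self.departments) if self.departments else 1

    def with_patients(self, patients: Iterable[Patient]) -> "Instance":
        return replace(self, patients=tuple(patients))


@dataclass
class Plan:
    """Assignment state of one planning run.

    ``fixed`` holds prior occupants (patient id -> bed id); they are data,
    not decisions.  ``assignments`` holds this run's decisions: patient id ->
    bed id, or the :data:`OVERFLOW` sentinel.
    """

    fixed: dict = field(default_factory=dict)
    assignments: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def copy(self) -> "Plan":
        return Plan(dict(self.fixed), dict(self.assignments), dict(self.meta))

    def bed_of(self, patient_id: int):
        bed = self.assignments.get(patient_id, self.fixed.get(patient_id))
        return None if bed == OVERFLOW else bed

    def assigned_patients(self) -> dict:
        """This run's real bed assignments (overflow entries excluded)."""
        return {p: b for p, b in self.assignments.items() if b != OVERFLOW}

    def overflow_patients(self) -> set:
        return {p for p, b in self.assignments.items() if b == OVERFLOW}

    def occupancy_calendar(self, instance: Instance) -> dict:
        """(bed id, day) -> patient id over fixed and new assignments."""
        cal = {}
        for source in (self.fixed, self.assigned_patients()):
            for pid, bid in source.items():
                patient = instance.patient_by_id[pid]
                for t in patient.stay_days():
                    if t in instance.horizon:
                        cal[(bid, t)] = pid
        return cal


@dataclass(frozen=True)
class RoomDayState:
    """Prior-occupant summary of a room on one day.

    For an empty room the convention is ``a_max = 0`` and ``a_min`` equal to
    the maximum possible age (120 by default), with the empty flag ``F = 1``.
    ``department`` carries the common department id when all prior occupants
    share one department, else ``None``.
    """

    a_max: int
    a_min: int
    empty: bool  # F_{r,t}
    department: Optional[int]
    gender: Optional[int]


def prior_occupants(room_id: int, day: int, plan: Plan, instance: Instance) -> list:
    """Patients already fixed in a bed of this room and present on `day`."""
    beds = set(instance.beds_in_room(room_id))
    out = []
    for pid, bid in plan.fixed.items():
        if bid in beds and instance.patient_by_id[pid].present(day):
            out.append(instance.patient_by_id[pid])
    return out


def new_occupants(room_id: int, day: int, plan: Plan, instance: Instance) -> list:
    beds = set(instance.beds_in_room(room_id))
    out = []
    for pid, bid in plan.assigned_patients().items():
        if bid in beds and instance.patient_by_id[pid].present(day):
            out.append(instance.patient_by_id[pid])
    return out


def room_day_state(room_id: int, day: int, plan: Plan, instance: Instance) -> RoomDayState:
    if room_id not in instance.room_by_id:
        raise KeyError(f"unknown room id {room_id}")
    occ = prior_occupants(room_id, day, plan, instance)
    if not occ:
        return RoomDayState(0, instance.params.max_age, True, None, None)
    ages = [p.age for p in occ]
    depts = {p.department for p in occ}
    genders = {p.gender for p in occ}
    return RoomDayState(
        a_max=max(ages),
        a_min=min(ages),
        empty=False,
        department=depts.pop() if len(depts) == 1 else None,
        gender=genders.pop() if len(genders) == 1 else None,
    )


# ---------------------------------------------------------------------------
# candidate sets
# ---------------------------------------------------------------------------

def _stay_in_horizon(patient: Patient, instance: Instance) -> list:
    return [t for t in patient.stay_days() if t in instance.horizon]


def _bed_free(bed: Bed, days: Iterable[int], plan: Plan, instance: Instance) -> bool:
    days = list(days)
    if any(t in bed.blocked_days for t in days):
        return False
    for pid, bid in plan.fixed.items():
        if bid == bed.id:
            occupant = instance.patient_by_id[pid]
            if any(occupant.present(t) for t in days):
                return False
    return True


def _room_compatible(patient: Patient, room_id: int, days: Iterable[int],
                     plan: Plan, instance: Instance) -> bool:
    """Gender and isolation compatibility against prior occupants."""
    for t in days:
        occ = prior_occupants(room_id, t, plan, instance)
        if not occ:
            continue
        if patient.isolation:
            return False  # isolating patients need a room empty for the stay
        if any(o.isolation for o in occ):
            return False  # no one joins an isolated patient
        if any(o.gender != patient.gender for o in occ):
            return False
    return True


def candidate_beds(patient: Patient, plan: Plan, instance: Instance) -> set:
    """Subset of beds B_p available for this patient (prior occupants only).

    Conflicts with assignments made in the *current* run are handled by the
    solvers / feasibility checks, not by B_p.
    """
    days = _stay_in_horizon(patient, instance)
    if not days:
        return set()
    result = set()
    for bed in instance.beds:
        if not patient.requirements <= bed.features:
            continue
        if not _bed_free(bed, days, plan, instance):
            continue
        if not _room_compatible(patient, bed.room_id, days, plan, instance):
            continue
        result.add(bed.id)
    return result


def candidate_patients(bed_id: int, day: int, plan: Plan, instance: Instance) -> set:
    """Subset of patients P_{b,t} who fit bed b on day t (dual of B_p)."""
    if day not in instance.horizon:
        raise ValueError(f"day {day} outside planning horizon")
    out = set()
    for p in instance.patients:
        if p.id in plan.fixed:
            continue
        if p.present(day) and bed_id in candidate_beds(p, plan, instance):
            out.add(p.id)
    return out


def restrict_scope(instance: Instance, plan: Plan):
    """Relevant beds and patients for one planning run.

    Beds whose prior occupant stays to the end of the horizon (or beyond)
    are never vacated within it and are dropped.  Open patients are those
    without a fixed bed whose stay intersects the horizon: just-arrived
    patients, overflow patients, scheduled future electives, and anticipated
    emergencies.
    """
    t_end = instance.horizon[-1]
    blocked_to_end = set()
    for pid, bid in plan.fixed.items():
        occupant = instance.patient_by_id[pid]
        if occupant.arrival_day + occupant.los - 1 >= t_end:
            blocked_to_end.add(bid)
    relevant_beds = [b.id for b in instance.beds if b.id not in blocked_to_end]
    relevant_patients = [
        p.id for p in instance.patients
        if p.id not in plan.fixed and _stay_in_horizon(p, instance)
    ]
    return relevant_beds, relevant_patients


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_instance(instance: Instance) -> list:
    """Structural validation; returns a list of human-readable violations."""
    report = []
    seen = set()
    for b in instance.beds:
        if b.id in seen:
            report.append(f"bed {b.id}: duplicate bed id")
        seen.add(b.id)
        if b.room_id not in instance.room_by_id:
            report.append(f"bed {b.id}: unknown room {b.room_id}")
    seen = set()
    for r in instance.rooms:
        if r.id in seen:
            report.append(f"room {r.id}: duplicate room id")
        seen.add(r.id)
        if r.ward_id not in instance.ward_by_id:
            report.append(f"room {r.id}: unknown ward {r.ward_id}")
        if not r.bed_ids:
            report.append(f"room {r.id}: has no beds")
        for bid in r.bed_ids:
            bed = instance.bed_by_id.get(bid)
            if bed is None or bed.room_id != r.id:
                report.append(f"room {r.id}: bed membership mismatch for bed {bid}")
    for w in instance.wards:
        for rid in w.room_ids:
            room = instance.room_by_id.get(rid)
            if room is None or room.ward_id != w.id:
                report.append(f"ward {w.id}: room membership mismatch for room {rid}")
        for t in instance.horizon:
            if w.capacity(t) < 0:
                report.append(f"ward {w.id}: negative spare capacity on day {t}")
    if len(instance.horizon) < 1:
        report.append("horizon: must contain at least one day")
    for d in instance.departments:
        if not (isinstance(d, int) and d >= 1):
            report.append(f"department {d}: ids must be positive integers")
    seen = set()
    for p in instance.patients:
        if p.id in seen:
            report.append(f"patient {p.id}: duplicate patient id")
        seen.add(p.id)
        if p.gender not in (-1, 1):
            report.append(f"patient {p.id}: gender must be -1 (male) or +1 (female)")
        if not (0 <= p.age <= instance.params.max_age):
            report.append(f"patient {p.id}: age {p.age} outside [0, {instance.params.max_age}]")
        if p.department not in instance.departments:
            report.append(f"patient {p.id}: unknown department {p.department}")
        if p.los < 1:
            report.append(f"patient {p.id}: length of stay must be >= 1")
        if p.care_level < 0:
            report.append(f"patient {p.id}: negative care level")
        if p.ptype not in PATIENT_TYPES:
            report.append(f"patient {p.id}: unknown patient type {p.ptype!r}")
    return report
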