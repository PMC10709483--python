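import pytest

from bedplan.domain import Bed, Instance, Params, Patient, Plan, Room, Ward


def make_instance(patients=(), horizon=2, capacity=10.0, params=None,
                  n_rooms=2, beds_per_room=2, features=("standard",)):
    """Small single-ward hospital: `n_rooms` rooms of `beds_per_room` beds."""
    beds, rooms, room_ids = [], [], []
    bid = 1
    for rid in range(1, n_rooms + 1):
        bed_ids = []
        for _ in range(beds_per_room):
            beds.append(Bed(bid, rid, frozenset(features)))
            bed_ids.append(bid)
            bid += 1
        rooms.append(Room(rid, 1, tuple(bed_ids)))
        room_ids.append(rid)
    ward = Ward(1, tuple(room_ids), {t: capacity for t in range(1, horizon + 1)})
    return Instance(wards=(ward,), rooms=tuple(rooms), beds=tuple(beds),
                    departments=(1, 2, 3, 4, 5), patients=tuple(patients),
                    horizon=range(1, horizon + 1), params=params or Params())


def make_patient(pid, gender=1, age=70, department=1, care=1.0, ptype="elective",
                 arrival=1, los=1, overflow_entry=None, requirements=(),
                 isolation=False, weight=None):
    return Patient(id=pid, gender=gender, age=age, department=department,
                   care_level=care, ptype=ptype, registration_day=arrival,
                   arrival_day=arrival, los=los,
                   overflow_entry_day=overflow_entry,
                   requirements=frozenset(requirements), isolation=isolation,
                   weight=weight)


@pytest.fixture
def toy_instance():
    """2 rooms x 2 beds, 2-day horizon, one elective staying both days."""
    return make_instance([make_patient(1, ptype="elective", arrival=1, los=2)])


@pytest.fixture
def competition_instance():
    """The canonical 1-bed competition: elective (Xi=10) vs emergency (Xi=9)."""
    patients = [make_patient(1, ptype="elective", arrival=1, los=1),
                make_patient(2, ptype="emergency", arrival=1, los=1)]
    inst = make_instance(patients, horizon=1, n_rooms=1, beds_per_room=1)
    return inst


@pytest.fixture
def empty_plan():
    return Plan()
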