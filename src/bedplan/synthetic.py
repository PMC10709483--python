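"""Seeded generators for hospital instances, event streams and metadata.

The defaults emulate the study conditions of a two-department cluster in a
large maximum-care hospital: five wards with 24 beds each (two-bed rooms),
28-day data sets with about 648 unique patients, a 40/60 male/female split,
mean age 70 years, mean length of stay 6 days (shifted geometric), and a
high emergency share.  A 21-day stream at these densities carries on the
order of 1,500 unique events (registrations, arrivals, LOS updates,
discharges, no-shows).

Metadata series plant department-specific log-linear drivers into Poisson
arrival counts -- a trauma-like profile (winter quarter, low minimum
temperature, large intra-day temperature swing) and a gastro-like profile
(bank holidays, weekends, Mondays) -- and return the ground-truth
coefficients so recovery tests can check the planted signs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import (
    ANTICIPATED,
    ELECTIVE,
    EMERGENCY,
    Bed,
    Instance,
    Params,
    Patient,
    Room,
    Ward,
)
from .simulator import Event

CARE_LEVELS = (1.0, 2.0, 3.0)
CARE_PROBS = (0.6, 0.3, 0.1)


def generate_hospital(n_wards: int = 5, beds_per_ward: int = 24,
                      rooms_per_ward: int = 12,
                      departments: Sequence[int] = (1, 2),
                      horizon_days: int = 7, seed: int = 0,
                      capacity_range: tuple = (6, 11),
                      telemetry_share: float = 0.25,
                      params: Optional[Params] = None) -> Instance:
    """Ward/room/bed topology with per-ward-day spare care capacity."""
    if n_wards < 1 or beds_per_ward < 1 or rooms_per_ward < 1:
        raise ValueError("sizes must be positive")
    if beds_per_ward % rooms_per_ward:
        raise ValueError(
            f"{beds_per_ward} beds per ward do not divide into {rooms_per_ward} rooms")
    rng = np.random.default_rng(seed)
    beds_per_room = beds_per_ward // rooms_per_ward
    wards, rooms, beds = [], [], []
    bid = rid = 1
    for wid in range(1, n_wards + 1):
        room_ids = []
        for _ in range(rooms_per_ward):
            bed_ids = []
            for _ in range(beds_per_room):
                features = {"standard"}
                if rng.random() < telemetry_share:
                    features.add("telemetry")
                beds.append(Bed(bid, rid, frozenset(features)))
                bed_ids.append(bid)
                bid += 1
            rooms.append(Room(rid, wid, tuple(bed_ids)))
            room_ids.append(rid)
            rid += 1
        capacity = {t: float(rng.integers(capacity_range[0], capacity_range[1]))
                    for t in range(1, horizon_days + 1)}
        wards.append(Ward(wid, tuple(room_ids), capacity))
    return Instance(
        wards=tuple(wards), rooms=tuple(rooms), beds=tuple(beds),
        departments=tuple(departments), patients=(),
        horizon=range(1, horizon_days + 1), params=params or Params())


def _draw_patient(pid, rng, instance, day, ptype, male_share, mean_age, mean_los,
                  telemetry_rate=0.1):
    gender = -1 if rng.random() < male_share else 1
    age = int(np.clip(rng.normal(mean_age, 12.0), 18, 100))
    los = int(rng.geometric(1.0 / mean_los))
    reqs = frozenset({"telemetry"}) if rng.random() < telemetry_rate else frozenset()
    return Patient(
        id=pid, gender=gender, age=age,
        department=int(rng.choice(instance.departments)),
        care_level=float(rng.choice(CARE_LEVELS, p=CARE_PROBS)),
        ptype=ptype, registration_day=day, arrival_day=day, los=los,
        requirements=reqs,
        isolation=bool(rng.random() < 0.02),
    )


def generate_patient_stream(instance: Instance, days: int = 28,
                            n_patients: Optional[int] = None,
                            male_share: float = 0.4, mean_age: float = 70.0,
                            mean_los: float = 6.0, emergency_share: float = 0.8,
                            los_update_rate: float = 0.25,
                            no_show_rate: float = 0.05,
                            elective_lead: tuple = (3, 10),
                            seed: int = 0):
    """Patients plus a sorted event stream over `days` days.

    ``n_patients`` defaults to the study density of 648 unique patients per
    28 days, scaled to `days`.  ``los_update_rate`` is the per-present-day
    probability of a one-day LOS revision (in a busy hospital roughly a
    fifth of inpatients see an update on any given day); ``no_show_rate`` applies to electives.
    """
    for rate in (male_share, emergency_share, los_update_rate, no_show_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_patients is None:
        n_patients = int(round(648 * days / 28))
    patients, events = [], []
    order = 0
    pid = 1

    def push(day, etype, patient_id, **payload):
        nonlocal order
        events.append(Event(day, order, etype, patient_id, payload))
        order += 1

    def life_events(p: Patient, is_elective: bool):
        nonlocal order
        arrived = True
        if is_elective:
            reg_day = max(1, p.arrival_day - int(rng.integers(*elective_lead)))
            push(reg_day, "elective_registration", p.id)
            if rng.random() < no_show_rate:
                push(p.arrival_day, "no_show", p.id)
                arrived = False
            else:
                push(p.arrival_day, "elective_arrival", p.id)
        else:
            push(p.arrival_day, "emergency_arrival", p.id)
        if not arrived:
            return
        end = p.arrival_day + p.los
        d = p.arrival_day + 1  # updates happen only once the patient is in house
        while d < min(end, days + 1):
            if rng.random() < los_update_rate:
                delta = int(rng.choice([-1, 1]))
                new_los = max(1, (end - p.arrival_day) + delta)
                new_end = p.arrival_day + new_los
                if new_end > d:  # cannot rewrite already-elapsed days
                    end = new_end
                    push(d, "los_update", p.id, new_los=new_los)
            d += 1
        if end <= days:
            push(end, "discharge", p.id)

    n_elective = int(round(n_patients * (1.0 - emergency_share)))
    for _ in range(n_elective):
        day = int(rng.integers(1, days + 1))
        p = _draw_patient(pid, rng, instance, day, ELECTIVE,
                          male_share, mean_age, mean_los)
        patients.append(p)
        life_events(p, is_elective=True)
        pid += 1
    daily_rate = n_patients * emergency_share / (days * len(instance.departments))
    for day in range(1, days + 1):
        for dept in instance.departments:
            for _ in range(rng.poisson(daily_rate)):
                p = _draw_patient(pid, rng, instance, day, EMERGENCY,
                                  male_share, mean_age, mean_los)
                p = Patient(**{**p.__dict__, "department": dept})
                patients.append(p)
                life_events(p, is_elective=False)
                pid += 1
    events.sort(key=Event.sort_key)
    return tuple(patients), events


def generate_single_instance(seed: int = 0, n_wards: int = 5,
                             beds_per_ward: int = 24, horizon_days: int = 7,
                             occupancy: float = 0.5,
                             arrivals_per_day: Optional[float] = None,
                             params: Optional[Params] = None):
    """One static, uncertainty-free planning instance plus its initial plan.

    Emulates the single-problem-instance benchmark protocol: a fraction of
    beds is pre-occupied by prior patients (some staying past the horizon),
    and the open patients -- electives and pre-announced emergencies with
    exactly known stays -- arrive within the horizon.
    """
    rng = np.random.default_rng(seed)
    skeleton = generate_hospital(n_wards=n_wards, beds_per_ward=beds_per_ward,
                                 horizon_days=horizon_days, seed=seed,
                                 params=params)
    from .domain import Plan

    patients = []
    fixed = {}
    pid = 1
    for room in skeleton.rooms:
        room_gender = None  # occupied rooms stay single-gender
        for bed_id in room.bed_ids:
            if rng.random() >= occupancy:
                continue
            los_left = int(rng.integers(1, horizon_days + 3))
            p = _draw_patient(pid, rng, skeleton, 1, ELECTIVE, 0.4, 70, 6,
                              telemetry_rate=0.0)
            gender = room_gender if room_gender is not None else p.gender
            room_gender = gender
            p = Patient(**{**p.__dict__, "arrival_day": 1, "los": los_left,
                           "gender": gender, "isolation": False})
            patients.append(p)
            fixed[pid] = bed_id
            pid += 1
    if arrivals_per_day is None:
        arrivals_per_day = 648 / 28 * (n_wards * beds_per_ward) / 120
    n_open = rng.poisson(arrivals_per_day * horizon_days * 0.6)
    for _ in range(max(3, n_open)):
        day = int(rng.integers(1, horizon_days + 1))
        ptype = EMERGENCY if rng.random() < 0.8 else ELECTIVE
        p = _draw_patient(pid, rng, skeleton, day, ptype, 0.4, 70, 6)
        patients.append(p)
        pid += 1
    instance = skeleton.with_patients(patients)
    return instance, Plan(fixed=fixed)


# ---------------------------------------------------------------------------
# metadata / arrival series with planted structure
# ---------------------------------------------------------------------------

#: planted log-linear coefficients (binary features as-is, continuous on the
#: standardized scale); detectability threshold for recovery tests: |b|>=0.1
PROFILES = {
    "trauma": {"Q1": 0.35, "T_min": -0.30, "T_dif": 0.20},
    "gastro": {"Holiday": 0.60, "WD_Sat": 0.35, "WD_Sun": 0.35, "WD_Mon": 0.35},
}

_BANK_HOLIDAYS = ((1, 1), (1, 6), (5, 1), (8, 15), (10, 3), (11, 1),
                  (12, 25), (12, 26))
_SCHOOL_BLOCKS = (((8, 1), (9, 12)), ((12, 23), (12, 31)), ((1, 1), (1, 7)),
                  ((4, 1), (4, 14)))


def _in_block(ts, block):
    (m1, d1), (m2, d2) = block
    a = (ts.month, ts.day) >= (m1, d1)
    b = (ts.month, ts.day) <= (m2, d2)
    return a and b


def generate_metadata_series(days: int = 1095, profiles: Sequence[str] = ("trauma", "gastro"),
                             noise_level: float = 1.0, seed: int = 0,
                             start: str = "2014-01-01", base_rate: float = 4.0,
                             overdispersion: float = 0.0):
    """Daily metadata table plus per-profile arrival counts and ground truth.

    Calendar features are exact; weather follows seasonal sinusoids plus
    ``noise_level``-scaled Gaussian noise; arrivals are Poisson draws from a
    log-linear rate with the planted :data:`PROFILES` coefficients.
    Returns ``(table, truth)``; `table` also carries per-profile
    ``arrivals_<profile>`` and ``PrevAdmin_<profile>`` columns.
    """
    if days < 60:
        raise ValueError("need at least 60 days of metadata")
    for prof in profiles:
        if prof not in PROFILES:
            raise KeyError(f"unknown department profile {prof!r}")
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=days, freq="D")
    doy = idx.dayofyear.to_numpy()
    season = -np.cos(2 * np.pi * doy / 365.25)  # -1 mid-winter .. +1 mid-summer

    t_dif = np.clip(6 + 2 * season + noise_level * rng.normal(0, 2, days), 1, None)
    t_mean = 9 + 10 * season + noise_level * rng.normal(0, 3, days)
    table = pd.DataFrame(index=idx)
    table["T_min"] = t_mean - t_dif / 2
    table["T_max"] = t_mean + t_dif / 2
    ap = 1013 + noise_level * rng.normal(0, 8, days)
    table["AP_min"] = ap - np.abs(rng.normal(2, 1, days))
    table["AP_max"] = ap + np.abs(rng.normal(2, 1, days))
    hum = np.clip(72 - 10 * season + noise_level * rng.normal(0, 6, days), 20, 100)
    table["H_min"] = np.clip(hum - 10, 5, 100)
    table["H_max"] = np.clip(hum + 10, 10, 100)
    wind = np.abs(rng.normal(12, 5, days))
    table["W_min"] = wind * 0.4
    table["W_max"] = wind * 1.6
    table["G_max"] = wind * (2.0 + np.abs(rng.normal(0, 0.5, days)))
    table["Rain"] = (rng.random(days) < 0.30 + 0.1 * (hum - 72) / 30).astype(float)
    snowy = (table["T_min"].to_numpy() < 0) & (rng.random(days) < 0.4)
    table["Snow"] = snowy.astype(float)
    table["S_cov"] = np.convolve(snowy, np.ones(3), "same").clip(0, 1)
    table["Hail"] = (rng.random(days) < 0.01).astype(float)
    table["Storm"] = (table["G_max"].to_numpy() > 35).astype(float)
    table["Holiday"] = np.array(
        [float((ts.month, ts.day) in _BANK_HOLIDAYS) for ts in idx])
    table["Hol_School"] = np.array(
        [float(any(_in_block(ts, b) for b in _SCHOOL_BLOCKS)) for ts in idx])
    fair = np.zeros(days)
    fair[(idx.month == 9) & (idx.day <= 14)] = 1.0
    table["Fair"] = fair
    table["SportEvent"] = ((idx.dayofweek == 5)
                           & (rng.random(days) < 0.3)).astype(float)

    # assemble the model features exactly as build_feature_table does
    from .forecasting import build_feature_table

    truth = {}
    dummy = pd.Series(np.zeros(days), index=idx)
    feats = build_feature_table(table, dummy).drop(columns=["arrivals", "PrevAdmin"])
    for prof in profiles:
        coefs = PROFILES[prof]
        eta = np.full(days, np.log(base_rate))
        for name, b in coefs.items():
            col = feats[name].to_numpy(float)
            if set(np.unique(col)) - {0.0, 1.0}:
                col = (col - col.mean()) / col.std()
            eta = eta + b * col
        lam = np.exp(eta)
        if overdispersion > 0:  # optional gamma mixing on top of Poisson
            lam = lam * rng.gamma(1.0 / overdispersion, overdispersion, days)
        counts = rng.poisson(lam)
        table[f"arrivals_{prof}"] = counts
        table[f"PrevAdmin_{prof}"] = np.concatenate([[0], counts[:-1]]).astype(float)
        truth[prof] = dict(coefs)
    return table, truth


def department_table(metadata: pd.DataFrame, profile: str) -> pd.DataFrame:
    """Feature table for one department profile (model-ready columns)."""
    from .forecasting import build_feature_table

    raw = metadata.drop(columns=[c for c in metadata.columns
                                 if c.startswith(("arrivals_", "PrevAdmin_"))])
    arrivals = metadata[f"arrivals_{profile}"]
    return build_feature_table(raw, arrivals)


def generate_tiny_instance(n_beds: int = 4, n_patients: int = 4,
                           horizon: int = 2, seed: int = 0,
                           params: Optional[Params] = None) -> Instance:
    """Random oracle-sized instance (guarded to brute-force limits)."""
    if n_beds > 8 or n_patients > 8 or horizon > 3:
        raise ValueError("tiny-instance guard exceeded (<=8 beds, <=8 patients, |T|<=3)")
    rng = np.random.default_rng(seed)
    params = params or Params()
    beds, rooms, room_ids = [], [], []
    bid = rid = 1
    remaining = n_beds
    while remaining > 0:
        size = int(min(remaining, rng.integers(1, 3)))
        bed_ids = []
        for _ in range(size):
            features = frozenset({"standard"} | ({"telemetry"} if rng.random() < 0.3 else set()))
            beds.append(Bed(bid, rid, features))
            bed_ids.append(bid)
            bid += 1
        rooms.append(Room(rid, 1, tuple(bed_ids)))
        room_ids.append(rid)
        rid += 1
        remaining -= size
    capacity = {t: float(rng.integers(1, 5)) for t in range(1, horizon + 1)}
    ward = Ward(1, tuple(room_ids), capacity)
    departments = (1, 2, 3)
    patients = []
    for pid in range(1, n_patients + 1):
        arrival = int(rng.integers(1, horizon + 1))
        patients.append(Patient(
            id=pid,
            gender=int(rng.choice([-1, 1])),
            age=int(rng.integers(20, 95)),
            department=int(rng.choice(departments)),
            care_level=float(rng.choice(CARE_LEVELS, p=CARE_PROBS)),
            ptype=str(rng.choice([ELECTIVE, EMERGENCY, ANTICIPATED],
                                 p=[0.4, 0.4, 0.2])),
            registration_day=arrival,
            arrival_day=arrival,
            los=int(rng.integers(1, horizon + 1)),
            requirements=frozenset({"telemetry"}) if rng.random() < 0.15 else frozenset(),
            isolation=bool(rng.random() < 0.1),
        ))
    return Instance(wards=(ward,), rooms=tuple(rooms), beds=tuple(beds),
                    departments=departments, patients=tuple(patients),
                    horizon=range(1, horizon + 1), params=params)
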