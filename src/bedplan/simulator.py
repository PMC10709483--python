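"""Event-driven rolling-horizon replanning.

The dynamic bed-assignment problem is approximated by re-solving the static
model at every event (admission, discharge, length-of-stay update, no-show,
elective registration).  Each event is one planning stage; a large hospital
with about 500 events per day over a 28-day horizon already faces more than
14,000 stages, which is why the heuristics and not the exact solver drive
the replanning loop.

Conventions (also in docs/methods.md):

* intra-day order processes discharges before admissions, so beds freed on a
  day are available to patients arriving on that day;
* a patient placed in a ward bed is never moved by later replanning
  (non-medical room transfers are not allowed) -- the committed occupancy is
  carried as fixed state into every subsequent solve;
* anticipated emergency stubs are refreshed from the forecaster at the first
  event of each day and never enter the realized score;
* realized utility is computed from the committed occupancy history with the
  planning objective's terms: per-patient ``omega * overflow days +
  Xi_p * sum_k Q_k`` over occupied days (k counted from each patient's first
  bed day), per room-day age spread and department homogeneity over actual
  occupants, and per ward-day overload of the care load of that day's newly
  admitted patients against spare capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .domain import (
    ANTICIPATED,
    EMERGENCY,
    Instance,
    Params,
    Patient,
    Plan,
    Ward,
    OVERFLOW,
)
from .ga import solve_ga
from .gla import solve_gla
from .pilot import PilotPolicy, solve_pilot
from .utility import q_weight

EVENT_TYPES = ("elective_registration", "elective_arrival", "emergency_arrival",
               "discharge", "los_update", "no_show")

#: intra-day processing priority: free beds first, then arrivals
_EVENT_PRIORITY = {"discharge": 0, "no_show": 1, "los_update": 2,
                   "elective_registration": 3, "elective_arrival": 4,
                   "emergency_arrival": 4}


@dataclass(frozen=True)
class Event:
    day: int
    order: int
    etype: str
    patient_id: int
    payload: dict = field(default_factory=dict)

    def sort_key(self):
        return (self.day, _EVENT_PRIORITY[self.etype], self.order, self.patient_id)


def stage_count(events_per_day: int, days: int) -> int:
    """Number of planning stages in the one-stage-per-event approximation."""
    return events_per_day * days


@dataclass
class SimulationReport:
    realized_utility: float
    overflow_person_days: int
    replan_count: int
    n_events: int
    committed: dict          # pid -> (bed, start day, end day)
    overflow_waits: dict     # pid -> days waited before bed (or until sim end)
    event_log: list = field(default_factory=list)


@dataclass
class SimulationState:
    instance: Instance
    current_day: int = 1
    known: set = field(default_factory=set)       # announced, not yet arrived
    present: set = field(default_factory=set)     # physically in hospital
    departed: set = field(default_factory=set)
    committed: dict = field(default_factory=dict)  # pid -> (bed, start day)
    current_end: dict = field(default_factory=dict)  # pid -> end day (exclusive)
    arrival_day: dict = field(default_factory=dict)
    overflow_entry: dict = field(default_factory=dict)
    anticipated: list = field(default_factory=list)  # Patient stubs, absolute days


def apply_event(state: SimulationState, event: Event) -> SimulationState:
    pid = event.patient_id
    if pid not in state.instance.patient_by_id:
        raise KeyError(f"event references unknown patient {pid}")
    patient = state.instance.patient_by_id[pid]
    state.current_day = event.day
    if event.etype == "elective_registration":
        state.known.add(pid)
        state.arrival_day[pid] = patient.arrival_day
        state.current_end.setdefault(pid, patient.arrival_day + patient.los)
    elif event.etype in ("elective_arrival", "emergency_arrival"):
        state.known.add(pid)
        state.present.add(pid)
        state.arrival_day[pid] = event.day
        state.current_end.setdefault(
            pid, event.day + event.payload.get("los", patient.los))
    elif event.etype == "discharge":
        if pid not in state.present:
            raise ValueError(f"discharge of absent patient {pid}")
        state.present.discard(pid)
        state.departed.add(pid)
        state.current_end[pid] = event.day
        state.overflow_entry.pop(pid, None)
    elif event.etype == "los_update":
        if pid not in state.present:
            raise ValueError(f"LOS update for patient {pid} who is not present")
        new_los = event.payload["new_los"]
        state.current_end[pid] = max(event.day + 1, state.arrival_day[pid] + new_los)
    elif event.etype == "no_show":
        if pid in state.present:
            raise ValueError(f"no-show of patient {pid} who already arrived")
        state.known.discard(pid)
        state.departed.add(pid)
    else:
        raise ValueError(f"unknown event type {event.etype!r}")
    return state


def _relative_patient(p: Patient, state: SimulationState, day: int, horizon: int):
    """Map a patient to the planning run's relative day frame (today = 1)."""
    arrival = max(state.arrival_day.get(p.id, p.arrival_day), day)
    end = state.current_end.get(p.id, p.arrival_day + p.los)
    if arrival >= day + horizon or end <= arrival:
        return None
    over_entry = state.overflow_entry.get(p.id)
    return replace(
        p,
        arrival_day=arrival - day + 1,
        los=end - arrival,
        overflow_entry_day=None if over_entry is None else over_entry - day + 1,
    )


def _snapshot(state: SimulationState, day: int, horizon: int, params: Params):
    """Static planning instance for `day` with relative horizon 1..horizon."""
    inst = state.instance
    wards = tuple(
        Ward(w.id, w.room_ids,
             {t: w.capacity(day + t - 1) for t in range(1, horizon + 1)})
        for w in inst.wards)
    beds = tuple(
        replace(b, blocked_days=frozenset(
            t - day + 1 for t in b.blocked_days if day <= t < day + horizon))
        for b in inst.beds)
    fixed = {}
    patients = []
    for pid, (bid, _start) in state.committed.items():
        if pid not in state.present:
            continue
        p = _relative_patient(inst.patient_by_id[pid], state, day, horizon)
        if p is not None:
            patients.append(p)
            fixed[pid] = bid
    open_pids = []
    for pid in sorted(state.present | state.known):
        if pid in state.committed or pid in state.departed:
            continue
        p = _relative_patient(inst.patient_by_id[pid], state, day, horizon)
        if p is not None:
            patients.append(p)
            open_pids.append(pid)
    for stub in state.anticipated:
        p = _relative_patient(stub, state, day, horizon)
        if p is not None and p.arrival_day > 1:
            patients.append(p)
    snapshot = Instance(
        wards=wards, rooms=inst.rooms, beds=beds,
        departments=inst.departments, patients=tuple(patients),
        horizon=range(1, horizon + 1), params=params)
    return snapshot, Plan(fixed=fixed), open_pids


_SOLVERS = {
    "gla": lambda inst, plan, params, seed, kw: solve_gla(inst, plan, params, **kw),
    "pilot": lambda inst, plan, params, seed, kw: solve_pilot(
        inst, plan, params, policy=kw.get("policy", PilotPolicy(seed=seed))),
    "ga": lambda inst, plan, params, seed, kw: solve_ga(
        inst, plan, params, seed=seed, **{k: v for k, v in kw.items() if k != "policy"}),
}


def run_simulation(instance: Instance, events: list, solver: str = "gla",
                   forecaster: Optional[Callable[[int, int], float]] = None,
                   params: Optional[Params] = None, seed: int = 0,
                   horizon_days: int = 7,
                   solver_kwargs: Optional[dict] = None) -> SimulationReport:
    """Replay an event stream, re-solving the static model at each event.

    ``forecaster(department, absolute_day) -> expected emergency arrivals``
    feeds the anticipated-emergency stubs; ``None`` disables anticipation.
    """
    params = params or instance.params
    solver_kwargs = solver_kwargs or {}
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}")
    events = sorted(events, key=Event.sort_key)
    state = SimulationState(instance=instance)
    rng = np.random.default_rng(seed)
    log = []
    replans = 0
    last_refresh_day = None

    for k, event in enumerate(events):
        if forecaster is not None and event.day != last_refresh_day:
            state.anticipated = _anticipate(instance, forecaster, event.day,
                                            horizon_days, params, rng)
            last_refresh_day = event.day
        apply_event(state, event)
        snapshot, plan, open_pids = _snapshot(state, event.day, horizon_days, params)
        solved = _SOLVERS[solver](snapshot, plan, params, seed + k + 1, solver_kwargs)
        replans += 1
        newly_committed = []
        for pid in open_pids:
            if pid not in state.present:
                continue
            bid = solved.assignments.get(pid)
            if bid is not None and bid != OVERFLOW:
                state.committed[pid] = (bid, event.day)
                state.overflow_entry.pop(pid, None)
                newly_committed.append(pid)
            else:
                state.overflow_entry.setdefault(pid, event.day)
        log.append({"day": event.day, "type": event.etype,
                    "patient": event.patient_id, "committed": newly_committed,
                    "overflow_size": len(state.overflow_entry)})

    last_day = events[-1].day if events else state.current_day
    return _score_realized(state, params, last_day, replans, len(events), log)


def _anticipate(instance: Instance, forecaster, day: int, horizon: int,
                params: Params, rng) -> list:
    from .forecasting import anticipate_emergencies  # deferred: optional layer

    forecasts = {}
    for dept in instance.departments:
        for t in range(day + 1, day + horizon):
            forecasts[(dept, t)] = max(0.0, float(forecaster(dept, t)))
    return anticipate_emergencies(forecasts, instance, rng)


def _score_realized(state: SimulationState, params: Params, last_day: int,
                    replans: int, n_events: int, log: list) -> SimulationReport:
    inst = state.instance
    committed = {}
    occupancy = {}  # (bed, day) -> pid
    admissions = {}  # (ward, day) -> care load of that day's admissions
    u_patients = 0.0
    overflow_waits = {}
    overflow_days_total = 0

    for pid, (bid, start) in state.committed.items():
        p = inst.patient_by_id[pid]
        if p.ptype == ANTICIPATED:
            continue
        end = min(state.current_end.get(pid, start + p.los), last_day + 1)
        committed[pid] = (bid, start, end)
        waited = start - state.arrival_day.get(pid, start)
        overflow_waits[pid] = waited
        overflow_days_total += waited
        n_days = max(0, end - start)
        u_patients += params.overflow_rate * waited + params.xi(p) * sum(
            q_weight(k, params.q) for k in range(1, n_days + 1))
        for d in range(start, end):
            occupancy[(bid, d)] = pid
        wid = inst.ward_of_bed(bid).id
        admissions[(wid, start)] = admissions.get((wid, start), 0.0) + p.care_level
    for pid, entry in state.overflow_entry.items():
        if inst.patient_by_id[pid].ptype != ANTICIPATED:
            waited = last_day + 1 - entry
            overflow_waits[pid] = waited
            overflow_days_total += waited

    spread_total = 0.0
    homog_total = 0.0
    room_of = {b.id: b.room_id for b in inst.beds}
    by_room_day = {}
    for (bid, d), pid in occupancy.items():
        by_room_day.setdefault((room_of[bid], d), []).append(pid)
    for people in by_room_day.values():
        ages = [inst.patient_by_id[q].age for q in people]
        depts = {inst.patient_by_id[q].department for q in people}
        if len(ages) > 1:
            spread_total += max(ages) - min(ages)
        if len(depts) == 1:
            homog_total += 1
    overload_total = 0.0
    for (wid, d), load in admissions.items():
        overload_total += max(0.0, load - inst.ward_by_id[wid].capacity(d))

    realized = (params.alpha * u_patients - params.beta * spread_total
                + params.gamma * homog_total - params.delta * overload_total)
    return SimulationReport(
        realized_utility=realized,
        overflow_person_days=overflow_days_total,
        replan_count=replans,
        n_events=n_events,
        committed=committed,
        overflow_waits=overflow_waits,
        event_log=log,
    )


def compare_solvers(instance: Instance, events: list, solvers: dict,
                    params: Optional[Params] = None, seed: int = 0,
                    horizon_days: int = 7,
                    forecaster=None) -> dict:
    """Run several solver configurations on one stream; normalize to 'gla'.

    `solvers` maps a label to (solver name, kwargs); the returned dict maps
    each label to (report, normalized utility in percent of the GLA run).
    """
    reports = {}
    for label, (name, kwargs) in solvers.items():
        reports[label] = run_simulation(instance, events, solver=name,
                                        forecaster=forecaster, params=params,
                                        seed=seed, horizon_days=horizon_days,
                                        solver_kwargs=kwargs)
    base = reports.get("gla")
    out = {}
    for label, rep in reports.items():
        norm = 100.0 * rep.realized_utility / base.realized_utility if base else None
        out[label] = (rep, norm)
    return out
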