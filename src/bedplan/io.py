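"""Configuration and file I/O: YAML run configuration, CSV/JSON hospital
instances, event-stream CSV, and plan reports with utility breakdown."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .domain import Bed, Instance, Params, Patient, Plan, Room, Ward
from .pilot import PilotPolicy
from .simulator import Event
from .utility import total_utility

_PARAM_FIELDS = {f.name for f in dataclasses.fields(Params)}
_POLICY_FIELDS = {f.name for f in dataclasses.fields(PilotPolicy)}
_TOP_KEYS = {"params", "policy", "solver", "forecaster", "horizon_days", "seed"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    params: Params = Params()
    policy: PilotPolicy = PilotPolicy()
    solver: str = "gla"
    forecaster: str = "baseline_avg"
    horizon_days: int = 7
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "policy": dataclasses.asdict(self.policy),
            "solver": self.solver,
            "forecaster": self.forecaster,
            "horizon_days": self.horizon_days,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _build_config(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    pdata = data.get("params", {}) or {}
    bad = set(pdata) - _PARAM_FIELDS
    if bad:
        raise ValueError(f"unknown keys under params: {sorted(bad)}")
    params = Params(**pdata)
    for name in ("alpha", "beta", "gamma", "delta", "overflow_rate"):
        if getattr(params, name) < 0:
            raise ValueError(f"params.{name}: weights must be non-negative")
    if not 0 <= params.q < 1:
        raise ValueError("params.q: decay must lie in [0, 1)")
    poldata = data.get("policy", {}) or {}
    bad = set(poldata) - _POLICY_FIELDS
    if bad:
        raise ValueError(f"unknown keys under policy: {sorted(bad)}")
    return RunConfig(params=params, policy=PilotPolicy(**poldata),
                     solver=data.get("solver", "gla"),
                     forecaster=data.get("forecaster", "baseline_avg"),
                     horizon_days=int(data.get("horizon_days", 7)),
                     seed=int(data.get("seed", 0)))


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load a YAML run configuration; empty/missing file gives full defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build_config(data)


def save_config(config: RunConfig, path: Union[str, Path]):
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# instance I/O
# ---------------------------------------------------------------------------

def _instance_to_dict(instance: Instance) -> dict:
    return {
        "horizon_days": len(instance.horizon),
        "departments": list(instance.departments),
        "params": dataclasses.asdict(instance.params),
        "wards": [{"id": w.id, "room_ids": list(w.room_ids),
                   "spare_capacity": {str(k): v for k, v in w.spare_capacity.items()}}
                  for w in instance.wards],
        "rooms": [{"id": r.id, "ward_id": r.ward_id, "bed_ids": list(r.bed_ids)}
                  for r in instance.rooms],
        "beds": [{"id": b.id, "room_id": b.room_id,
                  "features": sorted(b.features),
                  "blocked_days": sorted(b.blocked_days)} for b in instance.beds],
        "patients": [{**dataclasses.asdict(p),
                      "requirements": sorted(p.requirements)}
                     for p in instance.patients],
    }


def save_instance(instance: Instance, path: Union[str, Path]):
    Path(path).write_text(json.dumps(_instance_to_dict(instance), indent=1,
                                     sort_keys=True))


def _instance_from_dict(data: dict) -> Instance:
    wards = tuple(Ward(w["id"], tuple(w["room_ids"]),
                       {int(k): float(v) for k, v in w["spare_capacity"].items()})
                  for w in data["wards"])
    rooms = tuple(Room(r["id"], r["ward_id"], tuple(r["bed_ids"]))
                  for r in data["rooms"])
    beds = tuple(Bed(b["id"], b["room_id"], frozenset(b.get("features", [])),
                     frozenset(b.get("blocked_days", []))) for b in data["beds"])
    patients = tuple(Patient(**{**p, "requirements": frozenset(p.get("requirements", []))})
                     for p in data["patients"])
    return Instance(wards=wards, rooms=rooms, beds=beds,
                    departments=tuple(data["departments"]), patients=patients,
                    horizon=range(1, data["horizon_days"] + 1),
                    params=Params(**data.get("params", {})))


def load_instance(path: Union[str, Path]) -> Instance:
    """Load an instance from one JSON document or a directory of CSV files
    (wards.csv, rooms.csv, beds.csv, patients.csv)."""
    path = Path(path)
    if path.is_dir():
        return _instance_from_csv_dir(path)
    return _instance_from_dict(json.loads(path.read_text()))


def save_instance_csv(instance: Instance, directory: Union[str, Path]):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"id": w.id, "room_ids": " ".join(map(str, w.room_ids)),
                   "spare_capacity": " ".join(f"{k}:{v}" for k, v in
                                              sorted(w.spare_capacity.items()))}
                  for w in instance.wards]).to_csv(directory / "wards.csv", index=False)
    pd.DataFrame([{"id": r.id, "ward_id": r.ward_id,
                   "bed_ids": " ".join(map(str, r.bed_ids))}
                  for r in instance.rooms]).to_csv(directory / "rooms.csv", index=False)
    pd.DataFrame([{"id": b.id, "room_id": b.room_id,
                   "features": " ".join(sorted(b.features)),
                   "blocked_days": " ".join(map(str, sorted(b.blocked_days)))}
                  for b in instance.beds]).to_csv(directory / "beds.csv", index=False)
    pd.DataFrame([{**dataclasses.asdict(p),
                   "requirements": " ".join(sorted(p.requirements))}
                  for p in instance.patients]).to_csv(
        directory / "patients.csv", index=False)
    meta = {"horizon_days": len(instance.horizon),
            "departments": list(instance.departments),
            "params": dataclasses.asdict(instance.params)}
    (directory / "instance.json").write_text(json.dumps(meta, indent=1))


def _split(cell) -> list:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return str(cell).split()


def _instance_from_csv_dir(directory: Path) -> Instance:
    meta = json.loads((directory / "instance.json").read_text())
    wards_df = pd.read_csv(directory / "wards.csv")
    wards = tuple(
        Ward(int(row.id), tuple(int(x) for x in _split(row.room_ids)),
             {int(k): float(v) for k, v in
              (pair.split(":") for pair in _split(row.spare_capacity))})
        for row in wards_df.itertuples())
    rooms_df = pd.read_csv(directory / "rooms.csv")
    rooms = tuple(Room(int(row.id), int(row.ward_id),
                       tuple(int(x) for x in _split(row.bed_ids)))
                  for row in rooms_df.itertuples())
    beds_df = pd.read_csv(directory / "beds.csv")
    beds = tuple(Bed(int(row.id), int(row.room_id),
                     frozenset(_split(row.features)),
                     frozenset(int(x) for x in _split(row.blocked_days)))
                 for row in beds_df.itertuples())
    patients_df = pd.read_csv(directory / "patients.csv")
    patients = []
    for row in patients_df.itertuples():
        patients.append(Patient(
            id=int(row.id), gender=int(row.gender), age=int(row.age),
            department=int(row.department), care_level=float(row.care_level),
            ptype=str(row.ptype), registration_day=int(row.registration_day),
            arrival_day=int(row.arrival_day), los=int(row.los),
            overflow_entry_day=None if pd.isna(row.overflow_entry_day)
            else int(row.overflow_entry_day),
            requirements=frozenset(_split(row.requirements)),
            isolation=bool(row.isolation),
            weight=None if pd.isna(row.weight) else float(row.weight)))
    return Instance(wards=wards, rooms=rooms, beds=beds,
                    departments=tuple(meta["departments"]),
                    patients=tuple(patients),
                    horizon=range(1, meta["horizon_days"] + 1),
                    params=Params(**meta.get("params", {})))


# ---------------------------------------------------------------------------
# events and plans
# ---------------------------------------------------------------------------

def save_events(events, path: Union[str, Path]):
    pd.DataFrame([{"day": e.day, "order": e.order, "type": e.etype,
                   "patient_id": e.patient_id,
                   "payload": json.dumps(e.payload, sort_keys=True)}
                  for e in events]).to_csv(path, index=False)


def load_events(path: Union[str, Path]) -> list:
    df = pd.read_csv(path)
    return [Event(int(r.day), int(r.order), str(r.type), int(r.patient_id),
                  json.loads(r.payload) if isinstance(r.payload, str) else {})
            for r in df.itertuples()]


def save_plan(plan: Plan, instance: Instance, path: Union[str, Path],
              config: Optional[RunConfig] = None, seed: Optional[int] = None):
    """Persist a plan with its utility breakdown and provenance stamp."""
    for pid, bid in {**plan.fixed, **plan.assignments}.items():
        if bid not in (None, "OVERFLOW") and bid not in instance.bed_by_id:
            raise ValueError(f"plan references unknown bed {bid} (patient {pid})")
        if pid not in instance.patient_by_id:
            raise ValueError(f"plan references unknown patient {pid}")
    breakdown = total_utility(plan, instance)
    doc = {
        "fixed": {str(k): v for k, v in sorted(plan.fixed.items())},
        "assignments": {str(k): v for k, v in sorted(plan.assignments.items())},
        "utility": breakdown.as_dict(),
        "config_hash": config.digest() if config else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_plan(path: Union[str, Path], instance: Instance) -> Plan:
    doc = json.loads(Path(path).read_text())
    plan = Plan(fixed={int(k): v for k, v in doc["fixed"].items()},
                assignments={int(k): v for k, v in doc["assignments"].items()})
    for pid, bid in {**plan.fixed, **plan.assignments}.items():
        if pid not in instance.patient_by_id:
            raise ValueError(f"plan references unknown patient {pid}")
        if bid != "OVERFLOW" and bid not in instance.bed_by_id:
            raise ValueError(f"plan references unknown bed {bid}")
    return plan
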