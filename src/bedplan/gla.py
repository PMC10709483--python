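"""Greedy look-ahead (GLA) subheuristic.

The GLA heuristic repeatedly executes the globally most beneficial feasible
patient-bed assignment: it builds the matrix of marginal utilities
``U_{b,p}`` over the relevant patients and beds, keeps per-patient maxima
``U^max_p`` / ``U^argmax_p`` so each step compares only |P| values, executes
the best positive assignment, and updates exactly the entries an executed
assignment can affect (same ward, overlapping stay days).  Patients whose
best marginal is non-positive go to the overflow buffer.

The incremental state here is an optimised equivalent of
:func:`bedplan.utility.marginal_utility`; tests assert exact agreement with
the from-scratch recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .domain import Instance, Params, Plan, OVERFLOW, candidate_beds, restrict_scope
from .utility import feasibility_violations, overflow_bonus, q_weight


@dataclass
class SolveContext:
    """Per-run precomputation shared by all GLA completions of one master plan.

    Everything here depends only on the instance and the *fixed* occupancy,
    which never change while one planning run (or one pilot search) executes.
    """

    instance: Instance
    params: Params
    open_patients: list = field(default_factory=list)
    relevant_beds: list = field(default_factory=list)
    stay: dict = field(default_factory=dict)          # pid -> in-horizon days
    base_value: dict = field(default_factory=dict)    # pid -> OF_p + Xi_p * sum Q_t
    bp: dict = field(default_factory=dict)            # pid -> candidate bed ids
    fixed_taken: set = field(default_factory=set)     # (bed, day) blocked or pre-occupied
    room_prior: dict = field(default_factory=dict)    # (room, day) -> (ages, dept|None, isolation)
    room_of: dict = field(default_factory=dict)       # bed id -> room id
    ward_of: dict = field(default_factory=dict)       # bed id -> ward id

    @classmethod
    def build(cls, instance: Instance, plan: Plan, params: Optional[Params] = None,
              drop_days: Optional[int] = None) -> "SolveContext":
        params = params or instance.params
        beds, patients = restrict_scope(instance, plan)
        if drop_days is not None:
            last_arrival = instance.horizon[0] + drop_days - 1
            patients = [pid for pid in patients
                        if instance.patient_by_id[pid].arrival_day <= last_arrival]
        ctx = cls(instance=instance, params=params,
                  open_patients=sorted(patients), relevant_beds=sorted(beds))
        current = instance.horizon[0]
        for pid in ctx.open_patients:
            p = instance.patient_by_id[pid]
            ctx.stay[pid] = [t for t in p.stay_days() if t in instance.horizon]
            sumq = sum(q_weight(t, params.q) for t in ctx.stay[pid])
            ctx.base_value[pid] = (overflow_bonus(p, current, params.overflow_rate)
                                   + params.xi(p) * sumq)
            ctx.bp[pid] = candidate_beds(p, plan, instance) & set(beds)
        for bed in instance.beds:
            ctx.room_of[bed.id] = bed.room_id
            ctx.ward_of[bed.id] = instance.room_by_id[bed.room_id].ward_id
            for t in bed.blocked_days:
                ctx.fixed_taken.add((bed.id, t))
        for pid, bid in plan.fixed.items():
            p = instance.patient_by_id[pid]
            rid = ctx.room_of[bid]
            for t in p.stay_days():
                if t not in instance.horizon:
                    continue
                ctx.fixed_taken.add((bid, t))
                key = (rid, t)
                ages, dept, iso = ctx.room_prior.get(key, ((), None, False))
                new_dept = p.department if (dept is None and not ages) or dept == p.department else None
                ctx.room_prior[key] = (ages + (p.age,), new_dept, iso or p.isolation)
        return ctx


def _spread(ages):
    return float(max(ages) - min(ages)) if len(ages) > 1 else 0.0


class UtilityMatrixState:
    """Mutable U_{b,p} matrix plus the occupancy it was computed against."""

    def __init__(self, ctx: SolveContext, plan: Plan):
        self.ctx = ctx
        self.plan = plan
        self.new_taken = set()
        self.room_new = {}   # (room, day) -> list of pids
        self.ward_load = {}  # (ward, day) -> care load of new assignees
        inst = ctx.instance
        for pid, bid in plan.assigned_patients().items():
            p = inst.patient_by_id[pid]
            for t in p.stay_days():
                if t in inst.horizon:
                    self.new_taken.add((bid, t))
                    self.room_new.setdefault((ctx.room_of[bid], t), []).append(pid)
                    key = (ctx.ward_of[bid], t)
                    self.ward_load[key] = self.ward_load.get(key, 0.0) + p.care_level
        self.entries = {}  # pid -> {bid: u}
        self.best = {}     # pid -> (u, bid)
        for pid in ctx.open_patients:
            if pid not in plan.assignments:
                self._recompute_patient(pid)

    # -- marginal utility against the current state ------------------------
    def marginal(self, pid: int, bid: int) -> float:
        ctx, inst = self.ctx, self.ctx.instance
        p = inst.patient_by_id[pid]
        if bid not in ctx.bp[pid]:
            return 0.0
        days = ctx.stay[pid]
        rid, wid = ctx.room_of[bid], ctx.ward_of[bid]
        for t in days:
            if (bid, t) in ctx.fixed_taken or (bid, t) in self.new_taken:
                return 0.0
        # room compatibility against this run's assignees (priors are in B_p)
        for t in days:
            for qid in self.room_new.get((rid, t), ()):
                q = inst.patient_by_id[qid]
                if q.gender != p.gender or q.isolation or p.isolation:
                    return 0.0
        params = ctx.params
        d2 = d3 = d4 = 0.0
        for t in days:
            prior = ctx.room_prior.get((rid, t))
            new_pids = self.room_new.get((rid, t), ())
            new_ages = [inst.patient_by_id[q].age for q in new_pids]
            prior_ages = list(prior[0]) if prior else []
            before = _spread(prior_ages + new_ages)
            after = _spread(prior_ages + new_ages + [p.age])
            d2 += after - before
            # department homogeneity delta
            new_depts = {inst.patient_by_id[q].department for q in new_pids}
            if prior is None:
                h_before = int(bool(new_pids) and len(new_depts) == 1)
                h_after = int(len(new_depts | {p.department}) == 1)
            else:
                dstar = prior[1]
                h_before = int(bool(new_pids) and dstar is not None and new_depts == {dstar})
                h_after = int(dstar is not None and (new_depts | {p.department}) == {dstar})
            d3 += h_after - h_before
            # ward care overload delta
            cap = inst.ward_by_id[wid].capacity(t)
            load = self.ward_load.get((wid, t), 0.0)
            d4 += max(0.0, load + p.care_level - cap) - max(0.0, load - cap)
        return (params.alpha * ctx.base_value[pid]
                - params.beta * d2 + params.gamma * d3 - params.delta * d4)

    def _recompute_patient(self, pid: int):
        row = {}
        for bid in self.ctx.bp[pid]:
            u = self.marginal(pid, bid)
            if u != 0.0:
                row[bid] = u
        self.entries[pid] = row
        self.best[pid] = max(((u, -bid) for bid, u in row.items()), default=(0.0, 0))

    def pick_best(self):
        """Most promising open (patient, bed, utility); ties: lowest ids."""
        best = None
        for pid in sorted(self.best):
            u, negbid = self.best[pid]
            if u <= 0.0:
                continue
            if best is None or u > best[2] or (u == best[2] and pid < best[0]):
                best = (pid, -negbid, u)
        return best

    def execute(self, pid: int, bid: int):
        """Record the assignment and update the affected matrix entries."""
        ctx, inst = self.ctx, self.ctx.instance
        p = inst.patient_by_id[pid]
        self.plan.assignments[pid] = bid
        days = ctx.stay[pid]
        wid = ctx.ward_of[bid]
        max_care = max((inst.patient_by_id[q].care_level for q in self.entries
                        if q != pid), default=0.0)
        ward_days = set()
        for t in days:
            self.new_taken.add((bid, t))
            self.room_new.setdefault((ctx.room_of[bid], t), []).append(pid)
            key = (wid, t)
            before = self.ward_load.get(key, 0.0)
            after = before + p.care_level
            self.ward_load[key] = after
            # the overload delta of a future candidate changes only when the
            # capacity kink lies inside (before, after + candidate care]
            cap = inst.ward_by_id[wid].capacity(t)
            if before < cap and after + max_care > cap:
                ward_days.add(t)
        self.update_affected(pid, bid, ward_days=ward_days)

    def update_affected(self, executed_pid: int, executed_bid: int,
                        ward_days=None):
        """Refresh entries whose value the executed assignment can change.

        The executed patient's own row is removed.  Rows of patients whose
        stay overlaps the executed days are recomputed for beds in the same
        room (spread / department homogeneity / bed conflicts) and -- on days
        where the ward care load moved across the spare-capacity kink -- for
        every bed of the ward.  ``ward_days=None`` conservatively recouples
        the whole ward on all executed days."""
        ctx = self.ctx
        self.entries.pop(executed_pid, None)
        self.best.pop(executed_pid, None)
        days = set(ctx.stay[executed_pid])
        if ward_days is None:
            ward_days = days
        wid = ctx.ward_of[executed_bid]
        rid = ctx.room_of[executed_bid]
        for pid in list(self.entries):
            overlap = days.intersection(ctx.stay[pid])
            if not overlap:
                continue
            ward_coupled = bool(ward_days.intersection(ctx.stay[pid]))
            touched = False
            for bid in ctx.bp[pid]:
                if ctx.ward_of[bid] != wid:
                    continue
                if not (ward_coupled or bid == executed_bid
                        or ctx.room_of[bid] == rid):
                    continue
                u = self.marginal(pid, bid)
                row = self.entries[pid]
                if u != 0.0:
                    row[bid] = u
                    touched = True
                elif bid in row:
                    del row[bid]
                    touched = True
            if touched:
                self.best[pid] = max(((u, -bid) for bid, u in self.entries[pid].items()),
                                     default=(0.0, 0))


def solve_gla(instance: Instance, initial_plan: Plan, params: Optional[Params] = None,
              tie_seed: int = 0, drop_days: Optional[int] = None,
              instrument: Optional[dict] = None) -> Plan:
    """Run the GLA subheuristic to completion.

    Tie-breaking on equal marginals is deterministic (lowest patient id,
    then lowest bed id); ``tie_seed`` is accepted for interface stability
    but unused.  ``drop_days`` restricts the considered patients to those
    arriving within that many days of the horizon start (the pilot method's
    drop policy).  ``instrument``, if given, counts completions under the
    key ``"gla_calls"`` and accumulates executed marginal utility under
    ``"delta_utility"``.
    """
    del tie_seed
    params = params or instance.params
    violations = feasibility_violations(initial_plan, instance)
    if violations:
        raise ValueError("infeasible initial plan: " + "; ".join(violations))
    if instrument is not None:
        instrument["gla_calls"] = instrument.get("gla_calls", 0) + 1
    plan = initial_plan.copy()
    ctx = SolveContext.build(instance, plan, params, drop_days=drop_days)
    state = UtilityMatrixState(ctx, plan)
    order = []
    delta = 0.0
    while True:
        pick = state.pick_best()
        if pick is None:
            break
        pid, bid, u = pick
        state.execute(pid, bid)
        order.append(pid)
        delta += u
    for pid in ctx.open_patients:
        if pid not in plan.assignments:
            plan.assignments[pid] = OVERFLOW
            order.append(pid)
    plan.meta["assignment_order"] = order
    plan.meta["delta_utility"] = delta
    if instrument is not None:
        instrument["delta_utility"] = instrument.get("delta_utility", 0.0) + delta
    return plan
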