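"""Exact reference solvers for the patient-bed assignment model.

``build_mip`` constructs a backend-agnostic mixed-integer model: binary
assignment variables, room age spread linearised through pairwise presence
constraints, department-homogeneity indicators, and ward-overload slack.
Its objective is identical to :func:`bedplan.utility.total_utility` for any
fixed assignment -- in particular, empty and single-occupant room-days
contribute zero age spread, matching the evaluator, so heuristics and the
exact solver are referred against one objective.

``solve_exact`` executes the model with the HiGHS solver through
``scipy.optimize.milp``; ``brute_force_optimum`` exhaustively enumerates all
feasible patient -> (bed | overflow) maps on guarded tiny instances and is
the fully independent oracle used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, sparse

from .domain import (
    Instance,
    Params,
    Plan,
    OVERFLOW,
    candidate_beds,
    prior_occupants,
    restrict_scope,
    validate_instance,
)
from .utility import assignment_feasible, marginal_utility, overflow_bonus, q_weight


@dataclass
class ModelDescription:
    """Sparse linear MIP: maximize c'v + constant s.t. lo <= A v <= hi."""

    var_names: list = field(default_factory=list)
    lb: list = field(default_factory=list)
    ub: list = field(default_factory=list)
    integrality: list = field(default_factory=list)  # 1 integer, 0 continuous
    objective: dict = field(default_factory=dict)    # var name -> coefficient
    constant: float = 0.0
    constraints: list = field(default_factory=list)  # (name, {var: coef}, lo, hi)
    x_pairs: dict = field(default_factory=dict)      # var name -> (pid, bid)

    def add_var(self, name, lo=0.0, hi=1.0, integer=True, obj=0.0):
        self.var_names.append(name)
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        if obj:
            self.objective[name] = obj
        return name

    def add_constraint(self, name, coefs, lo=-np.inf, hi=np.inf):
        self.constraints.append((name, coefs, lo, hi))

    def to_lp(self) -> str:
        """Serialize to CPLEX-style LP format."""
        def expr(coefs):
            parts = []
            for v, c in coefs.items():
                sign = "+" if c >= 0 else "-"
                parts.append(f"{sign} {abs(c):.12g} {v}")
            return " ".join(parts)

        lines = ["Maximize", " obj: " + expr(self.objective), "Subject To"]
        for name, coefs, lo, hi in self.constraints:
            if hi != np.inf:
                lines.append(f" {name}_u: {expr(coefs)} <= {hi:.12g}")
            if lo != -np.inf:
                lines.append(f" {name}_l: {expr(coefs)} >= {lo:.12g}")
        lines.append("Bounds")
        for v, lo, hi in zip(self.var_names, self.lb, self.ub):
            hi_s = "+inf" if hi == np.inf else f"{hi:.12g}"
            lines.append(f" {lo:.12g} <= {v} <= {hi_s}")
        ints = [v for v, i in zip(self.var_names, self.integrality) if i]
        if ints:
            lines.extend(["General", " " + " ".join(ints)])
        lines.append("End")
        return "\n".join(lines)


def _accumulate(coefs: dict, terms: dict, scale: float = 1.0):
    for v, c in terms.items():
        coefs[v] = coefs.get(v, 0.0) + scale * c


def build_mip(instance: Instance, initial_plan: Optional[Plan] = None,
              params: Optional[Params] = None) -> ModelDescription:
    params = params or instance.params
    plan = initial_plan or Plan()
    problems = validate_instance(instance)
    if problems:
        raise ValueError("invalid instance: " + "; ".join(problems))
    model = ModelDescription()
    rel_beds, rel_patients = restrict_scope(instance, plan)
    rel_beds = set(rel_beds)
    current = instance.horizon[0]
    max_age = float(params.max_age)

    # assignment variables; objective carries the basic patient utility
    bp = {}
    for pid in rel_patients:
        p = instance.patient_by_id[pid]
        bp[pid] = sorted(candidate_beds(p, plan, instance) & rel_beds)
        sumq = sum(q_weight(t, params.q) for t in p.stay_days() if t in instance.horizon)
        coef = params.alpha * (overflow_bonus(p, current, params.overflow_rate)
                               + params.xi(p) * sumq)
        for bid in bp[pid]:
            name = model.add_var(f"x_{pid}_{bid}", obj=coef)
            model.x_pairs[name] = (pid, bid)

    # presence expression of each candidate in each room-day of their stay
    pres = {}
    for pid in rel_patients:
        p = instance.patient_by_id[pid]
        for bid in bp[pid]:
            rid = instance.room_of_bed(bid).id
            for t in p.stay_days():
                if t in instance.horizon:
                    pres.setdefault((pid, rid, t), {})[f"x_{pid}_{bid}"] = 1.0

    # one bed per patient; one patient per bed-day
    for pid in rel_patients:
        if bp[pid]:
            model.add_constraint(f"onebed_{pid}",
                                 {f"x_{pid}_{bid}": 1.0 for bid in bp[pid]}, hi=1.0)
    for bid in sorted(rel_beds):
        for t in instance.horizon:
            coefs = {}
            for pid in rel_patients:
                if bid in bp[pid] and instance.patient_by_id[pid].present(t):
                    coefs[f"x_{pid}_{bid}"] = 1.0
            if len(coefs) > 1:
                model.add_constraint(f"bedday_{bid}_{t}", coefs, hi=1.0)

    for room in instance.rooms:
        for t in instance.horizon:
            prior = prior_occupants(room.id, t, plan, instance)
            cands = [pid for pid in rel_patients if (pid, room.id, t) in pres]

            # age spread: s >= age_i - age_j when both people are present;
            # rearranged: s - M*sum(pres of candidate members) >= diff - M*(2 - n_prior)
            people = ([(None, p.age) for p in prior]
                      + [(pid, instance.patient_by_id[pid].age) for pid in cands])
            if len(people) >= 2 and cands:
                sname = model.add_var(f"s_{room.id}_{t}", lo=0.0, hi=max_age,
                                      integer=False, obj=-params.beta)
                for ii, (pi, ai) in enumerate(people):
                    for jj, (pj, aj) in enumerate(people):
                        if ai <= aj:
                            continue
                        coefs = {sname: 1.0}
                        n_prior = 0
                        for member in (pi, pj):
                            if member is None:
                                n_prior += 1
                            else:
                                _accumulate(coefs, pres[(member, room.id, t)], -max_age)
                        lo = (ai - aj) - max_age * (2 - n_prior)
                        model.add_constraint(
                            f"sp_{room.id}_{t}_{ii}_{jj}", coefs, lo=lo)
            elif len(prior) >= 2:
                ages = [p.age for p in prior]
                model.constant -= params.beta * (max(ages) - min(ages))

            # gender / isolation exclusion among this run's candidates
            for i, pid in enumerate(cands):
                pi = instance.patient_by_id[pid]
                for pjd in cands[i + 1:]:
                    pj = instance.patient_by_id[pjd]
                    if pi.gender != pj.gender or pi.isolation or pj.isolation:
                        coefs = {}
                        _accumulate(coefs, pres[(pid, room.id, t)])
                        _accumulate(coefs, pres[(pjd, room.id, t)])
                        model.add_constraint(
                            f"excl_{room.id}_{t}_{pid}_{pjd}", coefs, hi=1.0)

            # department homogeneity (y for prior-empty, z for pre-occupied)
            if not cands:
                continue
            prior_depts = {p.department for p in prior}
            if not prior:
                yname = model.add_var(f"y_{room.id}_{t}", obj=params.gamma)
                coefs = {yname: -1.0}
                for pid in cands:
                    _accumulate(coefs, pres[(pid, room.id, t)])
                model.add_constraint(f"ylink_{room.id}_{t}", coefs, lo=0.0)
                for i, pid in enumerate(cands):
                    for pjd in cands[i + 1:]:
                        if (instance.patient_by_id[pid].department
                                != instance.patient_by_id[pjd].department):
                            coefs = {yname: 1.0}
                            _accumulate(coefs, pres[(pid, room.id, t)])
                            _accumulate(coefs, pres[(pjd, room.id, t)])
                            model.add_constraint(
                                f"ymix_{room.id}_{t}_{pid}_{pjd}", coefs, hi=2.0)
            elif len(prior_depts) == 1:
                dstar = next(iter(prior_depts))
                zname = model.add_var(f"z_{room.id}_{t}", obj=params.gamma)
                coefs = {zname: -1.0}
                for pid in cands:
                    _accumulate(coefs, pres[(pid, room.id, t)])
                model.add_constraint(f"zlink_{room.id}_{t}", coefs, lo=0.0)
                for pid in cands:
                    if instance.patient_by_id[pid].department != dstar:
                        coefs = {zname: 1.0}
                        _accumulate(coefs, pres[(pid, room.id, t)])
                        model.add_constraint(
                            f"zmix_{room.id}_{t}_{pid}", coefs, hi=1.0)

    # ward care overload slack
    for ward in instance.wards:
        ward_beds = {bid for rid in ward.room_ids for bid in instance.beds_in_room(rid)}
        for t in instance.horizon:
            coefs = {}
            for pid in rel_patients:
                p = instance.patient_by_id[pid]
                if not p.present(t):
                    continue
                for bid in bp[pid]:
                    if bid in ward_beds:
                        coefs[f"x_{pid}_{bid}"] = p.care_level
            if not coefs:
                continue
            oname = model.add_var(f"o_{ward.id}_{t}", lo=0.0, hi=np.inf,
                                  integer=False, obj=-params.delta)
            coefs[oname] = -1.0
            model.add_constraint(f"cap_{ward.id}_{t}", coefs, hi=ward.capacity(t))

    return model


def fix_assignments(model: ModelDescription, plan: Plan) -> ModelDescription:
    """Impose a fixed assignment through variable bounds (oracle equality tests)."""
    chosen = {(pid, bid) for pid, bid in plan.assigned_patients().items()}
    assigned_pids = set(plan.assignments)
    for i, vname in enumerate(model.var_names):
        pair = model.x_pairs.get(vname)
        if pair is None:
            continue
        if pair in chosen:
            model.lb[i] = 1.0
        elif pair[0] in assigned_pids:
            model.ub[i] = 0.0
    return model


def solve_exact(model: ModelDescription, instance: Instance,
                initial_plan: Optional[Plan] = None,
                time_limit_seconds: Optional[float] = None):
    """Solve with HiGHS; returns (plan or None, best bound, gap, status)."""
    base = (initial_plan or Plan()).copy()
    base.meta.clear()
    if time_limit_seconds is not None and time_limit_seconds <= 0:
        return None, float("inf"), None, "no_feasible_solution"
    n = len(model.var_names)
    index = {v: i for i, v in enumerate(model.var_names)}
    c = np.zeros(n)
    for v, coef in model.objective.items():
        c[index[v]] = -coef  # scipy minimizes
    if model.constraints:
        rows, cols, vals, los, his = [], [], [], [], []
        for k, (_name, coefs, lo, hi) in enumerate(model.constraints):
            for v, coef in coefs.items():
                rows.append(k)
                cols.append(index[v])
                vals.append(coef)
            los.append(lo)
            his.append(hi)
        a = sparse.csr_matrix((vals, (rows, cols)),
                              shape=(len(model.constraints), n))
        constraints = [optimize.LinearConstraint(a, np.array(los), np.array(his))]
    else:
        constraints = []
    options = {}
    if time_limit_seconds is not None:
        options["time_limit"] = float(time_limit_seconds)
    res = optimize.milp(
        c=c,
        constraints=constraints,
        integrality=np.array(model.integrality) if n else None,
        bounds=optimize.Bounds(np.array(model.lb, dtype=float),
                               np.array(model.ub, dtype=float)) if n else None,
        options=options,
    )
    if res.x is None:
        return None, float("inf"), None, "no_feasible_solution"
    value = -res.fun + model.constant
    bound = -getattr(res, "mip_dual_bound", -res.fun) + model.constant
    gap = getattr(res, "mip_gap", 0.0 if res.status == 0 else None)
    plan = base
    assigned = set()
    for vname, (pid, bid) in model.x_pairs.items():
        if res.x[index[vname]] > 0.5:
            plan.assignments[pid] = bid
            assigned.add(pid)
    _beds, rel_patients = restrict_scope(instance, initial_plan or Plan())
    for pid in rel_patients:
        if pid not in assigned:
            plan.assignments.setdefault(pid, OVERFLOW)
    plan.meta.update(objective=value, bound=bound, gap=gap)
    status = "optimal" if res.status == 0 else "incumbent"
    return plan, bound, gap, status


def brute_force_optimum(instance: Instance, initial_plan: Optional[Plan] = None,
                        params: Optional[Params] = None) -> Plan:
    """Exhaustive search over all feasible patient -> (bed | overflow) maps.

    Guarded to tiny instances (<= 8 relevant beds and patients, horizon <= 3).
    The leaf value telescopes from-scratch marginal utilities, which equals
    the total-utility difference to the empty assignment; ties break
    lexicographically over the per-patient choice sequence (beds in id order,
    overflow last), so the result is deterministic.
    """
    params = params or instance.params
    plan0 = (initial_plan or Plan()).copy()
    plan0.meta.clear()
    rel_beds, rel_patients = restrict_scope(instance, plan0)
    if len(rel_beds) > 8 or len(rel_patients) > 8 or len(instance.horizon) > 3:
        raise ValueError(
            f"brute force guard exceeded: {len(rel_beds)} beds, "
            f"{len(rel_patients)} patients, |T|={len(instance.horizon)}")
    patients = sorted(rel_patients)
    bp = {pid: sorted(candidate_beds(instance.patient_by_id[pid], plan0, instance)
                      & set(rel_beds))
          for pid in patients}

    best = {"value": float("-inf"), "choices": None}
    plan = plan0.copy()
    choices = []

    def dfs(i, acc):
        if i == len(patients):
            key = tuple(choices)
            if acc > best["value"] + 1e-12 or (
                    abs(acc - best["value"]) <= 1e-12
                    and (best["choices"] is None or key < best["choices"])):
                best["value"] = acc
                best["choices"] = key
            return
        pid = patients[i]
        p = instance.patient_by_id[pid]
        bpset = set(bp[pid])
        for k, bid in enumerate(bp[pid]):
            if not assignment_feasible(p, bid, plan, instance, bp=bpset):
                continue
            u = marginal_utility(p, bid, plan, instance, params, bp=bpset)
            plan.assignments[pid] = bid
            choices.append(k)
            dfs(i + 1, acc + u)
            choices.pop()
            del plan.assignments[pid]
        plan.assignments[pid] = OVERFLOW
        choices.append(len(bp[pid]))
        dfs(i + 1, acc)
        choices.pop()
        del plan.assignments[pid]

    dfs(0, 0.0)
    result = plan0.copy()
    for pid, k in zip(patients, best["choices"]):
        result.assignments[pid] = bp[pid][k] if k < len(bp[pid]) else OVERFLOW
    result.meta["delta_utility"] = best["value"]
    return result
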