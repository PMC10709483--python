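"""Pilot-method hyper-heuristic wrapping the GLA subheuristic.

The pilot method avoids the greedy heuristic's local-optimum traps by
look-ahead: at each of ``depth`` iterations it draws a set of candidate
first moves ("pilots"), completes each tentative partial solution with the
GLA subheuristic, evaluates the completed plans with the full objective, and
commits only the best first move into the master solution.  After ``depth``
committed moves the remaining patients are assigned by one final GLA run.

Three policies bound the effort:

* *filter* -- only ``n_pilots`` pilots are drawn per iteration, sampled from
  the candidate assignments of the five most promising patients by U^max;
* *drop* -- completions only consider patients arriving within ``drop_days``
  of the horizon start;
* *evaluation depth* -- only ``depth`` moves are pilot-committed.

With ``depth=0`` the method degenerates to plain GLA, bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .domain import Instance, Params, Plan
from .gla import SolveContext, UtilityMatrixState, solve_gla
from .utility import feasibility_violations

TOP_PATIENT_POOL = 5  # pilots are drawn from the five most promising patients


@dataclass(frozen=True)
class PilotPolicy:
    n_pilots: int = 5
    depth: int = 5
    drop_days: Optional[int] = None
    seed: int = 0


def subheuristic_call_count(n_pilots: int, depth: int) -> int:
    """Number of GLA completions the pilot search performs when candidate
    pilots never run out: one per pilot per committed move."""
    return n_pilots * depth


def draw_pilots(state: UtilityMatrixState, filter_size: int, rng: np.random.Generator) -> list:
    """Sample `filter_size` distinct (patient, bed) pilots.

    The pool is every positive-utility candidate assignment of the (up to)
    five open patients with the largest ``U^max_p``; the whole pool is
    returned when it is not larger than the filter size.
    """
    ranked = sorted(
        (pid for pid in state.best if state.best[pid][0] > 0.0),
        key=lambda pid: (-state.best[pid][0], pid),
    )[:TOP_PATIENT_POOL]
    pool = [(pid, bid) for pid in ranked
            for bid, u in sorted(state.entries[pid].items()) if u > 0.0]
    if len(pool) <= filter_size:
        return pool
    idx = rng.choice(len(pool), size=filter_size, replace=False)
    return [pool[i] for i in sorted(idx)]


def solve_pilot(instance: Instance, initial_plan: Plan, params: Optional[Params] = None,
                policy: PilotPolicy = PilotPolicy(),
                instrument: Optional[dict] = None) -> Plan:
    """Pilot-method search over first moves, completed by the GLA heuristic."""
    params = params or instance.params
    violations = feasibility_violations(initial_plan, instance)
    if violations:
        raise ValueError("infeasible initial plan: " + "; ".join(violations))
    rng = np.random.default_rng(policy.seed)
    master = initial_plan.copy()
    master.meta.clear()

    for _ in range(policy.depth):
        ctx = SolveContext.build(instance, master, params)
        state = UtilityMatrixState(ctx, master.copy())
        pilots = draw_pilots(state, policy.n_pilots, rng)
        if not pilots:
            break
        best = None  # (utility delta, pid, bid)
        for pid, bid in pilots:
            trial = master.copy()
            trial.meta.clear()
            u_pilot = state.marginal(pid, bid)
            trial.assignments[pid] = bid
            completed = solve_gla(instance, trial, params,
                                  drop_days=policy.drop_days, instrument=instrument)
            u = u_pilot + completed.meta["delta_utility"]
            key = (u, -pid, -bid)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (u, pid, bid)
        master.assignments[best[1]] = best[2]

    final = solve_gla(instance, master, params)
    final.meta["pilot_committed"] = len(master.assignments) - len(initial_plan.assignments)
    return final
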