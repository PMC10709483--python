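# bedplan

Operational **patient-bed assignment (PBA)** for hospitals: which inpatient
goes into which physical room and bed, over a short rolling planning horizon,
under continuous arrivals, discharges, length-of-stay (LOS) revisions and
no-shows — with a forecasting layer that anticipates emergency admissions per
medical department from calendar, weather and event metadata.

The package is aimed at healthcare operations researchers and hospital bed
managers who need a testable, end-to-end reference implementation: the
multi-stakeholder utility model, a greedy look-ahead (GLA) heuristic, a
pilot-method hyper-heuristic on top of it, a genetic-algorithm benchmark, an
exact mixed-integer oracle, an event-driven rolling-horizon simulator, the
emergency-arrival forecasting stack, and seeded synthetic-data generators so
everything runs without access to confidential hospital records.

## The model

A plan assigns each open patient `p` a bed `b` (binary `x_{b,p}`) or sends
them to an overflow buffer. The objective balances four stakeholder terms:

```
maximize  U = α · Σ_p Σ_{b∈B_p} (OF_p + Ξ_p · Σ_{t∈stay(p)} Q_t) · x_{b,p}     (patients)
            − β · Σ_{r,t} (a_max[r,t] − a_min[r,t])                            (roommate compatibility)
            + γ · Σ_{r,t} (F[r,t]·y[r,t] + (1−F[r,t])·z[r,t])                  (doctors' walking distance)
            − δ · Σ_{w,t} o⁺[w,t]                                              (nurse workload)
```

subject to: one bed per patient, one patient per bed-day, single-gender
rooms, bed infrastructure ⊇ patient requirements, and medical isolation
(single-occupancy rooms). `Q_t = (1−q)^t` discounts far-future days, `Ξ_p`
weights patient types (electives 10, emergencies 9, anticipated emergencies
4), `OF_p` rewards patients already waiting in overflow, the age spread
`a_max − a_min` per room-day proxies roommate compatibility, `y`/`z` flag
department-homogeneous rooms, and `o⁺` is the care load of newly assigned
patients above a ward-day's spare capacity. Default weights: `α=1, β=0.1,
γ=δ=2, q=0.01`, a 7-day horizon.

Solvers:

* **GLA** — repeatedly execute the globally best feasible assignment by
  marginal utility `U_{b,p}`, with incremental updates of affected entries;
* **pilot hyper-heuristic** — evaluate candidate first moves by completing
  each with GLA, commit the best, repeat up to an evaluation depth; filter
  (pilots sampled from the five most promising patients) and drop (arrival
  window) policies bound the effort;
* **GA** — permutation-encoded genetic algorithm, GLA-seeded and elitist, so
  it never returns less than the GLA plan;
* **exact** — the full MIP (HiGHS via SciPy), plus a brute-force enumeration
  oracle for tiny instances.

The rolling simulator re-solves the static model at every event and scores
the realized occupancy; the forecasting layer (per-weekday baseline,
Holt-Winters, SARIMA, ridge/lasso/elastic-net/group-lasso, MLP) feeds
anticipated emergency stubs into each day's plan.

## Worked example

```python
from bedplan import solve_gla, solve_pilot, total_utility
from bedplan.pilot import PilotPolicy
from bedplan.synthetic import generate_single_instance

inst, init = generate_single_instance(seed=0, n_wards=1, beds_per_ward=24)
gla = solve_gla(inst, init)
u = total_utility(gla, inst)
pilot = solve_pilot(inst, init, policy=PilotPolicy(n_pilots=20, depth=20, seed=1))
v = total_utility(pilot, inst)
```

prints (via the obvious format strings):

```
pre-occupied beds: 12 | open patients: 21
GLA   utility   471.39  (patients 496.39, age spread -39.00, dept bonus +88, overload -74; overflow 2)
Pilot utility   508.36  (+7.84% vs GLA)
```

Reading: on this 24-bed, one-ward instance with 12 beds pre-occupied, the
greedy heuristic places 19 of 21 open patients (2 wait in overflow); its
utility decomposes into the patient term (496.39), an age-spread penalty of
39.0 weighted by β=0.1, a department bonus for 44 homogeneous room-days, and
a care-overload penalty. The pilot search (20 pilots, depth 20 — 400 GLA
completions) finds a plan 7.8% better by rearranging the early, binding
assignments.

The same flows are scriptable from a shell:

```bash
bedplan generate --kind single --seed 0 --wards 1 --beds-per-ward 24 --out inst.json
bedplan solve inst.json --algorithm pilot --pilots 20 --depth 20 --seed 1 --out plan.json
bedplan benchmark --oracle --n-instances 10 --seed 1
```

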