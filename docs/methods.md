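# Methods

## Decision model

One planning run assigns the *open* patients — just arrived, waiting in
overflow, scheduled electives, and anticipated emergencies — to beds over a
horizon of days `t = 1..|T|` (default `|T| = 7`, day 1 = today). Patients
already lying in a ward bed are *prior occupants*: data, not decisions, since
non-medical room transfers are not allowed. A stay is the half-open interval
`[arrival, arrival + LOS)`, so a bed is reusable on the discharge day.

The objective `U = α·T1 − β·T2 + γ·T3 − δ·T4` combines:

* **T1, basic patient utility.** Each assignment contributes
  `OF_p + Ξ_p · Σ_t Q_t` over the in-horizon stay days, with
  `Q_t = (1−q)^t`. `Ξ_p` defaults to 10 / 9 / 4 for elective / emergency /
  anticipated patients; `OF_p = ω ×` (whole days already waited in overflow),
  ω = 1 per day. ω is a modeling choice (the linear form is the simplest
  monotone prioritisation of long-waiting patients); it is configurable.
* **T2, roommate compatibility.** Per room-day, the age spread
  `max age − min age` over everyone present (prior occupants and new
  assignees). Empty and single-occupant room-days contribute **zero**. A
  literal reading of the age-linearisation constraints would let an empty
  room contribute its `A_max − A_min = 0 − 120` convention values; the
  evaluator, the incremental solver state and the MIP all encode the
  people-in-the-room semantics instead, so every solver optimises the same
  function.
* **T3, department homogeneity.** +1 per room-day where at least one patient
  is newly assigned and the room is homogeneous: for an initially empty room,
  all assignees share one department; for a pre-occupied room, the prior
  occupants must already be homogeneous and every assignee must match their
  department. The pre-occupied indicator therefore carries the common
  department *id*, not just a binary flag.
* **T4, nurse workload.** Per ward-day, `max(0, Σ c_p − C_{w,t})` where the
  care-level sum runs over **newly assigned** patients present that day and
  `C_{w,t}` is the spare capacity for further patients.

Hard constraints: ≤ 1 bed per patient; ≤ 1 patient per bed-day; single-gender
rooms (including prior occupants); bed features ⊇ patient requirements;
medical isolation read strictly — an isolating patient needs a room that is
empty for their whole stay, and nobody joins an isolated patient. Ward
eligibility is not a hard constraint; department preferences act only through
T3. Candidate sets `B_p` (beds available to a patient) check blocks, prior
occupancy, infrastructure, gender and isolation against prior occupants;
conflicts among this run's assignments are handled by the solvers and the
feasibility checker.

## Solvers

**GLA (greedy look-ahead).** Builds the marginal-utility matrix `U_{b,p}`
over the relevant beds `B̄` (those vacated within the horizon) and open
patients `P̄`, keeps per-patient maxima `U^max_p`/`U^argmax_p`, executes the
best strictly positive assignment, and updates only the entries the executed
move can touch: the same room (spread/homogeneity/bed conflicts) and — only
on days where the ward care load crossed the spare-capacity kink — the whole
ward. The marginal of any remaining candidate is otherwise provably
unchanged, and property tests assert exact (1e−9) agreement between the
incremental state and a from-scratch recomputation at every step.
Negative-marginal assignments are never executed; those patients wait in
overflow and re-enter later runs with a larger `OF_p`. Ties break on lowest
patient id, then lowest bed id, making the heuristic fully deterministic.

**Pilot hyper-heuristic.** For each of `depth` iterations: rank open patients
by `U^max_p`, pool every positive-utility (patient, bed) pair of the top five
patients, sample `n_pilots` distinct pairs (the whole pool when smaller),
complete each tentative move with a GLA run (optionally restricted by the
drop policy to patients arriving within `drop_days`), and commit the move
whose completed plan scores best (ties: utility, then lowest patient id, then
bed id). A pilot is a single (patient, bed) assignment. The remainder is
completed by one unrestricted GLA run, so `depth = 0` reproduces GLA
bit-for-bit. The instrumented completion counter equals `n_pilots × depth`
whenever the pool never runs dry. With an exhaustive filter the method can
never fall below GLA (the greedy move is always among the evaluated pilots);
with sampling, single runs may dip below GLA, but the mean over repeated runs
dominates on the synthetic single instances tested.

**GA benchmark.** Chromosome = priority permutation of open patients, decoded
by greedy best-bed insertion (always feasible); order crossover, swap
mutation, binary tournament, one elite. The GLA plan's assignment order
decodes back to the GLA plan and is injected into generation 0, so with
elitism the GA is never worse than GLA. Defaults follow common practice for
this benchmark: population 50, 100 generations, crossover 0.8, mutation 0.2.
`repair_plan` additionally turns arbitrary patient→bed maps into feasible
plans (offenders move to their best feasible bed or overflow, processed by
descending patient weight).

**Exact oracle.** A backend-agnostic MIP (LP-format export) solved with
HiGHS through `scipy.optimize.milp`: binary `x_{b,p}`, per-room-day spread
variables bounded below by every pairwise age difference of potentially
present people (presence = linear expression in `x`), homogeneity indicators
with pairwise mixing cuts, and ward-overload slacks. For any fixed
assignment its objective equals `total_utility` to 1e−6 (tested). A DFS
enumeration over all patient → (bed | overflow) maps, guarded to ≤ 8 beds,
≤ 8 patients, ≤ 3 days, is the fully independent second oracle; tie-breaks
are lexicographic so it is deterministic.

## Rolling-horizon simulator

Every event (elective registration, arrival, emergency arrival, discharge,
LOS update, no-show) is one stage: the state is updated, anticipated
emergency stubs are refreshed at the first event of each day (counts =
forecast rounded to nearest; LOS = the department's median emergency LOS;
gender drawn at the instance's ratio; weight `Ξ^an`), the static model is
re-solved on the 7-day window, and assignments are committed only for
patients physically present — committed patients never move. Intra-day order
processes discharges before admissions so freed beds are usable the same
day. Realized utility is computed from the committed occupancy history with
the planning terms: per patient `ω ×` overflow days + `Ξ_p Σ_k Q_k` over
occupied days (k from the first bed day), per room-day spread and
homogeneity over actual occupants, and per ward-day overload of that day's
admissions against spare capacity. Anticipated stubs never enter the
realized score. Normalisation across solvers divides by the GLA run's
realized utility.

## Forecasting layer

Per department, daily emergency arrivals are a regression target on the
metadata table (weekday/season one-hots, school/bank holiday and
post-holiday flags, temperature/air-pressure/humidity/wind aggregates with
intra-day ranges, precipitation/snow-cover/storm flags, fair and sport-event
flags, lag-1 admissions). The pipeline: chronological 2-year-train /
1-year-test split; greedy Pearson screen dropping one member of every pair
with `|PCC| ≥ 0.7` (column order decides, so in a chain a~b~c the middle
member is dropped); shadow-feature selection; eight forecasters.

Shadow-feature selection fits a random forest on [active features |
permuted shadow copies] each round and scores a hit when a feature's
permutation importance beats the best shadow. Two deliberate choices:
importances are evaluated on a held-out third of the rows (train-set
permutation importance rewards whatever a forest memorises, which
systematically favours continuous noise over sparse binary drivers), and
features already binomially below the fair coin after a burn-in are
eliminated, shrinking the shadow pool the survivors compete against —
without elimination, genuine but moderate drivers rarely clear the max of
~30 shadows. Defaults: 40 trees, all features per split, 20 rounds, burn-in
5, significance 0.05.

Forecasters: per-weekday historical mean (baseline); Holt-Winters additive
trend/seasonality with period 7, parameters by one-step squared-error
minimisation; SARIMA with `d` from an augmented Dickey-Fuller test and
(p, q, P, Q ≤ 1, s = 7) chosen by AIC; ridge / lasso / elastic net with
10-fold CV (elastic-net mixing searched 0.025 … 1 in 0.025 steps); group
lasso (own implementation: proximal gradient on standardized features,
`√p_g`-weighted group-l2 penalty, CV over a geometric λ path) with one group
per metadata factor block; and an MLP (hidden layers 32:16:8:4:2, ReLU, MSE
loss, l2 penalty, adam, early stopping on a validation split). Predictions
are clipped at zero; counts stay real-valued until anticipation rounds them.

## Synthetic data — what it emulates and what it does not

`generate_hospital` defaults to the study cluster shape: 5 wards × 24 beds in
two-bed rooms, two departments, per-ward-day spare capacity drawn from
6–10 care units (calibrated so a realistic fraction of ward-days is tight);
a quarter of beds carry a telemetry feature. `generate_patient_stream`
defaults: 648 unique patients per 28 days (scaled by stream length), 40%
men, mean age 70 (sd 12, clipped 18–100), LOS shifted-geometric with mean 6,
80% emergencies arriving Poisson per day and department, electives
registered 3–10 days ahead, 5% no-shows, and a 25% per-present-day chance of
a ±1-day LOS revision — that revision density reproduces the reported event
volume (~1,500 unique events per 21 days) and the observation that a fifth
of inpatients see LOS updates on a given day. `generate_single_instance`
freezes uncertainty (exactly known stays, pre-announced emergencies) for the
static benchmark protocol, with half the beds pre-occupied.

`generate_metadata_series` plants log-linear Poisson drivers: a trauma-like
department (winter quarter +0.35, standardized minimum temperature −0.30,
standardized temperature swing +0.20) and a gastro-like department (bank
holiday +0.60, Saturday/Sunday/Monday +0.35 each). The holiday coefficient
is larger because the flag is active on only ~8 days/year: detectability of
a binary driver scales with effect² × frequency, and the planted scenario is
meant to make its drivers clearly recoverable. Continuous weather follows
seasonal sinusoids plus Gaussian noise; calendar features are exact;
ground-truth coefficients are returned for recovery tests. Counts are pure
Poisson by default (`overdispersion` adds gamma mixing when wanted).

None of this reproduces a real hospital's joint distributions: arrivals are
independent across days given the rate, LOS is memoryless, no patient
transfers between departments, and weather is stationary apart from the
seasonal cycle. Passing tests therefore demonstrate correctness of the
algorithms and the stated directional effects under these planted
conditions, not clinical performance.

## Experiment scaling and numerical conventions

* Oracle equivalence runs on 50 (tests) / 30 (acceptance script) random tiny
  instances of 3–5 beds, 3–4 patients, 2–3 days — inside the enumeration
  guard; agreement tolerance 1e−6, heuristic dominance tolerance 1e−9.
* The sampled-pilot experiment uses the full policy (20 pilots, depth 20,
  20 repetitions in tests / 10 in the script) on 24-bed single-ward
  instances; six (tests) / four (script) instances keep the run inside a
  desktop-scale budget.
* Forecasting direction uses 20 seeds (tests) / 10 (script) of the 3-year
  planted series; feature recovery uses 20 seeds for the strong-driver
  simulation and 6 / 4 seeds for the generator scenario, where recovery is
  asserted through each driver's correlation-screen representative (if the
  screen drops `T_min` for `T_mean`, confirming `T_mean` counts).
* Degenerate inputs: empty rooms score zero spread; a constant regression
  target or an empty test set raises; forecasts below zero are clipped;
  `q = 0` gives `Q_t ≡ 1`; a zero time limit for the exact solver reports
  "no feasible solution" rather than an empty plan.
* All stochastic components (generators, pilot sampling, GA, forest rounds)
  take explicit integer seeds; reruns with equal seeds are bit-identical.
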