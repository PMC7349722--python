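# Methods

## The simulated emergency department

The simulator is a continuous-time discrete-event model. Patients arrive
by a homogeneous Poisson process (default 7/hour; the scenario grid
raises it to 8, 9 and 10). On arrival a patient receives an acuity level
drawn from the occurrence ratios (0.10, 0.30, 0.40, 0.10, 0.10 for
levels 1–5) and one of eleven treatment patterns. Every pattern begins
triage → registration → evaluation and ends in discharge or admission;
the middle varies over laboratory, X-ray, consultation and CT steps.
Both the acuity and the pattern are known the moment the patient
arrives; the *actual* duration of a treatment is revealed only when the
treatment finishes, so schedulers may use only average processing times.

Four pooled resource groups perform the treatments: doctors (triage,
evaluation), nurses (registration, laboratory, consultation, discharge,
admission), one X-ray technician and one CT technician, with capacities
{3, 5, 1, 1}. A unit serves one patient at a time; there are no travel
times, no treatment interruptions, no skill differentiation, no beds,
and acuity never changes during the stay — all deliberate
simplifications of a real ED.

**The laboratory is an unlimited-capacity station.** Although the
laboratory treatment is administratively a nurse task, lab work is
modelled as starting immediately and consuming no nurse unit. This is
not a convenience: with the laboratory's 35-minute mean occupying
nurses, the nurse group's offered load at 7 arrivals/hour already
exceeds its capacity (≈ 51.3 min of nurse work per patient × 7/h against
5 × 60 min/h, utilisation ≈ 1.20), and the system would be saturated in
the *normal* scenario — every scheduler would drown. With the lab
unconstrained, group utilisations at 7/hour are ≈ 0.82 (doctor), 0.75
(nurse), 0.76 (X-ray), 0.61 (CT); the doctor group saturates around
9–10/hour, which reproduces the qualitative escalation the scenario grid
is designed to probe (moderate congestion at 7/hour, near-total penalty
saturation at 10/hour).

**Event semantics.** Events are processed in non-decreasing time;
simultaneous events are ordered service-end < arrival < training-tick,
and within a kind by ascending patient id. After each event, idle units
are matched to waiters group by group in the fixed order doctor, nurse,
X-ray, CT: the scheduler is asked repeatedly for one patient until the
idle set or the waiting list empties, and a selected patient starts
service immediately (the model is work-conserving). Waiting time for a
step is service start minus the time the patient became ready for it.

**Randomness and common random numbers.** All stochastic patient
attributes — arrival times, acuities, patterns, and the actual duration
of every (patient, step) — are drawn when the instance is generated,
before any scheduling happens. Durations are therefore identical across
schedulers for a given instance seed (common random numbers), scheduling
order cannot perturb the draws, and runs are bit-identical under a fixed
seed. No scheduler API exposes a duration before the treatment ends, so
pre-drawing does not leak information the model says is unknown.
Exponential entries are parameterised by their mean in minutes (a *rate*
of 7/min for triage would imply 8.6-second triage). Normal durations are
truncated below at 0.1 minute by resampling, which biases the
35/15-minute lab and the 14/6-minute evaluation means upward by well
under 2%; the discharge step is a 30-minute constant.

**Warm-up and censoring.** Instances are 14 days long. Metrics are
computed only over patients *arriving* after the first simulated day
(exclusion by arrival time is unambiguous), and only over patients
discharged by the horizon; patients still in the system are reported
separately as censored, since their stays are right-censored and any
imputation would bias the penalty share under overload.

## Pattern frequencies — what the generator does and does not emulate

The eleven patterns cover the bulk of observed ED processes, but their
empirical frequencies are not public. The generator defaults to a
**uniform** distribution over the eleven patterns, overridable through
`pattern_weights` in configuration. This choice fixes the offered load,
and the absolute penalty level of non-acuity-aware rules in the
moderately loaded scenario is quite sensitive to it: under the uniform
mix, FCFS at 7/hour produces a penalty share of roughly 15–17%, whereas
a mix weighting nurse- and X-ray-heavy patterns more strongly pushes the
same statistic several times higher before the saturated scenarios are
reached. Results at the saturated end (10/hour) and all *relative*
orderings between schedulers — acuity-aware rules dominating FCFS and
critical ratio, AW close to the DQN scheduler in the normal scenario,
AA starving acuity-5 patients under overload — are insensitive to the
mix in our experiments. Consequently, passing tests demonstrate the
mechanics and the orderings, not that absolute penalty levels transfer
to any particular real ED.

## The scheduling MDP

*State.* For each group, the waiting-list composition as ratios: the
share of each acuity level (5 entries) and the share of each treatment
type the group performs, concatenated over the four groups in fixed
order — 29 entries, each in [0, 1]. Ratios standardise the scale
regardless of queue length; an empty list maps to the all-zero vector
(the ratio is undefined at zero waiters, and zeros read naturally as
"nothing waiting"). Counting first and dividing once keeps point masses
exact. The state is permutation-invariant in each list.

*Action.* Selecting one patient from the deciding group's waiting list.
A candidate is described by 12 features: acuity level, accumulated
acuity-weighted waiting time (including the still-open wait), a one-hot
over all nine treatment codes for the awaited treatment, and that
treatment's average processing time. The one-hot spans all nine codes
globally because a single network serves all four groups. Features are
fed raw; an optional min–max scaler for the two time-valued features
exists but is off by default (only the state ratios are standardised).

*Reward.* Minus the acuity-weighted waiting time the selected patient
has accumulated at the moment of selection — all closed waits plus the
wait the selection terminates. It is never positive, it is zero for a
patient that never waited, and summed over an episode it recovers (with
a sign flip) the weighted waiting the objective counts, which the test
suite verifies by recomputation from the event log. One boundary case:
the wait preceding the final discharge treatment enters through the
selection that starts that treatment, so no separate terminal reward is
needed.

## The DQN scheduler

One fully connected network maps state ⊕ candidate-features (41 inputs)
through hidden layers of 64, 32 and 2 leaky-ReLU units (slope 0.01) to a
single linear Q-value. The printed layer-size convention ends at width 2;
since the network's job is one scalar per (state, candidate) pair, a
linear scalar head follows the width-2 layer. Scoring a waiting list is
one batched forward pass; action selection is epsilon-greedy with ties
broken toward the lowest patient id. The same candidate-scoring path
produces the next-state maxima for the training targets, so the variable
action set is handled identically on both sides of the Bellman error.

Training: transitions (state, chosen candidate's features, reward, next
decision's state and candidate inputs) accumulate in a 2000-entry FIFO
replay memory. Every 60 simulated minutes, once the memory is at least
half full, one uniform minibatch of 100 is drawn and one Adam step taken
on the squared error between Q and r + γ·max over the next decision's
candidates under the target network (r alone when the episode ended
before another decision). The target network syncs to the online network
once per episode. Epsilon decays multiplicatively **per episode**
(default 0.999, floor 1e-8): with thousands of decisions per day, a
per-decision decay of 0.999 would extinguish exploration within the
first episode, while per-episode decay matches a ~1000-episode budget; a
per-decision variant remains available behind
`epsilon_decay_scope="step"`. A configuration switch
(`state_scope="group"`) feeds only the deciding group's state block
(zero-masked elsewhere) for experiments on locality; the global state is
the default. Divergent (non-finite) losses abort with a diagnostic.

Defaults: learning rate 1e-7 (Adam), discount 0.9999, epsilon 1 → 0.999
decay → 1e-8 floor, memory 2000, batch 100, 1000 episodes, each episode
one 14-day instance at 7 arrivals/hour.

**What the learning rate implies, honestly.** Adam's per-parameter step
is bounded by roughly the learning rate, so a 1000-episode run (~336
ticks/episode) moves any weight by at most ~3×10⁻², and a reduced
25-episode run by ~10⁻³ — far too little to reshape a randomly
initialised network whose targets are in the hundreds of weighted
minutes. The trained policy's behaviour is therefore dominated by the
*structure* of the scoring (per-candidate Q over the acuity, weighted
wait and treatment features) and the initialisation, not by gradient
descent; at the default learning rate, trained and untrained networks
select nearly identically. Empirically this greedy per-candidate scoring
nevertheless keeps the normal-scenario penalty share near the
acuity-aware rules (typically 1–2%, seed-dependent) and well below
FCFS/SRPT/critical-ratio, and it keeps discharging acuity-5 patients
under overload where the strict acuity-first rule starves them. The
learning *machinery* is validated separately: on a two-candidate toy
problem with a feasible learning rate (1e-2), the same code drives the
Q-values to the known rewards and the greedy policy to the brute-force
optimum. Users who want the network to actually learn on this problem
should raise the learning rate and/or normalise rewards; both are plain
configuration.

## Dispatching rules

All rules are total and deterministic on non-empty lists; every tie
breaks toward the lowest patient id. With wa the weighted acuity
(5 for level 1 … 1 for level 5), c the waiting weight, ar the arrival
time, and apt the average processing times:

| rule | quantity | orientation |
|------|----------|-------------|
| FCFS | ar | min |
| SRPT | Σ remaining apt | min |
| CR | (ar + Σ total apt − t) / Σ remaining apt | min |
| AS | (wk1 + wk2·wa) · Σ remaining apt | **max** (flag for min) |
| AW | (wk1 + wk2·wa) · c · (t − ar − completed processing) | max |
| AA | (acuity level, ar) lexicographic | min |

Defaults wk1 = 6, wk2 = 4. Two of these needed genuine decisions. The
critical ratio's numerator is anchored to a nominal due date of arrival
plus the pattern's total average processing time, which makes the ratio
1 at arrival and negative exactly when the patient is past the due date
(the stated reading of a negative value). The AS orientation is
ambiguous as a formula: selecting the *minimum* of
(wk1 + wk2·wa) × remaining time would systematically prefer acuity-5
patients (smallest factor) and starve the urgent levels, inverting the
rule's purpose as an acuity-aware heuristic and contradicting its
observed placement well below FCFS on the penalty index; the default is
therefore the maximum, with the mirrored variant available behind
`as_orientation="min"`.

## Metrics

"Over the threshold" is read as length of stay (discharge − arrival)
exceeding 60/180 minutes plus the pattern's **total average** processing
time: since the threshold explicitly adds processing time, the compared
quantity must include processing, i.e. the LOS. The penalty percentage
is undefined (NaN) when no acuity-1/2 patient was discharged. Scenario
summaries average per-instance means with equal instance weights;
patient-pooled aggregation is available behind `pool_patients`.

## Problem sizes and numerical choices

The experiment harness uses 50 instances × 14 days per scenario ×
scheduler, which stabilises the per-scenario penalty mean to well under
one percentage point at the saturated end and ~±0.5 points elsewhere.
The test suite exercises the same design with 50 instances for the
headline rule comparisons, 4–6 instances for cross-scenario ordering
checks, and a 25-episode reduced training budget for the DQN fixture —
the package's own trade-off between statistical resolution and a test
suite that runs in minutes; as discussed above, longer training at the
default learning rate does not change what is being asserted. Sampling
tolerances in tests are 3-sigma bands around exact expectations
(multinomial acuity frequencies, the Poisson arrival-count identity, the
truncated-normal moments against the closed-form oracle). All times are
minutes; seeds are plain integers; every stochastic path accepts an
explicit generator.

## Known limitations

* Pattern frequencies are a modelling unknown (above); absolute penalty
  levels in moderately loaded scenarios should not be read as estimates
  for any real ED.
* The lab-as-infinite-capacity reading removes one genuine contention
  point; if lab draws do tie up nurses in a target ED, the nurse group
  becomes the bottleneck and all absolute results shift.
* Patients in the system at the horizon are excluded rather than
  imputed, slightly flattering schedulers that strand long stays near
  the end of an instance (counts are reported so the effect is visible).
* At the default learning rate the DQN's gradient updates are
  vanishingly small (discussed above); the agent is best understood as a
  structured scoring policy with verified learning machinery rather than
  a converged optimum.
* Single-agent, single-department scope: no beds, boarding, ambulance
  diversion, staff rostering, or interacting departments.
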