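# edsched

Patient scheduling for a simulated emergency department (ED): a
discrete-event simulator, six priority dispatching rules, and a deep
Q-network (DQN) scheduler, with an experiment harness that compares them
on acuity-weighted waiting time and the share of urgent patients whose
stay exceeds a clinical threshold.

## The problem

An ED receives unscheduled Poisson arrivals. Each patient *i* is triaged
to an acuity level *au* ∈ {1,…,5} (1 = most urgent) and follows one of
eleven treatment patterns — ordered sequences over nine treatments
(triage, registration, evaluation, laboratory, X-ray, consultation, CT
scan, discharge, admission) obtained by process mining real ED visit
logs. Treatments are performed by four pooled resource groups (3 doctors,
5 nurses, 1 X-ray technician, 1 CT technician); the laboratory is an
unlimited-capacity station. Durations are stochastic (exponential,
truncated normal, or constant, in minutes).

Whenever a unit of group *g* is idle and patients are waiting for that
group, a scheduler must pick one patient from the waiting list ℘*gt*.
The objective is the acuity-weighted waiting time

  c·W(i) = c_au · Σ_j wt_ij,

with weights c = (30, 15, 1, 1, 1) per acuity level, so one waited minute
of a level-1 patient counts thirty-fold. A second index is the
**penalty-patient percentage**: among discharged acuity-1/2 patients, the
share whose length of stay exceeded 60 min (level 1) or 180 min (level 2)
plus the total average processing time of their pattern.

## Schedulers

Six dispatching rules — FCFS, SRPT (shortest remaining average processing
time), critical ratio, and three acuity-aware combinations (AS, AW, AA) —
plus a DQN agent. The DQN views the decision as an MDP: the state is the
per-group waiting-list composition (acuity and treatment-type ratios, 29
entries), an action is the choice of one waiting patient, and the reward
is −c_au × the waiting time the selected patient has accumulated. One
shared network (hidden layers 64/32/2, leaky ReLU, linear scalar head)
scores each candidate from the state concatenated with the candidate's
features, which accommodates action sets of any size. Training uses
epsilon-greedy exploration, a 2000-transition FIFO replay memory, a
target network synced per episode, and one Adam minibatch step per
simulated hour.

## Worked example

```python
from edsched import ScenarioConfig, run_scenario

cfg = ScenarioConfig(n_instances=5, master_seed=42)
for rule in ("fcfs", "aw"):
    table = run_scenario(cfg, scenario=1, scheduler_name=rule)
    print(f"{rule:4s}  penalty {table.penalty_pct.mean():5.2f}%   "
          f"weighted wait {table.mean_weighted_wait.mean():6.1f} min   "
          f"discharged {table.n_discharged.mean():.0f}")
```

prints

```
fcfs  penalty 15.33%   weighted wait  536.6 min   discharged 2167
aw    penalty  1.48%   weighted wait  199.2 min   discharged 2168
```

Five 14-day instances at 7 arrivals/hour (scenario 1), one-day warm-up:
under FCFS about one in seven urgent patients overstays the threshold and
the mean acuity-weighted wait is ~537 weighted minutes; the acuity-aware
AW rule cuts the penalty share to ~1.5% and the weighted wait by more
than half, while discharging the same number of patients (both rules see
identical arrival and duration streams — common random numbers).

Training and evaluating the DQN scheduler:

```python
from edsched import train
result = train(episodes=25, seed=7)          # reduced budget; default is 1000
result.scheduler.save("dqn_weights.npz")
```

A CLI wraps the same functionality: `edsched train`, `edsched run
--scenario 1 --scheduler aw --instances 50 --seed 0`, `edsched report`.

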