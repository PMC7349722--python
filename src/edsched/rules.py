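"""The six baseline dispatching rules.

Each rule is a deterministic function from (waiting list, clock) to one
selected patient. All ties, everywhere, break toward the lowest patient
id (= earliest creation), which keeps every rule total and reproducible.

Rules and their priority quantities, with wa_i the weighted acuity
(5 for level 1 ... 1 for level 5), c_i the waiting-time weight, ar_i the
arrival time and apt_ij the average processing times:

========  =============================================================
FCFS      earliest arrival time ar_i
SRPT      smallest remaining average processing time sum
CR        smallest critical ratio (ar_i + total apt - t) / remaining apt;
          negative values mean the patient is already past its nominal
          due date (delayed)
AS        (wk1 + wk2*wa_i) * remaining apt; by default the largest score
          wins, so high acuity and long remaining work raise priority
AW        (wk1 + wk2*wa_i) * c_i * net elapsed wait; largest score wins
AA        lexicographic: most urgent acuity level first, then earliest
          arrival
========  =============================================================

Default weights wk1 = 6, wk2 = 4.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain import Patient
from .simulator import Scheduler

__all__ = [
    "RuleConfig",
    "RuleScheduler",
    "fcfs",
    "srpt",
    "critical_ratio",
    "acuity_srpt",
    "acuity_wait",
    "acuity_arrival",
    "RULES",
    "make_scheduler",
]


@dataclass
class RuleConfig:
    """Weights for the linear-combination rules AS and AW."""

    wk1: float = 6.0
    wk2: float = 4.0
    #: orientation of the AS score; "max" follows the observed behaviour of
    #: the rule (high acuity prioritised), "min" is the mirrored variant
    as_orientation: str = "max"


def _empty_guard(candidates):
    if not candidates:
        raise ValueError("cannot select from an empty waiting list")


def fcfs(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """First come, first served: earliest ED arrival time wins."""
    _empty_guard(candidates)
    return min(candidates, key=lambda p: (p.arrival_time, p.id))


def srpt(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """Shortest remaining average processing time (from the current step)."""
    _empty_guard(candidates)
    return min(candidates, key=lambda p: (p.remaining_avg_time(), p.id))


def critical_ratio(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """Smallest critical ratio: slack to the nominal due date over remaining work.

    The due date is anchored at arrival plus the pattern's total average
    processing time; a negative ratio marks a delayed patient.
    """
    _empty_guard(candidates)

    def cr(p: Patient) -> float:
        return (p.arrival_time + p.total_apt - t) / p.remaining_avg_time()

    return min(candidates, key=lambda p: (cr(p), p.id))


def acuity_srpt(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """AS: acuity-weighted remaining-time score (wk1 + wk2*wa_i) * remaining apt."""
    _empty_guard(candidates)
    cfg = config or RuleConfig()

    def score(p: Patient) -> float:
        return (cfg.wk1 + cfg.wk2 * p.acuity.weighted_acuity) * p.remaining_avg_time()

    sign = 1.0 if cfg.as_orientation == "min" else -1.0
    return min(candidates, key=lambda p: (sign * score(p), p.id))


def acuity_wait(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """AW: acuity-weighted waiting score, largest wins.

    Score = (wk1 + wk2*wa_i) * c_i * (t - ar_i - completed processing),
    the net elapsed waiting time weighted twice by urgency.
    """
    _empty_guard(candidates)
    cfg = config or RuleConfig()

    def score(p: Patient) -> float:
        net_wait = t - p.arrival_time - p.completed_processing()
        return (cfg.wk1 + cfg.wk2 * p.acuity.weighted_acuity) * p.acuity.waiting_weight * net_wait

    return min(candidates, key=lambda p: (-score(p), p.id))


def acuity_arrival(candidates: list[Patient], t: float, config: RuleConfig | None = None) -> Patient:
    """AA: most urgent acuity level first, earliest arrival second."""
    _empty_guard(candidates)
    return min(candidates, key=lambda p: (p.acuity.level, p.arrival_time, p.id))


RULES = {
    "fcfs": fcfs,
    "srpt": srpt,
    "cr": critical_ratio,
    "as": acuity_srpt,
    "aw": acuity_wait,
    "aa": acuity_arrival,
}


class RuleScheduler(Scheduler):
    """Adapter presenting a dispatching rule as a simulator scheduler."""

    def __init__(self, rule_name: str, config: RuleConfig | None = None):
        if rule_name not in RULES:
            raise KeyError(f"unknown rule {rule_name!r}; known: {sorted(RULES)}")
        self.rule_name = rule_name
        self.rule = RULES[rule_name]
        self.config = config or RuleConfig()

    def select_patient(self, group, candidates, t, sim):
        return self.rule(candidates, t, self.config)


def make_scheduler(name: str, config: RuleConfig | None = None, **dqn_kwargs) -> Scheduler:
    """Registry lookup: fcfs | srpt | cr | as | aw | aa | dqn."""
    if name == "dqn":
        from .dqn import DQNScheduler

        return DQNScheduler(**dqn_kwargs)
    return RuleScheduler(name, config)
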