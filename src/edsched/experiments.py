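"""Scenario runner: arrival-rate scenarios x schedulers x seeded instances.

The four standard scenarios raise the Poisson arrival rate from 7 to 10
patients per hour against fixed resource capacities {doctor: 3, nurse: 5,
x-ray: 1, CT: 1}. Each scenario is evaluated on independent instances of
14 simulated days with a one-day warm-up, and every scheduler sees the
*same* instances: arrival times, acuities, patterns and actual durations
are drawn per (instance, patient, step) before scheduling starts, so
comparisons use common random numbers (a flag disables this and gives
each scheduler its own streams).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .domain import DomainTables, generate_patients, load_tables
from .metrics import instance_report
from .rules import RuleConfig, make_scheduler
from .simulator import EDSimulator, Scheduler, SimulationResult

__all__ = [
    "SCENARIO_RATES",
    "ScenarioConfig",
    "instance_rng",
    "run_instance",
    "run_scenario",
    "run_scenarios",
    "summarize",
]

#: scenario id -> Poisson arrival rate (patients per hour)
SCENARIO_RATES = {1: 7.0, 2: 8.0, 3: 9.0, 4: 10.0}

MINUTES_PER_DAY = 1440.0


@dataclass
class ScenarioConfig:
    """Full description of an experiment; serialisable to YAML/JSON."""

    arrival_rate: float = 7.0
    resources: dict = field(
        default_factory=lambda: {"doctor": 3, "nurse": 5, "xray": 1, "ct": 1}
    )
    n_instances: int = 50
    days: float = 14.0
    warmup_days: float = 1.0
    scheduler: str = "fcfs"
    master_seed: int = 0
    #: common random numbers: identical instances across schedulers
    crn: bool = True
    wk1: float = 6.0
    wk2: float = 4.0
    as_orientation: str = "max"
    pattern_weights: list | None = None
    deterministic_durations: bool = False
    #: pool patients across instances instead of averaging per-instance means
    pool_patients: bool = False
    dqn_checkpoint: str | None = None

    @property
    def horizon_minutes(self) -> float:
        return self.days * MINUTES_PER_DAY

    @property
    def warmup_minutes(self) -> float:
        return self.warmup_days * MINUTES_PER_DAY

    def rule_config(self) -> RuleConfig:
        return RuleConfig(wk1=self.wk1, wk2=self.wk2, as_orientation=self.as_orientation)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**raw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def instance_rng(master_seed: int, scenario: int, instance: int, stream: str = "") -> np.random.Generator:
    """Reproducible generator for one (scenario, instance) pair.

    Under common random numbers the stream name is empty, so every
    scheduler draws the identical instance.
    """
    entropy = [int(master_seed), int(scenario), int(instance)]
    if stream:
        entropy.append(abs(hash(stream)) % 2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _resolve_scheduler(config: ScenarioConfig, name: str, tables: DomainTables) -> Scheduler:
    if name == "dqn":
        from .dqn import DQNScheduler

        if config.dqn_checkpoint is None:
            raise FileNotFoundError(
                "scheduler 'dqn' needs a trained checkpoint (dqn_checkpoint)"
            )
        return DQNScheduler.from_checkpoint(config.dqn_checkpoint, tables=tables)
    return make_scheduler(name, config.rule_config())


def run_instance(
    config: ScenarioConfig,
    scenario: int,
    instance: int,
    scheduler: Scheduler | None = None,
    tables: DomainTables | None = None,
    keep_events: bool = False,
) -> SimulationResult:
    """Simulate one seeded instance of a scenario under one scheduler."""
    tables = tables or load_tables()
    sched = scheduler or _resolve_scheduler(config, config.scheduler, tables)
    name = config.scheduler if scheduler is None else getattr(scheduler, "rule_name", "custom")
    rng = instance_rng(config.master_seed, scenario, instance, stream="" if config.crn else name)
    rate = SCENARIO_RATES.get(scenario, config.arrival_rate)
    patients = generate_patients(
        rng,
        rate,
        config.horizon_minutes,
        tables=tables,
        pattern_weights=config.pattern_weights,
        deterministic_durations=config.deterministic_durations,
    )
    sim = EDSimulator(
        patients,
        sched,
        horizon=config.horizon_minutes,
        tables=tables,
        capacities=config.resources,
        keep_events=keep_events,
    )
    return sim.run()


def run_scenario(
    config: ScenarioConfig,
    scenario: int,
    scheduler_name: str | None = None,
    scheduler: Scheduler | None = None,
    tables: DomainTables | None = None,
) -> pd.DataFrame:
    """All instances of one scenario under one scheduler; one row per instance."""
    tables = tables or load_tables()
    name = scheduler_name or config.scheduler
    rows = []
    for k in range(config.n_instances):
        sched = scheduler or _resolve_scheduler(config, name, tables)
        cfg = dataclasses.replace(config, scheduler=name)
        result = run_instance(cfg, scenario, k, scheduler=sched, tables=tables)
        rep = instance_report(result, warmup_minutes=config.warmup_minutes)
        rep.update({"scenario": scenario, "scheduler": name, "instance": k})
        rows.append(rep)
    return pd.DataFrame(rows)


def summarize(per_instance: pd.DataFrame, pool_patients: bool = False) -> pd.DataFrame:
    """Scenario x scheduler summary: mean over instances of each metric.

    By default the penalty percentage is the unweighted mean of
    per-instance percentages; with ``pool_patients`` patients are pooled
    across instances before the ratio is taken.
    """
    group = per_instance.groupby(["scenario", "scheduler"], sort=True)
    summary = group[
        ["mean_weighted_wait", "penalty_pct", "n_discharged", "n_censored"]
        + [f"discharged_acuity{a}" for a in range(1, 6)]
        + [f"mean_wait_acuity{a}" for a in range(1, 6)]
    ].mean()
    if pool_patients:
        urgent = per_instance["discharged_acuity1"] + per_instance["discharged_acuity2"]
        pooled = (
            (per_instance["penalty_pct"] * urgent).groupby(
                [per_instance["scenario"], per_instance["scheduler"]]
            ).sum()
            / urgent.groupby([per_instance["scenario"], per_instance["scheduler"]]).sum()
        )
        summary["penalty_pct"] = pooled
    return summary.reset_index()


def run_scenarios(
    config: ScenarioConfig,
    scenarios: tuple[int, ...] = (1, 2, 3, 4),
    schedulers: tuple[str, ...] = ("fcfs", "srpt", "cr", "as", "aw", "aa"),
    tables: DomainTables | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the scenario grid; returns (per-instance table, summary table)."""
    tables = tables or load_tables()
    frames = [
        run_scenario(config, sc, scheduler_name=name, tables=tables)
        for sc in scenarios
        for name in schedulers
    ]
    per_instance = pd.concat(frames, ignore_index=True)
    return per_instance, summarize(per_instance, pool_patients=config.pool_patients)
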