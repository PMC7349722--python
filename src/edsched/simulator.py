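"""Discrete-event engine for the emergency department.

The engine advances a continuous-time clock through arrival, service-end
and (optional) training-tick events kept in a priority heap. Whenever an
idle resource unit and a non-empty waiting list coexist for some group,
the pluggable scheduler is asked repeatedly to pick one waiting patient
until either the idle set or the waiting list empties.

Determinism: events at equal times are ordered service_end < arrival <
train_tick, and within a kind by ascending patient id; groups are always
dispatched in the fixed order doctor, nurse, xray, ct. Together with
pre-drawn patient attributes this makes runs bit-identical under a fixed
seed, for every scheduler.

Treatments flagged ``capacity_exempt`` (the laboratory) start the moment
the patient reaches them: they belong to a station whose capacity is
unlimited, so they never queue and never occupy a resource unit.
"""

from __future__ import annotations

import heapq
import json
from typing import Iterable

import pandas as pd

from .domain import GROUP_ORDER, DomainTables, Patient, generate_patients, load_tables

__all__ = [
    "Scheduler",
    "SchedulingError",
    "SimulationResult",
    "EDSimulator",
    "run_episode",
    "write_event_log",
    "patients_to_dataframe",
]

# event-kind priorities for same-time ordering
_SERVICE_END, _ARRIVAL, _TRAIN_TICK = 0, 1, 2


class SchedulingError(RuntimeError):
    """Raised when a scheduler violates its contract (returns a non-candidate)."""


class Scheduler:
    """Base class for scheduling policies.

    Subclasses implement :meth:`select_patient`. The engine calls the
    remaining hooks at well-defined points; the defaults do nothing.
    """

    #: set True to receive :meth:`on_train_tick` every 60 simulated minutes
    requires_train_ticks: bool = False

    def begin_episode(self, sim: "EDSimulator") -> None:  # pragma: no cover - hook
        pass

    def select_patient(self, group: str, candidates: list[Patient], t: float, sim: "EDSimulator") -> Patient:
        raise NotImplementedError

    def on_train_tick(self, t: float, sim: "EDSimulator") -> None:  # pragma: no cover - hook
        pass

    def end_episode(self, sim: "EDSimulator") -> None:  # pragma: no cover - hook
        pass


class SimulationResult:
    """Outcome of one simulated episode.

    Attributes
    ----------
    patients : list[Patient]
        Every generated patient, with per-step start/end/wait stamps filled
        in as far as the episode progressed.
    events : list[tuple]
        Chronological event log of ``(kind, time, patient_id, group)``
        tuples, kinds ``arrival | service_start | service_end | discharge``.
    horizon : float
        Episode length in minutes.
    """

    def __init__(self, patients: list[Patient], events: list[tuple], horizon: float):
        self.patients = patients
        self.events = events
        self.horizon = horizon

    def discharged(self, arrived_after: float = 0.0) -> list[Patient]:
        """Discharged patients whose arrival time is >= ``arrived_after``."""
        return [
            p
            for p in self.patients
            if p.status == "discharged" and p.arrival_time >= arrived_after
        ]

    def censored(self, arrived_after: float = 0.0) -> list[Patient]:
        """Patients still in the system at the horizon (excluded from metrics)."""
        return [
            p
            for p in self.patients
            if p.status != "discharged" and p.arrival_time >= arrived_after
        ]


class EDSimulator:
    """Event-driven ED with four pooled resource groups and one scheduler."""

    def __init__(
        self,
        patients: list[Patient],
        scheduler: Scheduler,
        horizon: float,
        tables: DomainTables | None = None,
        capacities: dict[str, int] | None = None,
        train_tick_interval: float = 60.0,
        keep_events: bool = True,
    ):
        self.tables = tables or load_tables()
        self.patients = patients
        self.scheduler = scheduler
        self.horizon = float(horizon)
        caps = capacities or self.tables.capacities
        self.capacity = {g: int(caps[g]) for g in GROUP_ORDER}
        self.idle = dict(self.capacity)
        self.waiting: dict[str, list[Patient]] = {g: [] for g in GROUP_ORDER}
        self.train_tick_interval = train_tick_interval
        self.keep_events = keep_events
        self.events: list[tuple] = []
        self.now = 0.0
        self._heap: list[tuple] = []

    # -- event plumbing -----------------------------------------------------
    def _push(self, time: float, prio: int, tiebreak: int, payload) -> None:
        heapq.heappush(self._heap, (time, prio, tiebreak, payload))

    def _log(self, kind: str, t: float, patient: Patient | None, group: str | None) -> None:
        if self.keep_events:
            self.events.append((kind, t, None if patient is None else patient.id, group))

    # -- core transitions ---------------------------------------------------
    def _enter_step(self, p: Patient, t: float) -> None:
        """Route a patient to its current treatment (queue, lab, or discharge)."""
        if p.step >= p.n_steps:
            p.status = "discharged"
            self._log("discharge", t, p, None)
            return
        spec = self.tables.treatments[p.current_code]
        p.ready_time = t
        if spec.capacity_exempt:
            # unlimited-capacity station: starts immediately, no unit consumed
            self._start_service(p, spec.resource_group, t, occupy=False)
        else:
            p.status = "waiting"
            self.waiting[spec.resource_group].append(p)

    def _start_service(self, p: Patient, group: str, t: float, occupy: bool = True) -> None:
        j = p.step
        p.waits[j] = t - p.ready_time
        p.starts[j] = t
        p.status = "in_service"
        if occupy:
            self.idle[group] -= 1
        self._log("service_start", t, p, group)
        end = t + p.durations[j]
        self._push(end, _SERVICE_END, p.id, (p, group, occupy))

    def _dispatch(self, t: float) -> None:
        """Assign idle units to waiting patients, group by group."""
        for g in GROUP_ORDER:
            queue = self.waiting[g]
            while self.idle[g] > 0 and queue:
                p = self.scheduler.select_patient(g, queue, t, self)
                if p.status != "waiting" or self.tables.treatments[p.current_code].resource_group != g:
                    raise SchedulingError(
                        f"scheduler returned patient {p!r} not waiting in group {g}"
                    )
                queue.remove(p)
                self._start_service(p, g, t)

    # -- main loop ----------------------------------------------------------
    def run(self) -> SimulationResult:
        self.scheduler.begin_episode(self)
        for p in self.patients:
            self._push(p.arrival_time, _ARRIVAL, p.id, p)
        if self.scheduler.requires_train_ticks and self.train_tick_interval:
            t = self.train_tick_interval
            while t <= self.horizon:
                self._push(t, _TRAIN_TICK, 0, None)
                t += self.train_tick_interval
        heap = self._heap
        while heap:
            time, prio, _, payload = heapq.heappop(heap)
            if time > self.horizon:
                break
            self.now = time
            if prio == _SERVICE_END:
                p, group, occupied = payload
                p.ends[p.step] = time
                if occupied:
                    self.idle[group] += 1
                self._log("service_end", time, p, group)
                p.step += 1
                self._enter_step(p, time)
            elif prio == _ARRIVAL:
                self._log("arrival", time, payload, None)
                self._enter_step(payload, time)
            else:  # train tick
                self.scheduler.on_train_tick(time, self)
                continue
            self._dispatch(time)
        self.scheduler.end_episode(self)
        return SimulationResult(self.patients, self.events, self.horizon)


def run_episode(
    scheduler: Scheduler,
    rng,
    rate_per_hour: float,
    horizon_minutes: float,
    tables: DomainTables | None = None,
    capacities: dict[str, int] | None = None,
    pattern_weights=None,
    deterministic_durations: bool = False,
    keep_events: bool = True,
) -> SimulationResult:
    """Generate one arrival stream and simulate it under ``scheduler``."""
    tables = tables or load_tables()
    patients = generate_patients(
        rng,
        rate_per_hour,
        horizon_minutes,
        tables=tables,
        pattern_weights=pattern_weights,
        deterministic_durations=deterministic_durations,
    )
    sim = EDSimulator(
        patients,
        scheduler,
        horizon=horizon_minutes,
        tables=tables,
        capacities=capacities,
        keep_events=keep_events,
    )
    return sim.run()


def write_event_log(result: SimulationResult, path) -> None:
    """Write the event log as JSON lines (one event per line)."""
    with open(path, "w") as fh:
        for kind, t, pid, group in result.events:
            fh.write(json.dumps({"t": t, "kind": kind, "patient": pid, "group": group}) + "\n")


def patients_to_dataframe(patients: Iterable[Patient]) -> pd.DataFrame:
    """Per-patient table: arrival, acuity, pattern, per-step waits, discharge."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient": p.id,
                "arrival": p.arrival_time,
                "acuity": p.acuity.level,
                "pattern": p.pattern.pattern_id,
                "status": p.status,
                "waits": ";".join(f"{w:.3f}" for w in p.waits[: p.step]),
                "total_wait": p.total_wait(),
                "discharge": p.discharge_time,
            }
        )
    return pd.DataFrame(rows)
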