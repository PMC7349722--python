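"""Static emergency-department domain model.

This module holds the clinical "facts" of the simulated ED: the nine
treatments with their stochastic duration distributions and performing
resource groups, the eleven treatment patterns (ordered treatment
sequences obtained from process mining of real ED visit logs), the
five-level triage acuity table with its waiting-time weights, priority
scores and occurrence frequencies, and the stochastic patient generator.

Time is measured in minutes throughout. Durations are strictly positive;
normally distributed durations are truncated below at a small floor by
resampling. Exponential entries are parameterised by their *mean* in
minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "CODES",
    "GROUP_ORDER",
    "DURATION_FLOOR",
    "TreatmentSpec",
    "TreatmentPattern",
    "AcuityLevel",
    "DomainTables",
    "Patient",
    "load_tables",
    "sample_duration",
    "sample_arrivals",
    "sample_patient",
    "generate_patients",
    "remaining_avg_time",
]

#: All treatment codes, in canonical order (also the one-hot layout).
CODES = "ABCDEFGHI"

#: Fixed resource-group ordering used for state vectors and dispatch passes.
GROUP_ORDER = ("doctor", "nurse", "xray", "ct")

#: Lower truncation floor (minutes) for normally distributed durations.
DURATION_FLOOR = 0.1


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment: its duration distribution and performing resource group.

    ``capacity_exempt`` marks treatments performed at a station whose
    capacity is unlimited (the laboratory): such treatments start
    immediately and never occupy a resource unit, although the treatment
    remains administratively attached to its resource group.
    """

    code: str
    description: str
    dist: dict
    resource_group: str
    capacity_exempt: bool = False

    @property
    def mean(self) -> float:
        """Average processing time in minutes (the ``apt`` of this treatment)."""
        d = self.dist
        if d["kind"] == "constant":
            return float(d["value"])
        return float(d["mean"])

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one strictly positive duration in minutes."""
        d = self.dist
        kind = d["kind"]
        if kind == "exponential":
            return float(rng.exponential(d["mean"]))
        if kind == "normal":
            x = rng.normal(d["mean"], d["sd"])
            while x < DURATION_FLOOR:
                x = rng.normal(d["mean"], d["sd"])
            return float(x)
        if kind == "constant":
            return float(d["value"])
        raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class TreatmentPattern:
    """An ordered treatment sequence a patient follows from triage to discharge."""

    pattern_id: int
    sequence: tuple[str, ...]


@dataclass(frozen=True)
class AcuityLevel:
    """A triage acuity grade (1 = most urgent) and its scheduling attributes."""

    level: int
    waiting_weight: float  # c_i: weighted minutes credited per waited minute
    weighted_acuity: int  # wa_i: priority score (5 for level 1 ... 1 for level 5)
    occurrence_ratio: float


class DomainTables:
    """Immutable bundle of the treatment, pattern, acuity and capacity tables."""

    def __init__(
        self,
        treatments: dict[str, TreatmentSpec],
        patterns: tuple[TreatmentPattern, ...],
        acuity: dict[int, AcuityLevel],
        capacities: dict[str, int],
    ):
        self.treatments = treatments
        self.patterns = patterns
        self.acuity = acuity
        self.capacities = dict(capacities)
        # codes each group performs, in canonical A..I order
        self.group_treatments: dict[str, tuple[str, ...]] = {
            g: tuple(c for c in CODES if treatments[c].resource_group == g)
            for g in GROUP_ORDER
        }
        self.acuity_levels = tuple(sorted(acuity))
        self.occurrence_ratios = np.array(
            [acuity[a].occurrence_ratio for a in self.acuity_levels]
        )
        if not np.isclose(self.occurrence_ratios.sum(), 1.0):
            raise ValueError("acuity occurrence ratios must sum to 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "DomainTables":
        treatments = {
            code: TreatmentSpec(
                code=code,
                description=spec["description"],
                dist=spec["dist"],
                resource_group=spec["resource_group"],
                capacity_exempt=spec.get("capacity_exempt", False),
            )
            for code, spec in raw["treatments"].items()
        }
        patterns = tuple(
            TreatmentPattern(int(pid), tuple(seq))
            for pid, seq in sorted(raw["patterns"].items(), key=lambda kv: int(kv[0]))
        )
        acuity = {
            int(level): AcuityLevel(
                level=int(level),
                waiting_weight=float(spec["waiting_weight"]),
                weighted_acuity=int(spec["weighted_acuity"]),
                occurrence_ratio=float(spec["occurrence_ratio"]),
            )
            for level, spec in raw["acuity"].items()
        }
        capacities = {g: int(v["capacity"]) for g, v in raw["resource_groups"].items()}
        return cls(treatments, patterns, acuity, capacities)

    def to_dict(self) -> dict:
        return {
            "treatments": {
                c: {
                    "description": t.description,
                    "dist": t.dist,
                    "resource_group": t.resource_group,
                    **({"capacity_exempt": True} if t.capacity_exempt else {}),
                }
                for c, t in self.treatments.items()
            },
            "patterns": {str(p.pattern_id): list(p.sequence) for p in self.patterns},
            "acuity": {
                str(a.level): {
                    "waiting_weight": a.waiting_weight,
                    "weighted_acuity": a.weighted_acuity,
                    "occurrence_ratio": a.occurrence_ratio,
                }
                for a in self.acuity.values()
            },
            "resource_groups": {g: {"capacity": c} for g, c in self.capacities.items()},
        }

    def pattern_means(self, pattern: TreatmentPattern) -> tuple[float, ...]:
        return tuple(self.treatments[c].mean for c in pattern.sequence)


@lru_cache(maxsize=1)
def load_tables() -> DomainTables:
    """Load the default domain tables shipped with the package."""
    raw = json.loads(
        resources.files("edsched.data").joinpath("ed_tables.json").read_text()
    )
    return DomainTables.from_dict(raw)


def sample_duration(
    rng: np.random.Generator, code: str, tables: DomainTables | None = None
) -> float:
    """Draw one actual processing time (minutes) for a treatment code."""
    tables = tables or load_tables()
    if code not in tables.treatments:
        raise KeyError(f"unknown treatment code {code!r}")
    return tables.treatments[code].sample(rng)


def sample_arrivals(
    rng: np.random.Generator, rate_per_hour: float, horizon_minutes: float
) -> np.ndarray:
    """Poisson arrival times on ``[0, horizon)`` at ``rate_per_hour``.

    Inter-arrival gaps are i.i.d. exponential with mean ``60 / rate`` minutes.
    """
    if rate_per_hour <= 0:
        raise ValueError("arrival rate must be positive")
    if horizon_minutes <= 0:
        return np.empty(0)
    scale = 60.0 / rate_per_hour
    expected = horizon_minutes / scale
    times: list[np.ndarray] = []
    t = 0.0
    while t < horizon_minutes:
        chunk = rng.exponential(scale, size=max(16, int(expected * 1.2) + 4)).cumsum() + t
        times.append(chunk)
        t = chunk[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < horizon_minutes]


class Patient:
    """One ED visit: acuity, treatment pattern, and per-step progress.

    Actual durations are drawn per (patient, step) when the patient is
    created, so that identical seeds yield identical duration streams no
    matter how scheduling interleaves service events; they are exposed to
    the event log only once the corresponding treatment has finished, and
    no scheduler reads them beforehand.
    """

    __slots__ = (
        "id",
        "arrival_time",
        "acuity",
        "pattern",
        "codes",
        "n_steps",
        "apts",
        "total_apt",
        "durations",
        "step",
        "starts",
        "ends",
        "waits",
        "status",
        "ready_time",
    )

    def __init__(
        self,
        pid: int,
        arrival_time: float,
        acuity: AcuityLevel,
        pattern: TreatmentPattern,
        durations: np.ndarray,
        apts: tuple[float, ...],
    ):
        self.id = pid
        self.arrival_time = arrival_time
        self.acuity = acuity
        self.pattern = pattern
        self.codes = pattern.sequence
        self.n_steps = len(pattern.sequence)
        self.apts = apts
        self.total_apt = float(sum(apts))
        self.durations = durations
        self.step = 0  # 0-based index of the current treatment
        self.starts = [None] * self.n_steps
        self.ends = [None] * self.n_steps
        self.waits = [0.0] * self.n_steps
        self.status = "waiting"
        self.ready_time = arrival_time

    # -- progress -----------------------------------------------------------
    @property
    def current_code(self) -> str:
        return self.codes[self.step]

    @property
    def current_apt(self) -> float:
        return self.apts[self.step]

    @property
    def discharge_time(self) -> float | None:
        return self.ends[-1] if self.status == "discharged" else None

    def remaining_avg_time(self, from_step: int | None = None) -> float:
        """Sum of average processing times from ``from_step`` (1-based) onward.

        Defaults to the current treatment.
        """
        idx = self.step if from_step is None else from_step - 1
        if not 0 <= idx < self.n_steps:
            raise IndexError(f"step {from_step} out of range 1..{self.n_steps}")
        return float(sum(self.apts[idx:]))

    def accumulated_wait(self, t: float) -> float:
        """Total waiting accrued up to time ``t`` (unweighted minutes).

        While the patient is waiting this includes the still-open wait for
        the current treatment; otherwise it is the sum of closed waits.
        """
        total = sum(self.waits[: self.step])
        if self.status == "waiting":
            total += max(0.0, t - self.ready_time)
        return float(total)

    def total_wait(self) -> float:
        return float(sum(self.waits))

    def completed_processing(self) -> float:
        return float(sum(d for d, e in zip(self.durations, self.ends) if e is not None))


def sample_patient(
    rng: np.random.Generator,
    arrival_time: float,
    pid: int = 0,
    tables: DomainTables | None = None,
    pattern_weights: np.ndarray | None = None,
    deterministic_durations: bool = False,
) -> Patient:
    """Draw one patient: acuity from the occurrence ratios, pattern, durations.

    ``pattern_weights`` overrides the default uniform distribution over the
    eleven patterns. With ``deterministic_durations`` every actual duration
    equals its tabulated mean (useful for worked examples and debugging).
    """
    if arrival_time < 0:
        raise ValueError("arrival_time must be non-negative")
    tables = tables or load_tables()
    level = int(rng.choice(tables.acuity_levels, p=tables.occurrence_ratios))
    n_pat = len(tables.patterns)
    if pattern_weights is None:
        pattern = tables.patterns[int(rng.integers(n_pat))]
    else:
        w = np.asarray(pattern_weights, dtype=float)
        pattern = tables.patterns[int(rng.choice(n_pat, p=w / w.sum()))]
    apts = tables.pattern_means(pattern)
    if deterministic_durations:
        durations = np.array(apts)
    else:
        durations = np.array(
            [tables.treatments[c].sample(rng) for c in pattern.sequence]
        )
    return Patient(pid, float(arrival_time), tables.acuity[level], pattern, durations, apts)


def generate_patients(
    rng: np.random.Generator,
    rate_per_hour: float,
    horizon_minutes: float,
    tables: DomainTables | None = None,
    pattern_weights: np.ndarray | None = None,
    deterministic_durations: bool = False,
) -> list[Patient]:
    """Generate the full arrival stream for one simulation instance.

    All stochastic patient attributes (arrival times, acuities, patterns,
    actual durations) are drawn here, before any scheduling happens, so a
    given seed defines one instance that every scheduler sees identically
    (common random numbers).
    """
    tables = tables or load_tables()
    arrivals = sample_arrivals(rng, rate_per_hour, horizon_minutes)
    return [
        sample_patient(
            rng,
            t,
            pid=i,
            tables=tables,
            pattern_weights=pattern_weights,
            deterministic_durations=deterministic_durations,
        )
        for i, t in enumerate(arrivals)
    ]


def remaining_avg_time(patient: Patient, from_step: int) -> float:
    """Module-level convenience wrapper; ``from_step`` is 1-based."""
    return patient.remaining_avg_time(from_step)
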