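"""Shared test helpers: hand-built patients and event-log oracles."""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from edsched.domain import Patient


def make_patient(tables, pid=0, arrival=0.0, acuity=3, pattern_id=1, durations=None):
    """Build a patient with mean (or given) durations, no sampling involved."""
    pattern = tables.patterns[pattern_id - 1]
    assert pattern.pattern_id == pattern_id
    apts = tables.pattern_means(pattern)
    if durations is None:
        durations = np.array(apts)
    return Patient(pid, float(arrival), tables.acuity[acuity], pattern, np.asarray(durations, float), apts)


def advance(patient, n_done, waits=()):
    """Mark the first ``n_done`` treatments finished with the given waits."""
    t = patient.arrival_time
    for j in range(n_done):
        w = waits[j] if j < len(waits) else 0.0
        patient.waits[j] = w
        patient.starts[j] = t + w
        t = patient.starts[j] + patient.durations[j]
        patient.ends[j] = t
    patient.step = n_done
    patient.ready_time = t
    patient.status = "waiting" if n_done < patient.n_steps else "discharged"
    return patient


def busy_intervals(patients, tables):
    """Per-group service intervals, excluding unlimited-capacity (lab) steps."""
    per_group = defaultdict(list)
    for p in patients:
        for j, code in enumerate(p.codes):
            if p.starts[j] is None:
                continue
            spec = tables.treatments[code]
            if spec.capacity_exempt:
                continue
            end = p.ends[j] if p.ends[j] is not None else math.inf
            per_group[spec.resource_group].append((p.starts[j], end))
    return per_group


def max_concurrency(intervals):
    """Peak number of simultaneously open intervals (ends release first)."""
    events = sorted(
        [(s, 1) for s, _ in intervals] + [(e, -1) for _, e in intervals if e < math.inf],
        key=lambda ev: (ev[0], ev[1]),
    )
    cur = peak = 0
    for _, delta in events:
        cur += delta
        peak = max(peak, cur)
    return peak


def assert_simulation_invariants(result, tables):
    """Conservation, capacity, work-conservation and wait-recomputation checks."""
    # conservation: every patient is in exactly one terminal bucket
    statuses = {p.status for p in result.patients}
    assert statuses <= {"waiting", "in_service", "discharged"}
    n = len(result.patients)
    assert (
        sum(p.status == "discharged" for p in result.patients)
        + sum(p.status != "discharged" for p in result.patients)
        == n
    )
    per_group = busy_intervals(result.patients, tables)
    for g, intervals in per_group.items():
        # capacity: concurrent services never exceed the unit count
        cap = tables.capacities[g]
        assert max_concurrency(intervals) <= cap
        # work-conservation: a positive wait implies the group was full just
        # before the service started
        starts = sorted(intervals)
        for p in result.patients:
            for j, code in enumerate(p.codes):
                spec = tables.treatments[code]
                if (
                    spec.resource_group != g
                    or spec.capacity_exempt
                    or p.starts[j] is None
                    or p.waits[j] <= 1e-9
                ):
                    continue
                s = p.starts[j]
                busy_before = sum(1 for st, en in intervals if st < s and en >= s)
                assert busy_before == cap, f"idle {g} unit while patient {p.id} waited"
    # waits recomputed from the recorded timestamps
    for p in result.patients:
        ready = p.arrival_time
        for j in range(p.step if p.status != "discharged" else p.n_steps):
            if p.starts[j] is None:
                break
            assert p.waits[j] == (p.starts[j] - ready)
            ready = p.ends[j]


def replay_penalty_percentage(patients, tables, warmup_minutes):
    """Independent penalty recount straight from the raw per-step stamps."""
    base = {1: 60.0, 2: 180.0}
    num = den = 0
    for p in patients:
        if p.acuity.level not in base or p.arrival_time < warmup_minutes:
            continue
        if p.ends[-1] is None:
            continue
        total_apt = sum(tables.treatments[c].mean for c in p.codes)
        los = p.ends[-1] - p.arrival_time
        den += 1
        num += los > base[p.acuity.level] + total_apt
    return math.nan if den == 0 else 100.0 * num / den
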