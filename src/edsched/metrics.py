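"""Objective and penalty metrics.

Two quantities summarise a simulated instance:

* the acuity-weighted waiting time of a discharged patient,
  ``c_i * sum_j wt_ij`` over the full stay, and its mean over patients;
* the penalty-patient percentage — among discharged acuity-1/2 patients,
  the share whose length of stay exceeded a threshold of 60 minutes
  (acuity 1) or 180 minutes (acuity 2) plus the total average processing
  time of their treatment pattern.

Both are computed only over patients who arrived after the warm-up period
and were discharged before the horizon; patients still in the system at
the horizon are counted separately as censored.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .domain import Patient
from .simulator import SimulationResult

__all__ = [
    "weighted_waiting",
    "penalty_threshold",
    "is_penalty",
    "penalty_percentage",
    "instance_report",
]

_THRESHOLD_BASE = {1: 60.0, 2: 180.0}


def weighted_waiting(patient: Patient) -> float:
    """Acuity-weighted total waiting time (minutes): c_i * sum of all waits."""
    return patient.acuity.waiting_weight * patient.total_wait()


def penalty_threshold(patient: Patient) -> float:
    """Length-of-stay threshold for an acuity-1/2 patient (minutes).

    60 (acuity 1) or 180 (acuity 2) plus the pattern's total average
    processing time. Acuity levels 3-5 carry no threshold.
    """
    base = _THRESHOLD_BASE.get(patient.acuity.level)
    if base is None:
        raise ValueError(f"no penalty threshold for acuity level {patient.acuity.level}")
    return base + patient.total_apt


def is_penalty(patient: Patient) -> bool:
    """True if a discharged acuity-1/2 patient stayed past its threshold."""
    los = patient.discharge_time - patient.arrival_time
    return los > penalty_threshold(patient)


def penalty_percentage(discharged: Iterable[Patient]) -> float:
    """Percent of discharged acuity-1/2 patients over their threshold.

    NaN when no acuity-1/2 patient was discharged (undefined ratio).
    """
    urgent = [p for p in discharged if p.acuity.level in _THRESHOLD_BASE]
    if not urgent:
        return math.nan
    return 100.0 * sum(is_penalty(p) for p in urgent) / len(urgent)


def instance_report(result: SimulationResult, warmup_minutes: float = 0.0) -> dict:
    """Summary metrics of one instance, restricted to post-warm-up arrivals."""
    discharged = result.discharged(arrived_after=warmup_minutes)
    report: dict = {
        "n_discharged": len(discharged),
        "n_censored": len(result.censored(arrived_after=warmup_minutes)),
        "mean_weighted_wait": (
            float(np.mean([weighted_waiting(p) for p in discharged])) if discharged else math.nan
        ),
        "penalty_pct": penalty_percentage(discharged),
    }
    for level in range(1, 6):
        grp = [p for p in discharged if p.acuity.level == level]
        report[f"discharged_acuity{level}"] = len(grp)
        report[f"mean_wait_acuity{level}"] = (
            float(np.mean([p.total_wait() for p in grp])) if grp else math.nan
        )
    return report
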