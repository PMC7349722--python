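"""MDP view over the simulator: state vectors, per-patient features, reward.

State: for each resource group, the composition of its waiting list as two
ratio vectors — the share of each acuity level (5 entries) and the share of
each treatment type the group performs. Ratios keep every entry in [0, 1];
an empty waiting list maps to the all-zero vector (the ratio is undefined
at zero waiters, and zeros signal "nothing waiting"). The global state
concatenates the four group states in fixed order, giving 29 entries with
the default tables: (5+2) doctor + (5+5) nurse + (5+1) xray + (5+1) ct.

Action: choosing one patient from a group's waiting list. A candidate is
described to the Q-network by a 12-entry feature vector: acuity level,
accumulated weighted waiting time (including the still-open wait), a
one-hot over the nine treatment codes for the treatment it awaits, and
that treatment's average processing time. Actual durations are never
features — they are unknown until a treatment finishes.

Reward: minus the acuity-weighted waiting time the selected patient has
accumulated up to the moment of selection, i.e. -c_i * sum of its waits
including the wait this selection terminates. Always <= 0, and 0 for a
patient that never waited.
"""

from __future__ import annotations

import numpy as np

from .domain import CODES, GROUP_ORDER, DomainTables, Patient, load_tables

__all__ = [
    "state_dim",
    "feature_dim",
    "compute_state",
    "features",
    "compute_reward",
    "MinMaxScaler",
]

_CODE_INDEX = {c: i for i, c in enumerate(CODES)}

#: feature-vector length: acuity + weighted wait + one-hot(9) + apt
FEATURE_DIM = 1 + 1 + len(CODES) + 1


def state_dim(tables: DomainTables | None = None) -> int:
    """Length of the global state vector (29 with the default tables)."""
    tables = tables or load_tables()
    n_acuity = len(tables.acuity_levels)
    return sum(n_acuity + len(tables.group_treatments[g]) for g in GROUP_ORDER)


def feature_dim() -> int:
    return FEATURE_DIM


def compute_state(
    waiting: dict[str, list[Patient]], tables: DomainTables | None = None
) -> np.ndarray:
    """Global state vector from the per-group waiting lists.

    Permutation-invariant in each list (it only counts compositions).
    """
    tables = tables or load_tables()
    levels = tables.acuity_levels
    parts = np.zeros(state_dim(tables))
    offset = 0
    for g in GROUP_ORDER:
        codes = tables.group_treatments[g]
        block = len(levels) + len(codes)
        queue = waiting.get(g, ())
        n = len(queue)
        if n:
            # integer counts first, one division after: exact point masses
            level_pos = {a: offset + i for i, a in enumerate(levels)}
            code_pos = {c: offset + len(levels) + i for i, c in enumerate(codes)}
            for p in queue:
                parts[level_pos[p.acuity.level]] += 1
                parts[code_pos[p.current_code]] += 1
            parts[offset : offset + block] /= n
        offset += block
    return parts


def features(patient: Patient, t: float) -> np.ndarray:
    """Per-candidate feature vector fed to the Q-network.

    Layout: (acuity level, c_i x accumulated wait at t, one-hot current
    treatment over A..I, average processing time of that treatment).
    """
    vec = np.zeros(FEATURE_DIM)
    vec[0] = patient.acuity.level
    vec[1] = patient.acuity.waiting_weight * patient.accumulated_wait(t)
    vec[2 + _CODE_INDEX[patient.current_code]] = 1.0
    vec[-1] = patient.current_apt
    return vec


def compute_reward(patient: Patient, t: float) -> float:
    """Reward for selecting ``patient`` at time ``t`` (non-positive minutes).

    Equals minus the acuity-weighted sum of all waits the patient accrued
    so far, including the wait this selection brings to an end.
    """
    return -patient.acuity.waiting_weight * patient.accumulated_wait(t)


class MinMaxScaler:
    """Optional affine [0, 1] scaling of the two time-valued features.

    The state ratios are already in [0, 1]; the weighted-wait and
    average-processing-time features are raw minutes by default. When
    enabled this maps feature ``i`` through ``(x - lo_i) / (hi_i - lo_i)``,
    a bijection whose parameters round-trip through :meth:`get_params`.
    Disabled (identity) by default.
    """

    TIME_FEATURES = (1, FEATURE_DIM - 1)

    def __init__(self, weighted_wait_range=(0.0, 1.0), apt_range=(0.0, 1.0), enabled: bool = False):
        self.enabled = enabled
        self.ranges = {
            self.TIME_FEATURES[0]: tuple(map(float, weighted_wait_range)),
            self.TIME_FEATURES[1]: tuple(map(float, apt_range)),
        }
        for lo, hi in self.ranges.values():
            if hi <= lo:
                raise ValueError("range upper bound must exceed lower bound")

    def transform(self, vec: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return vec
        out = vec.copy()
        for i, (lo, hi) in self.ranges.items():
            out[..., i] = (vec[..., i] - lo) / (hi - lo)
        return out

    def inverse_transform(self, vec: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return vec
        out = vec.copy()
        for i, (lo, hi) in self.ranges.items():
            out[..., i] = vec[..., i] * (hi - lo) + lo
        return out

    def get_params(self) -> dict:
        return {
            "enabled": self.enabled,
            "weighted_wait_range": self.ranges[self.TIME_FEATURES[0]],
            "apt_range": self.ranges[self.TIME_FEATURES[1]],
        }
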