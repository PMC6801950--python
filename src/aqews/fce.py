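"""Fuzzy comprehensive evaluation of daily air quality.

Six pollutant concentrations are graded against five ordered air-quality
levels (I best ... V worst) using halved-trapezoidal membership functions:
the first level saturates downward, the last saturates upward, and the
interior levels are triangular between neighbouring concentration limits.
Factor weights follow the multi-scale scheme (each concentration divided by
the mean of its five level limits, normalized to sum one), the weight vector
and membership matrix are composed with the Zadeh min-max operator, and the
level with the largest composite membership wins, ties resolving to the
better level.  Each level maps to a fixed early-warning handbook entry
(category, colour, condition, recommended measures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import POLLUTANTS

__all__ = [
    "LEVELS",
    "DEFAULT_LIMITS",
    "HANDBOOK",
    "EvaluationResult",
    "membership_row",
    "membership_matrix",
    "factor_weights",
    "compose",
    "classify",
    "handbook",
    "evaluate_day",
    "evaluate_frame",
]

LEVELS = ("I", "II", "III", "IV", "V")

# Concentration limits per pollutant and level (ug/m^3, CO mg/m^3).
DEFAULT_LIMITS = pd.DataFrame(
    {
        "PM2.5": [35.0, 75.0, 115.0, 150.0, 250.0],
        "PM10": [50.0, 150.0, 250.0, 350.0, 420.0],
        "NO2": [40.0, 80.0, 180.0, 280.0, 565.0],
        "SO2": [50.0, 150.0, 475.0, 800.0, 1600.0],
        "CO": [2.0, 4.0, 14.0, 24.0, 36.0],
        "O3": [100.0, 160.0, 215.0, 265.0, 800.0],
    },
    index=list(LEVELS),
)

HANDBOOK = {
    "I": {
        "category": "excellent",
        "color": "green",
        "condition": "satisfactory air quality",
        "measure": "Outdoor activities are suitable for all people.",
    },
    "II": {
        "category": "good",
        "color": "blue",
        "condition": "acceptable air quality",
        "measure": "The very few abnormally sensitive people should reduce "
                   "outdoor activities.",
    },
    "III": {
        "category": "moderate",
        "color": "yellow",
        "condition": "mild pollution is unhealthy to sensitive people",
        "measure": "Sensitive people including children, the elderly and patients "
                   "with respiratory tract, cardiovascular and cerebrovascular "
                   "diseases should reduce outdoor activities. Public "
                   "transportation is recommended for travel.",
    },
    "IV": {
        "category": "poor",
        "color": "red",
        "condition": "moderate pollution is unhealthy to all people",
        "measure": "Sensitive people should avoid outdoor activities which also "
                   "need to be reduced by general people. Prefer public "
                   "transportation and reduce construction and traffic dust.",
    },
    "V": {
        "category": "hazardous",
        "color": "purple",
        "condition": "heavy pollution is hazardous to all people",
        "measure": "Besides above measures, road flushing and cleaning, "
                   "suspension of large-scale open-air activities, outdoor "
                   "personnel wear masks are all needed.",
    },
}


@dataclass
class EvaluationResult:
    """Full audit trail of one day's evaluation."""

    membership: np.ndarray      # R, 6 x 5
    weights: np.ndarray         # W, length 6, sums to 1
    composite: np.ndarray       # B, length 5
    level: str                  # "I".."V"
    category: str
    color: str
    condition: str
    measure: str


def _limits_matrix(limits) -> np.ndarray:
    if limits is None:
        limits = DEFAULT_LIMITS
    if isinstance(limits, pd.DataFrame):
        arr = limits[list(POLLUTANTS)].to_numpy(dtype=float).T  # 6 x 5
    else:
        arr = np.asarray(limits, dtype=float)
    if arr.shape != (len(POLLUTANTS), len(LEVELS)):
        raise ValueError(f"limits must be {len(POLLUTANTS)}x{len(LEVELS)}")
    if np.any(np.diff(arr, axis=1) <= 0):
        raise ValueError("limits must be strictly increasing across levels")
    return arr


def membership_row(x: float, limits_row) -> np.ndarray:
    """Halved-trapezoidal memberships of one concentration to the 5 levels."""
    u = np.asarray(limits_row, dtype=float).ravel()
    if u.size != len(LEVELS):
        raise ValueError("limits_row must have 5 entries")
    if np.any(np.diff(u) <= 0):
        raise ValueError("limits must be strictly increasing across levels")
    if not np.isfinite(x) or x < 0:
        raise ValueError("concentration must be finite and non-negative")
    r = np.zeros(len(LEVELS))
    # level 1: full membership below u1, linear decay to u2
    if x <= u[0]:
        r[0] = 1.0
    elif x <= u[1]:
        r[0] = (u[1] - x) / (u[1] - u[0])
    # interior levels: triangular between the neighbouring limits
    for j in range(1, len(LEVELS) - 1):
        if u[j - 1] <= x <= u[j]:
            r[j] = (x - u[j - 1]) / (u[j] - u[j - 1])
        elif u[j] < x <= u[j + 1]:
            r[j] = (u[j + 1] - x) / (u[j + 1] - u[j])
    # last level: linear rise from u4, saturating at 1 above u5
    if x > u[-1]:
        r[-1] = 1.0
    elif x > u[-2]:
        r[-1] = (x - u[-2]) / (u[-1] - u[-2])
    return r


def membership_matrix(x, limits=None) -> np.ndarray:
    arr = _limits_matrix(limits)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(POLLUTANTS):
        raise ValueError(f"expected {len(POLLUTANTS)} concentrations")
    return np.vstack([membership_row(xi, row) for xi, row in zip(x, arr)])


def factor_weights(x, limits=None) -> np.ndarray:
    """Multi-scale weights: x_i over the mean of pollutant i's level limits."""
    arr = _limits_matrix(limits)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != arr.shape[0]:
        raise ValueError("one concentration per pollutant required")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("concentrations must be finite and non-negative")
    scores = x / arr.mean(axis=1)
    total = scores.sum()
    if total == 0:
        raise ValueError("all concentrations are zero; weights undefined")
    return scores / total


def compose(weights, membership) -> np.ndarray:
    """Zadeh min-max composition: B_j = max_i min(W_i, R_ij)."""
    W = np.asarray(weights, dtype=float).ravel()
    R = np.atleast_2d(np.asarray(membership, dtype=float))
    if R.shape[0] != W.size:
        raise ValueError("weights length must match membership rows")
    return np.max(np.minimum(W[:, None], R), axis=0)


def classify(composite) -> str:
    """Maximum-membership level; ties go to the better (lower) level."""
    B = np.asarray(composite, dtype=float).ravel()
    if B.size != len(LEVELS):
        raise ValueError("composite vector must have 5 entries")
    if np.all(B == 0):
        raise ValueError("all-zero composite vector: evaluation undefined")
    return LEVELS[int(np.argmax(B))]  # argmax takes the first (best) on ties


def handbook(level: str) -> dict:
    """Early-warning handbook entry for a level."""
    try:
        return dict(HANDBOOK[level])
    except KeyError:
        raise ValueError(f"unknown air-quality level {level!r}") from None


def evaluate_day(x, limits=None) -> EvaluationResult:
    """Grade one day's six concentrations (order PM2.5, PM10, NO2, SO2, CO, O3)."""
    R = membership_matrix(x, limits)
    W = factor_weights(x, limits)
    B = compose(W, R)
    level = classify(B)
    entry = handbook(level)
    return EvaluationResult(membership=R, weights=W, composite=B, level=level,
                            **entry)


def evaluate_frame(frame: pd.DataFrame, limits=None) -> pd.DataFrame:
    """Evaluate every row of a date-indexed six-pollutant DataFrame."""
    rows = []
    for _, row in frame[list(POLLUTANTS)].iterrows():
        res = evaluate_day(row.to_numpy(), limits)
        rows.append(list(res.composite) + [res.level, res.category, res.color])
    cols = [f"b{lv}" for lv in LEVELS] + ["level", "category", "color"]
    return pd.DataFrame(rows, columns=cols, index=frame.index)
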