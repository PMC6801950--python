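"""Forecast-accuracy metrics and the Diebold-Mariano equal-accuracy test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetricReport", "DMResult", "metrics", "dm_test"]


@dataclass
class MetricReport:
    """MAE, RMSE, MAPE (in percent) and Theil's inequality coefficient."""

    mae: float
    rmse: float
    mape: float
    tic: float
    n: int


@dataclass
class DMResult:
    dm_statistic: float
    p_value: float
    loss: str
    n: int


def metrics(pred, actual) -> MetricReport:
    """Compute MAE, RMSE, MAPE (percent) and TIC of a forecast.

    TIC = RMSE / (sqrt(mean(pred^2)) + sqrt(mean(actual^2))) lies in [0, 1]
    with 0 for a perfect forecast.  MAPE requires all actual values nonzero.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.size != actual.size or pred.size == 0:
        raise ValueError("pred and actual must have equal, nonzero length")
    zeros = np.where(actual == 0)[0]
    if zeros.size:
        raise ZeroDivisionError(
            f"MAPE undefined: actual value is zero at index {zeros[0]}")
    err = pred - actual
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err / actual))) * 100.0
    tic = rmse / (float(np.sqrt(np.mean(pred**2))) + float(np.sqrt(np.mean(actual**2))))
    return MetricReport(mae=mae, rmse=rmse, mape=mape, tic=float(tic), n=pred.size)


def dm_test(errors_a, errors_b, alpha: float = 0.05, loss: str = "absolute") -> DMResult:
    """Diebold-Mariano test of equal predictive accuracy.

    The loss differential is ``D_i = |e_a,i| - |e_b,i|`` (absolute-error
    loss); the statistic ``DM = mean(D) / sqrt(s^2 / T)`` with the sample
    variance ``s^2`` of D is referred to the standard normal (two-sided
    p-value).  A positive DM means model *a* has the larger loss.  No
    small-sample correction is applied.
    """
    if loss != "absolute":
        raise NotImplementedError("only the absolute-error loss is implemented")
    ea = np.asarray(errors_a, dtype=float).ravel()
    eb = np.asarray(errors_b, dtype=float).ravel()
    if ea.size != eb.size or ea.size < 2:
        raise ValueError("error series must have equal length >= 2")
    d = np.abs(ea) - np.abs(eb)
    s2 = float(np.var(d, ddof=1))
    if s2 == 0.0:
        raise ZeroDivisionError("loss differential has zero variance (identical losses)")
    dm = float(np.mean(d) / np.sqrt(s2 / d.size))
    p = 2.0 * float(stats.norm.sf(abs(dm)))
    return DMResult(dm_statistic=dm, p_value=p, loss=loss, n=ea.size)
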