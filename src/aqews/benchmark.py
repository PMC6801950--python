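"""Paired comparison of the hybrid forecaster against its ablations.

Runs the full study protocol on one synthetic pollutant series: simulate a
daily series, split off the final ``horizon`` days as the test period, fit
the hybrid ICEEMDAN+WOA-ELM model alongside a plain ELM and a WOA-ELM on
the raw series, produce rolling one-step forecasts for all three, and score
them.  All three models share the seed, the lag window and the hidden-layer
width, so differences isolate the decomposition and the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import make_windows
from .elm import ELMRegressor, WOAELMRegressor
from .hybrid import HybridForecaster, rolling_one_step
from .metrics import MetricReport, metrics
from .synthetic import SynthConfig, generate

__all__ = ["ComparisonResult", "compare_models"]


@dataclass
class ComparisonResult:
    hybrid: MetricReport
    woa_elm: MetricReport
    elm: MetricReport
    seed: int


def compare_models(seed: int, pollutant: str = "PM2.5", n_days: int = 760,
                   horizon: int = 61, window: int = 4, n_hidden: int = 20,
                   woa_iters: int = 50, ensemble_size: int = 10,
                   policy: str = "redecompose") -> ComparisonResult:
    """One paired run: hybrid vs WOA-ELM vs plain ELM on the same series."""
    cfg = SynthConfig(n_days=n_days, seed=seed)
    series = generate(cfg)[pollutant]
    values = series.values
    train, test = values[:-horizon], values[-horizon:]

    hybrid = HybridForecaster(window=window, n_hidden=n_hidden,
                              ensemble_size=ensemble_size,
                              woa_iters=woa_iters, policy=policy,
                              random_state=seed)
    hybrid.fit(train)
    pred_hybrid = hybrid.predict(horizon, actuals=test).integrated

    windows = make_windows(train, window)
    woa_elm = WOAELMRegressor(n_hidden=n_hidden, max_iter=woa_iters,
                              random_state=seed).fit(windows.inputs, windows.targets)
    elm = ELMRegressor(n_hidden=n_hidden,
                       random_state=seed).fit(windows.inputs, windows.targets)
    pred_woa = rolling_one_step(woa_elm, train, test, window)
    pred_elm = rolling_one_step(elm, train, test, window)

    return ComparisonResult(hybrid=metrics(pred_hybrid, test),
                            woa_elm=metrics(pred_woa, test),
                            elm=metrics(pred_elm, test),
                            seed=seed)
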