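"""Decomposition-ensemble pollutant forecaster.

The training series is split by ICEEMDAN into intrinsic mode functions plus
a residue; one whale-optimized ELM is trained per component on lag windows
of that component; forecasts of all components are summed to give the
concentration forecast.  Decomposing first removes mode mixing between the
fast noise-like fluctuations and the slow seasonal/trend structure, so each
predictor faces a far simpler sub-problem than the raw series.

Rolling one-step prediction supports two policies for obtaining the test
period's component values:

``redecompose``
    Before each step the concatenation of the training data and the test
    history observed so far is re-decomposed (never any future value), and
    each model predicts from the latest lag window of its component.  This
    is the causal default.  Because spline envelopes are unreliable at the
    boundary, the history is first extended by an autoregressive forecast
    (``pad_length`` steps, order ``pad_order``) so that the window fed to
    each model sits away from the decomposition edge.
``free_run``
    Decompose once at fit time and let every component model extend its own
    component recursively.  Much cheaper, but component forecasts drift over
    long horizons because observed test values are never used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PollutantSeries, make_windows
from .decomposition import IMFSet, SiftConfig, iceemdan
from .elm import ELMRegressor, WOAELMRegressor

__all__ = ["HybridForecaster", "ForecastResult", "rolling_one_step", "ar_extend"]


def ar_extend(values, n_extend: int, order: int = 6) -> np.ndarray:
    """Extend a series by a least-squares AR(order) forecast.

    Returns the original values followed by ``n_extend`` recursively
    generated points, clipped to the observed range so an unstable fit
    cannot run away.
    """
    x = np.asarray(values, dtype=float).ravel()
    if n_extend < 1:
        return x.copy()
    order = int(min(order, max(1, len(x) // 2 - 1)))
    if len(x) <= order + 1:
        return np.concatenate([x, np.full(n_extend, x[-1])])
    rows = np.stack([x[i: i + order] for i in range(len(x) - order)])
    design = np.column_stack([rows, np.ones(len(rows))])
    coef, *_ = np.linalg.lstsq(design, x[order:], rcond=None)
    lo, hi = x.min(), x.max()
    ext = list(x)
    for _ in range(n_extend):
        nxt = float(np.dot(coef[:-1], ext[-order:]) + coef[-1])
        ext.append(min(max(nxt, lo), hi))
    return np.asarray(ext)


@dataclass
class ForecastResult:
    """Per-component and integrated rolling forecasts."""

    per_component: np.ndarray   # (n_components, horizon)
    integrated: np.ndarray      # (horizon,)
    actuals: np.ndarray | None
    config: dict

    def to_frame(self, dates=None) -> pd.DataFrame:
        frame = pd.DataFrame({"predicted": self.integrated})
        if self.actuals is not None:
            frame["actual"] = self.actuals
        if dates is not None:
            frame.insert(0, "date", pd.DatetimeIndex(dates).strftime("%Y-%m-%d"))
        return frame


def rolling_one_step(model, train_values, test_values, window: int) -> np.ndarray:
    """Rolling one-step forecast of a fitted lag-window regressor.

    Each day's input window is taken from the actual history (train values
    plus observed test values), the standard comparator protocol for
    single-series models.
    """
    history = np.concatenate([np.asarray(train_values, float).ravel(),
                              np.asarray(test_values, float).ravel()])
    n_train = len(train_values)
    rows = np.stack([history[n_train + t - window: n_train + t]
                     for t in range(len(test_values))])
    return model.predict(rows)


class HybridForecaster:
    """ICEEMDAN + WOA-ELM hybrid forecaster for one pollutant series.

    Parameters mirror the submodules: ``window`` is the lag length fed to
    every component model, ``ensemble_size``/``noise_scale`` configure the
    decomposition, ``woa_iters``/``woa_agents`` the optimizer, ``n_hidden``
    the ELM width.  ``max_imfs`` caps the number of extracted modes; the
    default of 4 keeps only components stable enough to re-extract causally
    during prediction (surplus oscillation folds into the residue).
    ``pad_length``/``pad_order`` control the autoregressive edge padding
    used by the ``redecompose`` policy.  All randomness derives from
    ``random_state``.
    """

    def __init__(self, window: int = 4, n_hidden: int = 20,
                 ensemble_size: int = 50, noise_scale: float = 0.2,
                 max_imfs: int = 4, sift_budget: int = 1000,
                 woa_agents: int = 10, woa_iters: int = 200,
                 val_fraction: float = 0.2, scale: bool = True,
                 policy: str = "redecompose", pad_length: int = 60,
                 pad_order: int = 6, random_state: int | None = None):
        if window < 1:
            raise ValueError("window must be >= 1")
        if policy not in ("redecompose", "free_run"):
            raise ValueError(f"unknown policy {policy!r}")
        self.window = window
        self.n_hidden = n_hidden
        self.ensemble_size = ensemble_size
        self.noise_scale = noise_scale
        self.max_imfs = max_imfs
        self.sift_budget = sift_budget
        self.pad_length = pad_length
        self.pad_order = pad_order
        self.woa_agents = woa_agents
        self.woa_iters = woa_iters
        self.val_fraction = val_fraction
        self.scale = scale
        self.policy = policy
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _seeds(self, n: int) -> list[int]:
        if self.random_state is None:
            return [None] * n
        ss = np.random.SeedSequence(self.random_state)
        return [int(s) for s in ss.generate_state(n) % (2**31)]

    def _sift_config(self, seed) -> SiftConfig:
        return SiftConfig(max_imfs=self.max_imfs, ensemble_size=self.ensemble_size,
                          noise_scale=self.noise_scale, sift_budget=self.sift_budget,
                          seed=seed)

    @staticmethod
    def _values(series) -> np.ndarray:
        if isinstance(series, PollutantSeries):
            return series.values.copy()
        if isinstance(series, pd.Series):
            return series.to_numpy(dtype=float)
        return np.asarray(series, dtype=float).ravel()

    def _train_component(self, values: np.ndarray, seed) -> WOAELMRegressor:
        windows = make_windows(values, self.window)
        model = WOAELMRegressor(n_hidden=self.n_hidden, scale=self.scale,
                                clip=True, n_agents=self.woa_agents,
                                max_iter=self.woa_iters,
                                val_fraction=self.val_fraction, random_state=seed)
        return model.fit(windows.inputs, windows.targets)

    # -- API -------------------------------------------------------------

    def fit(self, series) -> "HybridForecaster":
        values = self._values(series)
        if np.any(np.isnan(values)):
            raise ValueError("series contains missing values; impute first")
        if len(values) <= self.window + 10:
            raise ValueError("training series too short for the lag window")
        self.train_values_ = values
        seeds = self._seeds(self.max_imfs + 2)
        self._decomp_seed = seeds[0]
        imfs = iceemdan(values, self._sift_config(self._decomp_seed))
        self.imfs_ = imfs
        if imfs.n_modes == 0:
            # degenerate signal (e.g. a pure trend): model the raw series
            self.fallback_ = True
            self.components_ = [values]
        else:
            self.fallback_ = False
            self.components_ = list(imfs.modes) + [imfs.residue]
        self.models_ = [self._train_component(comp, seeds[1 + i])
                        for i, comp in enumerate(self.components_)]
        self.n_components_ = len(self.models_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("forecaster is not fitted")

    def _components_of(self, history: np.ndarray) -> list[np.ndarray]:
        """Causally decompose a history into n_components_ aligned components.

        The history is first AR-extended so that its final points, the ones
        the component models window over, sit away from the spline-envelope
        boundary; the extension is dropped from the returned components.
        """
        if self.fallback_:
            return [history]
        n_modes = self.n_components_ - 1
        cfg = self._sift_config(self._decomp_seed)
        cfg.max_imfs = n_modes  # surplus oscillation folds into the residue
        padded = ar_extend(history, self.pad_length, self.pad_order)
        imfs = iceemdan(padded, cfg)
        comps = [m[: len(history)] for m in imfs.modes]
        while len(comps) < n_modes:  # vanished low-frequency mode: contribute 0
            comps.append(np.zeros_like(history))
        comps.append(imfs.residue[: len(history)])
        return comps

    def predict(self, horizon: int, actuals=None, policy: str | None = None) -> ForecastResult:
        """Rolling one-step forecasts ``horizon`` days ahead.

        With ``actuals`` given (required length >= horizon), each step
        conditions on the observed history; without it the forecaster feeds
        its own integrated predictions back in.
        """
        self._check_fitted()
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        policy = policy or self.policy
        if actuals is not None:
            actuals = self._values(actuals)
            if len(actuals) < horizon:
                raise ValueError("actuals shorter than the requested horizon")
        per_comp = np.zeros((self.n_components_, horizon))

        if policy == "free_run":
            histories = [comp.copy() for comp in self.components_]
            for t in range(horizon):
                for c, model in enumerate(self.models_):
                    x = histories[c][-self.window:][None, :]
                    per_comp[c, t] = model.predict(x)[0]
                    histories[c] = np.append(histories[c], per_comp[c, t])
        else:  # redecompose
            history = self.train_values_.copy()
            for t in range(horizon):
                comps = self._components_of(history)
                for c, model in enumerate(self.models_):
                    x = comps[c][-self.window:][None, :]
                    per_comp[c, t] = model.predict(x)[0]
                next_obs = (actuals[t] if actuals is not None
                            else per_comp[:, t].sum())
                history = np.append(history, next_obs)

        integrated = per_comp.sum(axis=0)
        config = {k: getattr(self, k) for k in
                  ("window", "n_hidden", "ensemble_size", "noise_scale",
                   "max_imfs", "woa_agents", "woa_iters", "val_fraction",
                   "scale", "policy", "pad_length", "pad_order",
                   "random_state")}
        return ForecastResult(per_component=per_comp, integrated=integrated,
                              actuals=None if actuals is None else actuals[:horizon],
                              config=config)

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        payload = {
            "params": {k: getattr(self, k) for k in
                       ("window", "n_hidden", "ensemble_size", "noise_scale",
                        "max_imfs", "sift_budget", "woa_agents", "woa_iters",
                        "val_fraction", "scale", "policy", "pad_length",
                        "pad_order", "random_state")},
            "fallback": self.fallback_,
            "decomp_seed": self._decomp_seed,
            "train_values": self.train_values_.tolist(),
            "components": [c.tolist() for c in self.components_],
            "models": [],
        }
        for m in self.models_:
            entry = {
                "input_weights": m.input_weights_.tolist(),
                "biases": m.biases_.tolist(),
                "output_weights": np.asarray(m.output_weights_).tolist(),
                "activation": m.activation,
                "scale": m.scale,
                "clip": m.clip,
            }
            if m.scale:
                entry["x_lo"] = np.asarray(m._x_scaler.lo).tolist()
                entry["x_span"] = np.asarray(m._x_scaler.span).tolist()
                entry["y_lo"] = float(m._y_scaler.lo)
                entry["y_span"] = float(m._y_scaler.span)
            payload["models"].append(entry)
        return payload

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "HybridForecaster":
        from .elm import _MinMax  # shared scaler implementation

        obj = cls(**payload["params"])
        obj.fallback_ = payload["fallback"]
        obj._decomp_seed = payload["decomp_seed"]
        obj.train_values_ = np.asarray(payload["train_values"], dtype=float)
        obj.components_ = [np.asarray(c, dtype=float) for c in payload["components"]]
        obj.models_ = []
        for entry in payload["models"]:
            m = WOAELMRegressor(n_hidden=len(entry["biases"]),
                                activation=entry["activation"],
                                scale=entry["scale"],
                                clip=entry.get("clip", True))
            m.input_weights_ = np.asarray(entry["input_weights"], dtype=float)
            m.biases_ = np.asarray(entry["biases"], dtype=float)
            m.output_weights_ = np.asarray(entry["output_weights"], dtype=float)
            m.n_features_in_ = m.input_weights_.shape[1]
            if entry["scale"]:
                xs, ys = _MinMax(), _MinMax()
                xs.lo = np.asarray(entry["x_lo"], dtype=float)
                xs.span = np.asarray(entry["x_span"], dtype=float)
                ys.lo = entry["y_lo"]
                ys.span = entry["y_span"]
                m._x_scaler, m._y_scaler = xs, ys
            obj.models_.append(m)
        obj.n_components_ = len(obj.models_)
        return obj

    @classmethod
    def load(cls, path) -> "HybridForecaster":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
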