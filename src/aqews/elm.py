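"""Extreme learning machines, plain and whale-optimized.

An ELM is a single-hidden-layer feedforward network whose input weights and
biases are drawn at random and never trained; only the output weights are
fitted, in closed form, as the minimum-norm least-squares solution
``beta = pinv(H) @ T`` where ``H`` is the hidden-layer output matrix.  The
whale-optimized variant replaces the random draw by a WOA search over the
flattened (weights, biases) vector, scored by validation RMSE on a
chronological tail split, with ``beta`` re-solved analytically for every
candidate.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data_io import SupervisedWindows
from .woa import WOAConfig, optimize

__all__ = [
    "hidden_matrix",
    "solve_output_weights",
    "ELMRegressor",
    "WOAELMRegressor",
    "train_elm",
    "train_woa_elm",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


def hidden_matrix(X, weights, biases, activation: str = "sigmoid") -> np.ndarray:
    """Hidden-layer output matrix ``H[j, i] = g(w_i . x_j + b_i)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    biases = np.asarray(biases, dtype=float).ravel()
    if weights.shape[1] != X.shape[1] or biases.size != weights.shape[0]:
        raise ValueError("weight/bias shapes do not match the input matrix")
    try:
        g = _ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None
    return g(X @ weights.T + biases)


def solve_output_weights(H, T) -> np.ndarray:
    """Minimum-norm least-squares output weights via the pseudoinverse."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.asarray(T, dtype=float)
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


class _MinMax:
    """Train-only min-max scaler to [0, 1]; degenerate ranges map to 0."""

    def fit(self, a: np.ndarray) -> "_MinMax":
        a = np.asarray(a, dtype=float)
        self.lo = a.min(axis=0)
        rng = a.max(axis=0) - self.lo
        self.span = np.where(rng == 0, 1.0, rng)
        return self

    def transform(self, a):
        return (np.asarray(a, dtype=float) - self.lo) / self.span

    def inverse(self, a):
        return np.asarray(a, dtype=float) * self.span + self.lo


class ELMRegressor(RegressorMixin, BaseEstimator):
    """Extreme learning machine for regression.

    Parameters
    ----------
    n_hidden : hidden-neuron count L.  With L equal to the number of
        (full-rank) training samples the network interpolates the targets
        exactly.
    activation : "sigmoid" (default) or "tanh".
    scale : min-max scale inputs and targets to [0, 1], fitted on the
        training data only.  Recommended for sigmoid conditioning.
    clip : with ``scale`` on, clip scaled inputs and predictions to [0, 1]
        at predict time.  Keeps recursive forecasts inside the training
        range instead of letting the network extrapolate freely.
    random_state : seed for the uniform[-1, 1] draw of weights and biases.
    """

    def __init__(self, n_hidden: int = 20, activation: str = "sigmoid",
                 scale: bool = True, clip: bool = False,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.activation = activation
        self.scale = scale
        self.clip = clip
        self.random_state = random_state

    def _init_hidden(self, rng: np.random.Generator, n_features: int) -> None:
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(self.n_hidden, n_features))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)

    def _prepare(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.n_features_in_ = X.shape[1]
        if self.scale:
            self._x_scaler = _MinMax().fit(X)
            self._y_scaler = _MinMax().fit(y)
            return self._x_scaler.transform(X), self._y_scaler.transform(y)
        return X, y

    def _solve(self, Xs, ys) -> None:
        H = hidden_matrix(Xs, self.input_weights_, self.biases_, self.activation)
        self.output_weights_ = solve_output_weights(H, ys)

    def fit(self, X, y):
        Xs, ys = self._prepare(X, y)
        rng = np.random.default_rng(self.random_state)
        self._init_hidden(rng, self.n_features_in_)
        self._solve(Xs, ys)
        return self

    def predict(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        if self.scale:
            X = self._x_scaler.transform(X)
            if self.clip:
                X = np.clip(X, 0.0, 1.0)
        H = hidden_matrix(X, self.input_weights_, self.biases_, self.activation)
        pred = H @ self.output_weights_
        if self.scale:
            if self.clip:
                pred = np.clip(pred, 0.0, 1.0)
            pred = self._y_scaler.inverse(pred)
        return pred


class WOAELMRegressor(ELMRegressor):
    """ELM whose hidden parameters are tuned by the whale optimizer.

    The search space is the flattened (input weights, biases) vector with
    box bounds [-1, 1]; the fitness of a candidate is the RMSE on a
    chronological validation tail (``val_fraction`` of the training rows),
    with the output weights re-solved by pseudoinverse on the remaining
    head.  The returned model keeps the best candidate and its head-fitted
    output weights, so its measured validation RMSE never exceeds that of
    the best initial random draw.
    """

    def __init__(self, n_hidden: int = 20, activation: str = "sigmoid",
                 scale: bool = True, clip: bool = False, n_agents: int = 10,
                 max_iter: int = 200, val_fraction: float = 0.2,
                 spiral_b: float = 1.0, random_state: int | None = None):
        super().__init__(n_hidden=n_hidden, activation=activation, scale=scale,
                         clip=clip, random_state=random_state)
        self.n_agents = n_agents
        self.max_iter = max_iter
        self.val_fraction = val_fraction
        self.spiral_b = spiral_b

    def fit(self, X, y):
        Xs, ys = self._prepare(X, y)
        n = Xs.shape[0]
        n_fit = max(1, int(round((1.0 - self.val_fraction) * n)))
        if n_fit >= n:
            raise ValueError("val_fraction leaves no validation samples")
        X_fit, y_fit = Xs[:n_fit], ys[:n_fit]
        X_val, y_val = Xs[n_fit:], ys[n_fit:]
        L, nf = self.n_hidden, self.n_features_in_

        def unpack(theta: np.ndarray):
            w = theta[: L * nf].reshape(L, nf)
            b = theta[L * nf:]
            return w, b

        def val_rmse(theta: np.ndarray) -> float:
            w, b = unpack(theta)
            H = hidden_matrix(X_fit, w, b, self.activation)
            beta = solve_output_weights(H, y_fit)
            resid = hidden_matrix(X_val, w, b, self.activation) @ beta - y_val
            return float(np.sqrt(np.mean(resid**2)))

        cfg = WOAConfig(dim=L * nf + L, lower=-1.0, upper=1.0,
                        n_agents=self.n_agents, max_iter=self.max_iter,
                        spiral_b=self.spiral_b, seed=self.random_state)
        result = optimize(val_rmse, cfg)
        self.input_weights_, self.biases_ = unpack(result.best_position)
        self._solve(X_fit, y_fit)
        self.validation_rmse_ = result.best_fitness
        self.history_ = result.history
        return self


def train_elm(windows: SupervisedWindows, n_hidden: int = 20,
              activation: str = "sigmoid", seed: int | None = None,
              scale: bool = True) -> ELMRegressor:
    return ELMRegressor(n_hidden=n_hidden, activation=activation, scale=scale,
                        random_state=seed).fit(windows.inputs, windows.targets)


def train_woa_elm(windows: SupervisedWindows, n_hidden: int = 20,
                  n_agents: int = 10, max_iter: int = 200,
                  val_fraction: float = 0.2, seed: int | None = None,
                  scale: bool = True, activation: str = "sigmoid") -> WOAELMRegressor:
    return WOAELMRegressor(n_hidden=n_hidden, activation=activation, scale=scale,
                           n_agents=n_agents, max_iter=max_iter,
                           val_fraction=val_fraction,
                           random_state=seed).fit(windows.inputs, windows.targets)
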