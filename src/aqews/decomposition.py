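"""Empirical mode decomposition and its improved complete-ensemble variant.

EMD expresses a signal as a small number of intrinsic mode functions (IMFs)
plus a final residue.  Each IMF is obtained by *sifting*: cubic-spline
envelopes are drawn through the local maxima and minima, their mean is
subtracted, and the step repeats until the candidate satisfies a Cauchy-type
stopping criterion.  ICEEMDAN stabilises EMD on noisy data by averaging the
local-mean operator over an ensemble of white-noise-perturbed copies of the
current residue, which removes mode mixing while keeping the reconstruction
``sum(modes) + residue == signal`` exact by construction (the modes are
defined as successive differences of residues, so the sum telescopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = ["SiftConfig", "IMFSet", "emd", "iceemdan", "local_mean"]


@dataclass
class SiftConfig:
    """Knobs of the sifting core and the noise ensemble.

    ``max_sift_iters`` and ``sd_threshold`` control when one sift loop stops
    (Cauchy criterion: ``sum(m^2)/sum(h^2) < sd_threshold``).  ``sift_budget``
    bounds the total number of sift iterations spent on one decomposition
    run (applied independently to the signal path and to each noise
    realization).  ``ensemble_size`` and ``noise_scale`` only matter for
    :func:`iceemdan`; the per-stage noise amplitude is
    ``noise_scale * std(current residue)``.
    """

    max_sift_iters: int = 100
    sd_threshold: float = 0.2
    max_imfs: int = 16
    ensemble_size: int = 50
    noise_scale: float = 0.2
    sift_budget: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_sift_iters < 1 or self.max_imfs < 1 or self.sift_budget < 1:
            raise ValueError("iteration limits must be positive")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the final residue."""

    modes: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for m in self.modes:
            out += m
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per time point, columns ``imf1..imfK, residue``."""
        data = {f"imf{k + 1}": m for k, m in enumerate(self.modes)}
        data["residue"] = self.residue
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IMFSet":
        cols = [c for c in frame.columns if c.startswith("imf")]
        cols.sort(key=lambda c: int(c[3:]))
        modes = [frame[c].to_numpy(dtype=float) for c in cols]
        residue = frame["residue"].to_numpy(dtype=float)
        return cls(modes=modes, residue=residue, source_length=len(frame))


class _Budget:
    __slots__ = ("remaining",)

    def __init__(self, total: int) -> None:
        self.remaining = int(total)


def _validate_signal(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("signal must have at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return x


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima/minima; flat segments take the leading sign."""
    dx = np.diff(x)
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        empty = np.empty(0, dtype=int)
        return empty, empty
    if not nz.all():
        # forward-fill zero slopes with the previous non-zero slope sign
        idx = np.where(nz, np.arange(sign.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first = sign[nz][0]
        sign = np.where(idx >= 0, sign[np.maximum(idx, 0)], first)
    change = np.diff(sign)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _n_extrema(x: np.ndarray) -> int:
    mx, mn = _extrema_indices(x)
    return mx.size + mn.size


def _mirrored_knots(idx: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by mirroring up to three of them about each boundary."""
    n = x.size
    k = min(3, idx.size)
    left_t = -idx[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    t, v = _mirrored_knots(idx, x)
    if t.size < 2:  # cannot happen with >=1 extremum, kept as guard
        return np.full(x.size, v[0] if v.size else 0.0)
    spline = CubicSpline(t, v, bc_type="natural")
    return spline(np.arange(x.size, dtype=float))


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    mx, mn = _extrema_indices(x)
    if mx.size == 0 or mn.size == 0:
        return None
    upper = _envelope(mx, x)
    lower = _envelope(mn, x)
    return 0.5 * (upper + lower)


def local_mean(signal) -> np.ndarray:
    """Mean of the cubic-spline extrema envelopes (removed in one sift).

    A signal without both interior maxima and minima carries no oscillation,
    so it is its own local mean.
    """
    x = _validate_signal(signal)
    m = _envelope_mean(x)
    return x.copy() if m is None else m


def _sift_mode(x: np.ndarray, cfg: SiftConfig, budget: _Budget) -> np.ndarray:
    """Extract one IMF candidate by repeated envelope-mean subtraction."""
    h = x.copy()
    for _ in range(cfg.max_sift_iters):
        if budget.remaining <= 0:
            break
        m = _envelope_mean(h)
        if m is None:
            break
        budget.remaining -= 1
        denom = float(np.dot(h, h))
        h = h - m
        if denom == 0.0:
            break
        if float(np.dot(m, m)) / denom < cfg.sd_threshold:
            break
    return h


class _StreamingEMD:
    """Extracts EMD modes of one signal on demand, caching earlier modes."""

    def __init__(self, x: np.ndarray, cfg: SiftConfig) -> None:
        self._residue = x.copy()
        self._cfg = cfg
        self._budget = _Budget(cfg.sift_budget)
        self.modes: list[np.ndarray] = []
        self._done = False

    def _advance(self) -> None:
        if self._done or len(self.modes) >= self._cfg.max_imfs:
            self._done = True
            return
        if _n_extrema(self._residue) < 3 or self._budget.remaining <= 0:
            self._done = True
            return
        d = _sift_mode(self._residue, self._cfg, self._budget)
        if not np.any(d):
            self._done = True
            return
        self.modes.append(d)
        self._residue = self._residue - d

    def mode(self, k: int) -> np.ndarray | None:
        """k-th mode (1-based), or None if the signal has fewer modes."""
        while len(self.modes) < k and not self._done:
            self._advance()
        return self.modes[k - 1] if len(self.modes) >= k else None

    @property
    def residue(self) -> np.ndarray:
        return self._residue


def emd(signal, cfg: SiftConfig | None = None) -> IMFSet:
    """Plain empirical mode decomposition.

    A constant or monotone signal (no interior extrema) yields zero modes
    and ``residue == signal``.
    """
    cfg = cfg or SiftConfig()
    x = _validate_signal(signal)
    stream = _StreamingEMD(x, cfg)
    stream.mode(cfg.max_imfs)  # drive extraction to exhaustion
    return IMFSet(modes=list(stream.modes), residue=stream.residue.copy(),
                  source_length=x.size)


def _local_mean_operator(y: np.ndarray, cfg: SiftConfig, budget: _Budget) -> np.ndarray:
    """M(.): the signal minus its first (fully sifted) mode."""
    if _n_extrema(y) < 3:
        return y
    d = _sift_mode(y, cfg, budget)
    return y - d


def iceemdan(signal, cfg: SiftConfig | None = None) -> IMFSet:
    """Improved complete ensemble EMD with adaptive noise.

    Stage 1 averages the local mean of ``x + beta_0 * E_1(w_i)`` over the
    noise ensemble to obtain residue ``r_1`` and mode ``d_1 = x - r_1``;
    later stages perturb the running residue with the matching-order noise
    mode ``E_k(w_i)`` at amplitude ``noise_scale * std(r_{k-1})``.  Because
    each mode is the difference of consecutive residues, the reconstruction
    is exact regardless of ensemble size.
    """
    cfg = cfg or SiftConfig()
    if cfg.ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    x = _validate_signal(signal)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((cfg.ensemble_size, x.size))
    noise_emd = [_StreamingEMD(w, cfg) for w in noise]

    modes: list[np.ndarray] = []
    r_prev = x.copy()
    k = 1
    while len(modes) < cfg.max_imfs and _n_extrema(r_prev) >= 3:
        beta = cfg.noise_scale * float(np.std(r_prev))
        acc = np.zeros_like(x)
        count = 0
        if beta > 0:
            for stream in noise_emd:
                ek = stream.mode(k)
                if ek is None:
                    continue
                budget = _Budget(cfg.sift_budget)
                acc += _local_mean_operator(r_prev + beta * ek, cfg, budget)
                count += 1
        if count == 0:  # noise-free limit, or noise realizations exhausted
            budget = _Budget(cfg.sift_budget)
            acc = _local_mean_operator(r_prev, cfg, budget)
            count = 1
        r_k = acc / count
        d_k = r_prev - r_k
        if not np.any(d_k):
            break
        modes.append(d_k)
        r_prev = r_k
        k += 1
    return IMFSet(modes=modes, residue=r_prev, source_length=x.size)
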