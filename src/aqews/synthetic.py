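"""Synthetic daily pollutant series with realistic marginal statistics.

Each pollutant is simulated as a latent standardized process — an AR(2) base
(persistence), an annual sinusoid (seasonality) and white noise — pushed
through either a lognormal link (right-skewed, strictly positive, the
default: pollutant concentrations show maxima far above their means) or a
truncated-Gaussian link, then affinely recalibrated so the sample mean and
standard deviation match the per-pollutant targets exactly before clipping
at zero.  Default targets are the observed two-year Beijing statistics
(mean/std per pollutant); particulates and combustion tracers peak in
winter, ozone in summer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import POLLUTANTS, PollutantSeries

__all__ = ["SynthConfig", "BEIJING_TARGETS", "generate", "generate_frame",
           "inject_missing"]

# (mean, std) of daily concentrations, Beijing Sep 2016 - Sep 2018.
BEIJING_TARGETS = {
    "PM2.5": (61.2, 57.5),
    "PM10": (89.8, 72.8),
    "NO2": (45.5, 22.2),
    "SO2": (7.2, 7.2),
    "CO": (1.0, 0.8),
    "O3": (98.4, 63.3),
}

# Seasonal phase: +1 peaks mid-winter (day ~0 = 1 Sep start -> shifted),
# -1 peaks mid-summer.  Ozone is photochemical, hence summer-peaked.
_WINTER_PEAK = {"PM2.5": 1, "PM10": 1, "NO2": 1, "SO2": 1, "CO": 1, "O3": -1}


@dataclass
class SynthConfig:
    targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BEIJING_TARGETS))
    n_days: int = 760
    start: str = "2016-09-01"
    ar_coefs: tuple[float, float] = (0.6, 0.25)
    ar_share: float = 0.45       # variance shares of the latent process
    seasonal_share: float = 0.35
    noise_share: float = 0.20
    period: float = 365.25
    noise_family: str = "lognormal"  # or "gaussian-truncated"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_days < 100:
            raise ValueError("n_days must be >= 100")
        for p, (mean, std) in self.targets.items():
            if p not in POLLUTANTS:
                raise ValueError(f"unknown pollutant {p!r}")
            if mean <= 0 or std <= 0:
                raise ValueError(f"mean and std for {p} must be positive")
        shares = (self.ar_share, self.seasonal_share, self.noise_share)
        if any(s < 0 for s in shares) or sum(shares) <= 0:
            raise ValueError("variance shares must be non-negative and not all zero")
        if self.noise_family not in ("lognormal", "gaussian-truncated"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")


def _standardize(a: np.ndarray) -> np.ndarray:
    s = a.std()
    return (a - a.mean()) / s if s > 0 else np.zeros_like(a)


def _latent(cfg: SynthConfig, rng: np.random.Generator, winter_peak: int) -> np.ndarray:
    n = cfg.n_days
    phi1, phi2 = cfg.ar_coefs
    burn = 200
    eps = rng.standard_normal(n + burn)
    z = np.zeros(n + burn)
    for t in range(2, n + burn):
        z[t] = phi1 * z[t - 1] + phi2 * z[t - 2] + eps[t]
    ar = _standardize(z[burn:])

    t = np.arange(n, dtype=float)
    # 1 Sep start: winter solstice ~ day 111; align peak accordingly
    phase = 2.0 * np.pi * (t - 111.0) / cfg.period
    seasonal = _standardize(winter_peak * np.cos(phase)) if cfg.seasonal_share > 0 \
        else np.zeros(n)
    white = rng.standard_normal(n)

    total = cfg.ar_share + cfg.seasonal_share + cfg.noise_share
    g = (np.sqrt(cfg.ar_share / total) * ar
         + np.sqrt(cfg.seasonal_share / total) * seasonal
         + np.sqrt(cfg.noise_share / total) * white)
    return _standardize(g) if g.std() > 0 else g


def _link(g: np.ndarray, mean: float, std: float, family: str) -> np.ndarray:
    if family == "lognormal":
        # exponential link calibrated in log space: solve for the log-scale
        # that reproduces the target coefficient of variation exactly, then
        # match the mean multiplicatively.  Strictly positive by construction.
        from scipy.optimize import brentq

        target_cv = std / mean
        if g.std() == 0:
            raise ValueError("latent process is constant; cannot match std > 0")

        def cv_gap(s: float) -> float:
            y = np.exp(s * g)
            return y.std() / y.mean() - target_cv

        scale = brentq(cv_gap, 1e-9, 20.0, xtol=1e-12)
        y = np.exp(scale * g)
        return y * (mean / y.mean())
    # truncated-Gaussian link: affine then clip; clipping is a tail effect
    y = mean + std * g
    s = y.std()
    if s > 0:
        y = (y - y.mean()) * (std / s) + mean
    y = np.clip(y, 0.0, None)
    if y.mean() <= 0:
        raise ValueError("infeasible mean/std combination after clipping")
    return y


def generate(cfg: SynthConfig | None = None) -> dict[str, PollutantSeries]:
    """Simulate all configured pollutants; reproducible from ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    out: dict[str, PollutantSeries] = {}
    for i, pollutant in enumerate(POLLUTANTS):
        if pollutant not in cfg.targets:
            continue
        rng = np.random.default_rng(None if cfg.seed is None
                                    else [cfg.seed, i])
        mean, std = cfg.targets[pollutant]
        g = _latent(cfg, rng, _WINTER_PEAK[pollutant])
        values = _link(g, mean, std, cfg.noise_family)
        out[pollutant] = PollutantSeries(pollutant, dates, values)
    return out


def generate_frame(cfg: SynthConfig | None = None) -> pd.DataFrame:
    """Same as :func:`generate` but as one date-indexed DataFrame."""
    series = generate(cfg)
    frame = pd.DataFrame({p: s.values for p, s in series.items()},
                         index=next(iter(series.values())).dates)
    frame.index.name = "date"
    return frame


def inject_missing(series: PollutantSeries, fraction: float,
                   seed: int | None = None) -> PollutantSeries:
    """Mask exactly ``floor(fraction * n)`` interior points as missing."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    n = len(series)
    k = int(np.floor(fraction * n))
    values = series.values.copy()
    if k:
        rng = np.random.default_rng(seed)
        interior = np.arange(1, n - 1)
        idx = rng.choice(interior, size=k, replace=False)
        values[idx] = np.nan
    return PollutantSeries(series.pollutant, series.dates, values)
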