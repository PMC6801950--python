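"""Shared fixtures for the aqews test suite."""

import numpy as np
import pandas as pd
import pytest

from aqews import PollutantSeries, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_series():
    """A 120-day PM2.5 series with a known seed."""
    return generate(SynthConfig(n_days=120, seed=7))["PM2.5"]


@pytest.fixture
def tiny_series():
    """A hand-built 10-day series with one missing value."""
    dates = pd.date_range("2020-01-01", periods=10, freq="D")
    values = np.array([10.0, 12.0, np.nan, 16.0, 14.0, 13.0, 15.0, 11.0, 9.0, 10.0])
    return PollutantSeries("PM2.5", dates, values)


@pytest.fixture
def two_tone():
    """sin(2*pi*8t) + sin(2*pi*1t) on one second, and its two source tones."""
    t = np.linspace(0.0, 1.0, 1000)
    hi = np.sin(2.0 * np.pi * 8.0 * t)
    lo = np.sin(2.0 * np.pi * 1.0 * t)
    return hi + lo, hi, lo
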