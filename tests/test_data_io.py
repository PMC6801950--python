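import numpy as np
import pandas as pd
import pytest

from aqews import (POLLUTANTS, PollutantSeries, impute_missing, make_windows,
                   read_frame, read_series, split_train_test, write_series)


def test_roundtrip_csv(tmp_path, tiny_series):
    path = tmp_path / "s.csv"
    write_series(tiny_series, path)
    back = read_series(path, "PM2.5")
    np.testing.assert_allclose(back.values, tiny_series.values, equal_nan=True)
    assert (back.dates == tiny_series.dates).all()


def test_read_series_sorts_and_coerces(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("date,PM2.5\n2020-01-02,5\n2020-01-01,bad\n2020-01-03,7\n")
    s = read_series(path, "PM2.5")
    assert np.isnan(s.values[0]) and s.values[1] == 5.0 and s.values[2] == 7.0
    assert s.dates[0] == pd.Timestamp("2020-01-01")


def test_read_series_column_map(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("day,pm25\n2020-01-01,3\n2020-01-02,4\n")
    s = read_series(path, "PM2.5", column_map={"day": "date", "pm25": "PM2.5"})
    assert len(s) == 2


def test_read_series_errors(tmp_path):
    missing = tmp_path / "m.csv"
    missing.write_text("date,PM10\n2020-01-01,3\n")
    with pytest.raises(KeyError):
        read_series(missing, "PM2.5")
    empty = tmp_path / "e.csv"
    empty.write_text("")
    with pytest.raises(ValueError):
        read_series(empty, "PM2.5")


def test_read_frame_all_pollutants(tmp_path):
    path = tmp_path / "f.csv"
    header = "date," + ",".join(POLLUTANTS)
    path.write_text(header + "\n2020-01-01,1,2,3,4,5,6\n2020-01-02,1,2,3,4,5,6\n")
    out = read_frame(path)
    assert set(out) == set(POLLUTANTS)
    assert out["CO"].unit == "mg/m^3" and out["O3"].unit == "ug/m^3"


def test_series_validation():
    dates = pd.date_range("2020-01-01", periods=3, freq="D")
    with pytest.raises(ValueError, match="non-negative"):
        PollutantSeries("PM2.5", dates, [1.0, -2.0, 3.0])
    with pytest.raises(ValueError, match="daily spacing"):
        PollutantSeries("PM2.5", dates[[0, 2, 1]], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="unknown pollutant"):
        PollutantSeries("XX", dates, [1.0, 2.0, 3.0])


def test_impute_missing_interior_and_edges():
    dates = pd.date_range("2020-01-01", periods=5, freq="D")
    s = PollutantSeries("PM2.5", dates, [np.nan, 4.0, np.nan, 8.0, np.nan])
    out = impute_missing(s)
    np.testing.assert_allclose(out.values, [4.0, 4.0, 6.0, 8.0, 8.0])
    assert not out.missing_mask.any()
    with pytest.raises(ValueError):
        impute_missing(PollutantSeries("PM2.5", dates, [np.nan] * 5))


def test_split_train_test(tiny_series):
    train, test = split_train_test(tiny_series, "2020-01-07")
    assert len(train) == 7 and len(test) == 3
    assert train.dates[-1] == pd.Timestamp("2020-01-07")
    with pytest.raises(ValueError):
        split_train_test(tiny_series, "2020-01-10")  # last day: empty test
    with pytest.raises(ValueError):
        split_train_test(tiny_series, "2019-12-01")


def test_make_windows_shapes_and_content():
    w = make_windows(np.arange(10.0), 3)
    assert w.inputs.shape == (7, 3) and len(w) == 7
    np.testing.assert_allclose(w.inputs[0], [0, 1, 2])
    np.testing.assert_allclose(w.targets, np.arange(3.0, 10.0))
    with pytest.raises(ValueError):
        make_windows(np.arange(4.0), 4)
    with pytest.raises(ValueError):
        make_windows(np.arange(4.0), 0)
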