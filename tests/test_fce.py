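import numpy as np
import pandas as pd
import pytest

from aqews import (DEFAULT_LIMITS, HANDBOOK, POLLUTANTS, classify, compose,
                   evaluate_day, evaluate_frame, factor_weights, handbook,
                   membership_matrix, membership_row)

PM25_LIMITS = DEFAULT_LIMITS["PM2.5"].to_numpy()


def test_membership_worked_value():
    # PM2.5 = 55 sits halfway between the level-I and level-II limits
    np.testing.assert_allclose(membership_row(55.0, PM25_LIMITS),
                               [0.5, 0.5, 0.0, 0.0, 0.0])


def test_membership_saturation_and_rows_sum():
    assert membership_row(0.0, PM25_LIMITS)[0] == 1.0
    assert membership_row(1000.0, PM25_LIMITS)[-1] == 1.0
    for x in np.linspace(0.0, 300.0, 61):
        r = membership_row(x, PM25_LIMITS)
        assert np.all(r >= 0.0) and np.all(r <= 1.0)
        if PM25_LIMITS[0] <= x <= PM25_LIMITS[-1]:
            assert r.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        membership_row(-1.0, PM25_LIMITS)
    with pytest.raises(ValueError):
        membership_row(10.0, [1.0, 2.0, 2.0, 3.0, 4.0])


def test_exact_limit_vector_classifies_to_its_level():
    for k, level in enumerate(("I", "II", "III", "IV", "V")):
        x = DEFAULT_LIMITS.iloc[k][list(POLLUTANTS)].to_numpy()
        assert evaluate_day(x).level == level


def test_weights_normalized_and_proportional():
    x = np.array([55.0, 100.0, 60.0, 100.0, 3.0, 130.0])
    w = factor_weights(x)
    assert w.sum() == pytest.approx(1.0)
    means = DEFAULT_LIMITS[list(POLLUTANTS)].mean(axis=0).to_numpy()
    np.testing.assert_allclose(w, (x / means) / (x / means).sum())
    with pytest.raises(ValueError):
        factor_weights(np.zeros(6))


def test_compose_zadeh_min_max():
    W = np.array([0.6, 0.4])
    R = np.array([[1.0, 0.2], [0.3, 1.0]])
    np.testing.assert_allclose(compose(W, R), [0.6, 0.4])


def test_classify_ties_prefer_better_level():
    assert classify([0.3759, 0.3409, 0.0, 0.0, 0.0]) == "I"
    assert classify([0.4009, 0.4009, 0.1, 0.0, 0.0]) == "I"
    assert classify([0.0, 0.2, 0.2, 0.0, 0.0]) == "II"
    with pytest.raises(ValueError):
        classify([0.0] * 5)


def test_handbook_verbatim():
    entry = handbook("I")
    assert entry == HANDBOOK["I"]
    assert handbook("V")["color"] == "purple"
    with pytest.raises(ValueError):
        handbook("VI")


def test_evaluate_day_worked_example():
    # every concentration halfway between its level-I and level-II limits
    x = np.array([55.0, 100.0, 60.0, 100.0, 3.0, 130.0])
    res = evaluate_day(x)
    np.testing.assert_allclose(res.membership[:, :2], 0.5)
    assert res.composite[0] == pytest.approx(res.composite[1])
    assert res.level == "I" and res.category == "excellent"


def test_evaluate_frame_and_custom_limits():
    frame = pd.DataFrame([[10.0, 20.0, 10.0, 5.0, 0.5, 50.0],
                          [200.0, 300.0, 250.0, 600.0, 20.0, 300.0]],
                         columns=list(POLLUTANTS),
                         index=pd.Index(["d1", "d2"], name="date"))
    out = evaluate_frame(frame)
    assert list(out["level"]) == ["I", "IV"]
    assert set(out.columns) >= {"bI", "bV", "level", "category", "color"}
    doubled = DEFAULT_LIMITS * 2.0
    relaxed = evaluate_frame(frame, doubled)
    assert relaxed.loc["d2", "level"] <= out.loc["d2", "level"]
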