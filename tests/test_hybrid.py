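import numpy as np
import pytest

from aqews import (ELMRegressor, HybridForecaster, SynthConfig, ar_extend,
                   generate, make_windows, metrics, rolling_one_step)


@pytest.fixture(scope="module")
def fitted():
    """A small but realistic fit shared by the module's tests."""
    series = generate(SynthConfig(n_days=240, seed=0))["PM2.5"]
    train, test = series.values[:-20], series.values[-20:]
    model = HybridForecaster(ensemble_size=5, woa_iters=10, random_state=0)
    return model.fit(train), train, test


def test_rolling_one_step_uses_observed_history():
    train = np.arange(50.0)
    test = np.arange(50.0, 60.0)
    model = ELMRegressor(n_hidden=30, random_state=0)
    w = make_windows(train, 3)
    model.fit(w.inputs, w.targets)
    preds = rolling_one_step(model, train, test, 3)
    assert preds.shape == (10,)
    # a ramp is near-interpolable: one-step error stays small
    assert np.abs(preds - test).max() < 2.0


def test_ar_extend_length_and_range():
    x = np.sin(np.linspace(0, 12, 200)) + 5.0
    ext = ar_extend(x, 40, order=6)
    assert ext.shape == (240,)
    np.testing.assert_array_equal(ext[:200], x)
    assert ext.min() >= x.min() and ext.max() <= x.max()
    np.testing.assert_array_equal(ar_extend(x, 0), x)
    short = ar_extend(np.array([1.0, 2.0]), 3)
    np.testing.assert_allclose(short[-3:], 2.0)


def test_fit_attributes_and_reconstruction(fitted):
    model, train, _ = fitted
    assert model.n_components_ == len(model.models_) == len(model.components_)
    total = np.sum(model.components_, axis=0)
    np.testing.assert_allclose(total, train, atol=1e-8 * train.std())


def test_predict_redecompose_tracks_actuals(fitted):
    model, train, test = fitted
    result = model.predict(len(test), actuals=test)
    assert result.integrated.shape == (len(test),)
    assert result.per_component.shape == (model.n_components_, len(test))
    np.testing.assert_allclose(result.per_component.sum(axis=0), result.integrated)
    naive = metrics(np.r_[train[-1], test[:-1]], test).rmse
    assert metrics(result.integrated, test).rmse < 2.0 * naive


def test_predict_free_run_stays_bounded(fitted):
    model, train, test = fitted
    result = model.predict(len(test), policy="free_run")
    assert np.all(np.isfinite(result.integrated))
    span = train.max() - train.min()
    assert np.all(np.abs(result.integrated - train.mean()) < 2.0 * span)


def test_predict_reproducible(fitted):
    model, _, test = fitted
    a = model.predict(5, actuals=test)
    b = model.predict(5, actuals=test)
    np.testing.assert_array_equal(a.integrated, b.integrated)


def test_fit_errors():
    model = HybridForecaster()
    with pytest.raises(ValueError, match="missing"):
        model.fit(np.array([1.0, np.nan] * 50))
    with pytest.raises(ValueError, match="too short"):
        model.fit(np.arange(10.0))
    with pytest.raises(ValueError):
        HybridForecaster(window=0)
    with pytest.raises(ValueError):
        HybridForecaster(policy="oracle")


def test_predict_errors(fitted):
    model, _, test = fitted
    with pytest.raises(ValueError):
        model.predict(0)
    with pytest.raises(ValueError, match="shorter"):
        model.predict(len(test) + 1, actuals=test)
    with pytest.raises(RuntimeError):
        HybridForecaster().predict(5)


def test_fallback_on_trend_only_series():
    x = np.linspace(10.0, 60.0, 150)
    model = HybridForecaster(ensemble_size=3, woa_iters=5, random_state=0).fit(x)
    assert model.fallback_ and model.n_components_ == 1
    pred = model.predict(3, actuals=np.array([60.3, 60.6, 60.9]))
    assert np.all(np.isfinite(pred.integrated))


def test_save_load_roundtrip(tmp_path, fitted):
    model, _, test = fitted
    path = tmp_path / "model.json"
    model.save(path)
    loaded = HybridForecaster.load(path)
    a = model.predict(4, actuals=test).integrated
    b = loaded.predict(4, actuals=test).integrated
    np.testing.assert_allclose(a, b, atol=1e-10)
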