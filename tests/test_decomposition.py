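import numpy as np
import pytest

from aqews import IMFSet, SiftConfig, emd, iceemdan, local_mean


def corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def test_emd_reconstruction_exact(rng):
    x = rng.standard_normal(512).cumsum() + np.sin(np.linspace(0, 40, 512))
    result = emd(x)
    np.testing.assert_allclose(result.reconstruct(), x, atol=1e-10 * x.std())
    assert result.n_modes >= 1


def test_iceemdan_reconstruction_exact(rng):
    x = rng.standard_normal(400).cumsum()
    result = iceemdan(x, SiftConfig(ensemble_size=10, seed=3))
    np.testing.assert_allclose(result.reconstruct(), x, atol=1e-10 * x.std())


def test_iceemdan_reproducible(rng):
    x = rng.standard_normal(300)
    a = iceemdan(x, SiftConfig(ensemble_size=5, seed=11))
    b = iceemdan(x, SiftConfig(ensemble_size=5, seed=11))
    assert a.n_modes == b.n_modes
    for ma, mb in zip(a.modes, b.modes):
        np.testing.assert_array_equal(ma, mb)


def test_iceemdan_zero_noise_single_realization_is_emd(rng):
    x = np.sin(np.linspace(0, 30, 400)) + 0.3 * rng.standard_normal(400)
    plain = emd(x)
    degenerate = iceemdan(x, SiftConfig(ensemble_size=1, noise_scale=0.0))
    assert degenerate.n_modes == plain.n_modes
    for ma, mb in zip(degenerate.modes, plain.modes):
        np.testing.assert_allclose(ma, mb, atol=1e-10)


def test_two_tone_separation(two_tone):
    mix, hi, lo = two_tone
    result = emd(mix)
    assert result.n_modes >= 1
    assert abs(corr(result.modes[0], hi)) >= 0.95
    remainder = mix - result.modes[0]
    assert abs(corr(remainder, lo)) >= 0.95


def test_local_mean_of_symmetric_tone_is_small():
    t = np.linspace(0, 1, 500)
    x = np.sin(2 * np.pi * 10 * t)
    m = local_mean(x)
    interior = m[50:-50]  # edges are extrapolated
    assert np.abs(interior).max() < 0.05


def test_monotone_signal_has_no_modes():
    x = np.linspace(0.0, 5.0, 200) ** 2
    result = emd(x)
    assert result.n_modes == 0
    np.testing.assert_allclose(result.residue, x)


def test_constant_and_short_signals():
    result = emd(np.full(50, 3.0))
    assert result.n_modes == 0
    with pytest.raises(ValueError):
        emd(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        emd(np.array([1.0, np.nan, 2.0, 3.0]))


def test_max_imfs_cap(rng):
    x = rng.standard_normal(600)
    capped = emd(x, SiftConfig(max_imfs=2))
    assert capped.n_modes <= 2
    np.testing.assert_allclose(capped.reconstruct(), x, atol=1e-10)


def test_imfset_frame_roundtrip(rng):
    x = rng.standard_normal(256)
    result = emd(x)
    back = IMFSet.from_frame(result.to_frame())
    assert back.n_modes == result.n_modes
    np.testing.assert_allclose(back.reconstruct(), x, atol=1e-12)


def test_sift_config_validation():
    with pytest.raises(ValueError):
        SiftConfig(max_imfs=0)
    with pytest.raises(ValueError):
        SiftConfig(sd_threshold=0.0)
    with pytest.raises(ValueError):
        SiftConfig(noise_scale=-0.1)
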