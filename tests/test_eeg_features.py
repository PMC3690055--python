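"""EEG normalization, sliding epochs, and the 25 per-epoch features."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eegcam.eeg import (BandSet, DegenerateEpochError, EEGStream, Epoch,
                        FREQ_FEATURE_NAMES, TIME_FEATURE_NAMES,
                        feature_matrix, frequency_features, normalize_epoch,
                        sliding_epochs, time_features)


# ---------------------------------------------------------------------------
# Independent oracles (naive re-implementations of the printed definitions)
# ---------------------------------------------------------------------------

def oracle_normalize(raw):
    x = np.asarray(raw, float)
    x = x - sum(x) / len(x)
    lo, hi = min(x), max(x)
    return [(-1.0 + 2.0 * (v - lo) / (hi - lo)) for v in x]


def oracle_dft_band_means(x, bands, rate):
    """O(n^2) DFT magnitudes averaged over inclusive integer bins."""
    n = len(x)
    nbins = n // 2 + 1
    mags = []
    for k in range(nbins):
        re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        mags.append(np.hypot(re, im))
    out = []
    for lo, hi in bands:
        sel = [mags[k] for k in range(nbins)
               if lo - 1e-9 <= k * rate / n <= hi + 1e-9]
        out.append(sum(sel) / len(sel))
    return np.array(out)


def oracle_zero_crossings(x):
    return sum(1 for a, b in zip(x[:-1], x[1:]) if a * b < 0)


def oracle_time_features(x):
    x = np.asarray(x, float)
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    d1 = [x[i + 1] - x[i] for i in range(n - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(n - 2)]

    def var(v):
        m = sum(v) / len(v)
        return sum((u - m) ** 2 for u in v) / len(v)

    vd1, vd2 = var(d1), var(d2)
    mob = np.sqrt(vd1 / m2)
    mob_d1 = np.sqrt(vd2 / vd1) if vd1 > 0 else 0.0
    return {
        "kurtosis": m4 / m2 ** 2,
        "skewness": m3 / m2 ** 1.5,
        "rms_amplitude": max(abs(v) for v in x) / np.sqrt(2),
        "zero_crossings": oracle_zero_crossings(x),
        "minimum": min(x),
        "maximum": max(x),
        "var_d1": vd1,
        "var_d2": vd2,
        "zc_d1": oracle_zero_crossings(d1),
        "zc_d2": oracle_zero_crossings(d2),
        "activity": m2,
        "mobility": mob,
        "complexity": mob_d1 / mob if mob > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    ([1, 3, 5], [-1, 0, 1]),
    ([0, 1, 3], [-1, -1 / 3, 1]),
])
def test_normalize_small_examples(raw, expected):
    ep = normalize_epoch(np.array(raw, float), end_index=2)
    np.testing.assert_allclose(ep.values, expected, atol=1e-15)


def test_normalize_matches_independent_two_step_transform(rng):
    raw = rng.normal(2.0, 5.0, 128)
    ep = normalize_epoch(raw)
    np.testing.assert_allclose(ep.values, oracle_normalize(raw), atol=1e-12)
    assert ep.values.min() == -1.0
    assert ep.values.max() == 1.0


def test_normalize_constant_segment_errors_with_location():
    with pytest.raises(DegenerateEpochError, match="311"):
        normalize_epoch(np.full(128, 3.3), end_index=311)


@settings(max_examples=50, derandomize=True)
@given(arrays(np.float64, 128,
              elements=st.floats(-1e3, 1e3, allow_nan=False),
              unique=True))
def test_normalize_bounds_property(raw):
    ep = normalize_epoch(raw)
    assert np.all(ep.values >= -1.0) and np.all(ep.values <= 1.0)
    assert ep.values.min() == -1.0 and ep.values.max() == 1.0


# ---------------------------------------------------------------------------
# Sliding epochs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(128, 1), (130, 3), (1000, 873)])
def test_sliding_epoch_counts(n, expected, rng):
    stream = EEGStream(rng.normal(size=n))
    eps = list(sliding_epochs(stream))
    assert len(eps) == expected
    assert eps[-1].end_index == n - 1
    if n == 130:
        assert [e.end_index for e in eps] == [127, 128, 129]


def test_sliding_short_stream_warns_and_yields_nothing(caplog):
    stream = EEGStream(np.arange(100.0), trial_id="short")
    with caplog.at_level(logging.WARNING):
        assert list(sliding_epochs(stream)) == []
    assert any("shorter than window" in r.message for r in caplog.records)


def test_sliding_flags_constant_windows_instead_of_dropping(rng):
    x = rng.normal(size=300)
    x[100:280] = 5.0                      # long constant run
    eps = list(sliding_epochs(EEGStream(x)))
    assert len(eps) == 300 - 127          # count conserved
    flagged = [e for e in eps if not e.valid]
    assert flagged and all(len(e) == 128 for e in flagged)


# ---------------------------------------------------------------------------
# Frequency features
# ---------------------------------------------------------------------------

def test_zero_epoch_gives_zero_band_features():
    ep = Epoch(values=np.zeros(128), end_index=127, end_time=127 / 128)
    np.testing.assert_array_equal(frequency_features(ep), np.zeros(12))


def test_pure_sine_localizes_to_containing_bands():
    t = np.arange(128) / 128
    ep = Epoch(values=np.sin(2 * np.pi * 10 * t), end_index=127, end_time=1.0)
    feats = frequency_features(ep)
    containing = [i for i, (lo, hi) in enumerate(BandSet().bands)
                  if lo <= 10 <= hi]
    assert set(containing) == {0, 5, 6, 7}
    inside = sum(feats[i] for i in containing)
    assert inside / feats.sum() >= 0.99


def test_band_features_match_naive_dft_oracle(rng):
    ep = normalize_epoch(rng.normal(size=128))
    feats = frequency_features(ep)
    expected = oracle_dft_band_means(ep.values, BandSet().bands, 128.0)
    np.testing.assert_allclose(feats, expected, rtol=1e-9)


def test_band_beyond_nyquist_is_configuration_error():
    with pytest.raises(ValueError, match="Nyquist"):
        frequency_features(np.zeros(128), BandSet(bands=((10, 70),)), rate=128.0)


# ---------------------------------------------------------------------------
# Time features
# ---------------------------------------------------------------------------

def test_alternating_signal_statistics():
    x = np.tile([1.0, -1.0], 64)
    f = time_features(x)
    assert f["zero_crossings"] == 127
    assert f["minimum"] == -1.0 and f["maximum"] == 1.0
    assert f["rms_amplitude"] == pytest.approx(1 / np.sqrt(2))


def test_linear_ramp_has_constant_first_difference():
    f = time_features(np.linspace(-1, 1, 128))
    assert f["var_d1"] == pytest.approx(0.0, abs=1e-30)
    assert f["zc_d1"] == 0


def test_all_time_features_match_brute_force_oracle(rng):
    x = normalize_epoch(rng.normal(size=128)).values
    f = time_features(x)
    expected = oracle_time_features(x)
    assert set(f) == set(TIME_FEATURE_NAMES)
    for name in TIME_FEATURE_NAMES:
        assert f[name] == pytest.approx(expected[name], rel=1e-9), name


def test_zero_variance_epoch_is_degenerate():
    with pytest.raises(DegenerateEpochError):
        time_features(np.ones(128))


def test_scale_behavior_of_features(rng):
    x = rng.normal(size=128)
    c = 3.7
    f1, f2 = time_features(x), time_features(c * x)
    for name in ("kurtosis", "skewness", "mobility", "complexity"):
        assert f2[name] == pytest.approx(f1[name], rel=1e-9)
    assert f2["activity"] == pytest.approx(c ** 2 * f1["activity"], rel=1e-9)
    np.testing.assert_allclose(frequency_features(c * x),
                               c * frequency_features(x), rtol=1e-9)


# ---------------------------------------------------------------------------
# Batched path equals the per-epoch path
# ---------------------------------------------------------------------------

def test_feature_matrix_equals_per_epoch_functions(rng):
    stream = EEGStream(rng.normal(size=400))
    ends = np.array([127, 200, 399])
    freq, timef, valid = feature_matrix(stream, ends)
    assert valid.all()
    for row, end in enumerate(ends):
        ep = normalize_epoch(stream.samples[end - 127:end + 1], end_index=end)
        np.testing.assert_allclose(freq[row], frequency_features(ep), rtol=1e-12)
        tf = time_features(ep)
        np.testing.assert_allclose(
            timef[row], [tf[n] for n in TIME_FEATURE_NAMES], rtol=1e-12)
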