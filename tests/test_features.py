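"""Per-window feature functions against direct-from-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from semgfeat import (
    HistConfig,
    MdwtConfig,
    feat_hist,
    feat_iav,
    feat_mav,
    feat_mavs,
    feat_mdwt,
    feat_rms,
    feat_ssc,
    feat_td,
    feat_wl,
    feat_zc,
)

import oracles


def random_windows(n, t, c, seed):
    rng = np.random.default_rng(seed)
    return rng.normal(scale=rng.uniform(0.1, 2.0, size=(n, 1, 1)), size=(n, t, c))


# --- enumerated closed-form cases -----------------------------------------

@pytest.mark.parametrize(
    "func, signal, expected",
    [
        (feat_iav, [1, -2, 3], 6.0),
        (feat_iav, [0, 0, 0], 0.0),
        (feat_mav, [1, -2, 3], 2.0),
        (feat_mav, [5.0, 5.0], 5.0),
        (feat_rms, [7.0, 7.0, 7.0], 7.0),
        (feat_rms, [3.0, 4.0], np.sqrt(25 / 2)),
        (feat_wl, [0, 1, 2, 3, 4], 4.0),
        (feat_wl, [1, -1, 1], 4.0),
        (feat_wl, [2.5, 2.5, 2.5], 0.0),
    ],
)
def test_amplitude_features_closed_form(func, signal, expected):
    assert func(np.asarray(signal, dtype=float)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "signal, deadzone, expected",
    [
        ([0, 1, 0, 1], 0.0, 2),  # peak then trough
        ([0, 1, 2, 3], 0.0, 0),  # monotone ramp
        ([0, 1, 2, 3], 5.0, 0),
        ([0, 1, 0, 1], 2.0, 0),  # steps of 1 below the dead zone
    ],
)
def test_slope_sign_change_cases(signal, deadzone, expected):
    assert feat_ssc(np.asarray(signal, dtype=float), deadzone) == expected


@pytest.mark.parametrize(
    "signal, deadzone, expected",
    [
        ([1, -1, 1, -1], 0.0, 3),
        ([1, -1, 1, -1], 3.0, 0),  # |step| = 2 < 3
        ([1, 0, -1], 0.0, 0),  # a zero sample breaks both strict sign tests
    ],
)
def test_zero_crossing_cases(signal, deadzone, expected):
    assert feat_zc(np.asarray(signal, dtype=float), deadzone) == expected


def test_ssc_rejects_two_sample_window():
    with pytest.raises(ValueError):
        feat_ssc(np.array([1.0, 2.0]))


def test_rms_of_full_period_sinusoid():
    t = np.arange(1000)
    for amplitude, periods in [(1.0, 4), (2.5, 10)]:
        x = amplitude * np.sin(2 * np.pi * periods * t / len(t))
        assert feat_rms(x) == pytest.approx(amplitude / np.sqrt(2), rel=1e-9)


def test_mavs_direct_difference_and_final_row_rule():
    mav_rows = np.array([[2.0], [5.0], [5.0]])
    np.testing.assert_allclose(feat_mavs(mav_rows), [[3.0], [0.0], [0.0]])
    np.testing.assert_allclose(feat_mavs(np.array([[4.0, 1.0]])), [[0.0, 0.0]])


def test_td_constant_window():
    win = np.full((50, 2), -3.0)
    td = feat_td([win], deadzone=0.0)
    np.testing.assert_allclose(td, [[3.0, 0, 0, 0, 0, 3.0, 0, 0, 0, 0]])


# --- histogram -------------------------------------------------------------

def test_hist_counts_sum_to_window_length(rng):
    win = rng.normal(size=(64, 3))
    h = feat_hist(win)
    assert h.shape == (60,)
    np.testing.assert_array_equal(h.reshape(3, 20).sum(axis=1), [64, 64, 64])


def test_hist_zero_sample_lands_in_bin_ten():
    win = np.zeros((16, 1))
    h = feat_hist(win, sigma_per_channel=np.array([1.0]))
    expected = np.zeros(20)
    expected[10] = 16  # 0 lies in the 11th of 20 even bins over [-3, 3]
    np.testing.assert_array_equal(h, expected)


def test_hist_flat_channel_goes_to_central_bin():
    win = np.full((30, 1), 2.0)
    h = feat_hist(win)  # window-local sigma is 0
    assert h[20 // 2] == 30 and h.sum() == 30


def test_hist_matches_direct_binning_oracle():
    rng = np.random.default_rng(7)
    sigma = 1.7
    x = rng.uniform(-3 * sigma, 3 * sigma, size=1000)
    h = feat_hist(x[:, None], sigma_per_channel=np.array([sigma]))
    np.testing.assert_array_equal(h, oracles.hist(x, 20, 3.0, sigma))


def test_hist_clips_out_of_range_samples():
    win = np.array([[-100.0], [100.0], [0.0]])
    h = feat_hist(win, sigma_per_channel=np.array([1.0]))
    assert h[0] == 1 and h[-1] == 1 and h.sum() == 3


# --- marginal DWT ----------------------------------------------------------

def test_mdwt_zero_window_and_homogeneity():
    assert np.all(feat_mdwt(np.zeros((128, 2))) == 0)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(128, 2))
    np.testing.assert_allclose(feat_mdwt(-2.5 * x), 2.5 * feat_mdwt(x), rtol=1e-12)


def test_mdwt_matches_filter_bank_oracle():
    rng = np.random.default_rng(42)
    x = rng.normal(size=256)
    got = feat_mdwt(x, MdwtConfig("db7", 3))
    np.testing.assert_allclose(got, oracles.mdwt(x, "db7", 3), rtol=1e-8)


def test_mdwt_window_too_short_names_max_depth():
    with pytest.raises(ValueError, match="at most"):
        feat_mdwt(np.zeros((20, 1)), MdwtConfig("db7", 3))


# --- oracle sweep over seeded random windows -------------------------------

def test_every_feature_matches_naive_loop_oracle():
    """100 seeded random windows: vectorized implementation == per-formula
    loop; exact for integer counts, <=1e-9 relative for reals."""
    wins = random_windows(100, 128, 2, seed=123)
    deadzone = 0.3
    mav_rows = np.stack([feat_mav(w) for w in wins])
    td = feat_td(list(wins), deadzone)
    mavs_oracle = oracles.mavs([[oracles.mav(w[:, c]) for c in range(2)] for w in wins])
    np.testing.assert_allclose(feat_mavs(mav_rows), mavs_oracle, rtol=1e-9)
    for i, w in enumerate(wins):
        for c in range(2):
            x = w[:, c]
            assert feat_iav(w)[c] == pytest.approx(oracles.iav(x), rel=1e-9)
            assert feat_mav(w)[c] == pytest.approx(oracles.mav(x), rel=1e-9)
            assert feat_rms(w)[c] == pytest.approx(oracles.rms(x), rel=1e-9)
            assert feat_wl(w)[c] == pytest.approx(oracles.wl(x), rel=1e-9)
            assert feat_ssc(w, deadzone)[c] == oracles.ssc(x, deadzone)
            assert feat_zc(w, deadzone)[c] == oracles.zc(x, deadzone)
            sigma = float(np.std(x))
            np.testing.assert_array_equal(
                feat_hist(w)[c * 20 : (c + 1) * 20], oracles.hist(x, 20, 3.0, sigma)
            )
            np.testing.assert_allclose(
                feat_mdwt(w)[c * 3 : (c + 1) * 3],
                oracles.mdwt(x, "db7", 3),
                rtol=1e-8,
            )
            block = td[i, c * 5 : (c + 1) * 5]
            expected = [
                oracles.mav(x),
                mavs_oracle[i, c],
                oracles.zc(x, deadzone),
                oracles.ssc(x, deadzone),
                oracles.wl(x),
            ]
            np.testing.assert_allclose(block, expected, rtol=1e-9, atol=1e-12)


# --- structural properties -------------------------------------------------

window_strategy = hnp.arrays(
    np.float64,
    shape=st.tuples(st.integers(4, 40), st.integers(1, 3)),
    elements=st.floats(-10, 10, allow_nan=False, allow_subnormal=False),
)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(win=window_strategy)
def test_iav_is_t_times_mav(win):
    np.testing.assert_allclose(feat_iav(win), win.shape[0] * feat_mav(win), rtol=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(win=window_strategy, scale=st.floats(0.01, 100))
def test_scale_invariance_and_homogeneity(win, scale):
    """Counts are invariant and amplitude features homogeneous under
    positive scaling (dead zone 0)."""
    np.testing.assert_array_equal(feat_zc(win * scale), feat_zc(win))
    if win.shape[0] >= 3:
        np.testing.assert_array_equal(feat_ssc(win * scale), feat_ssc(win))
    for f in (feat_iav, feat_mav, feat_rms, feat_wl):
        np.testing.assert_allclose(f(win * scale), scale * f(win), rtol=1e-9, atol=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(win=window_strategy)
def test_time_reversal_invariance(win):
    rev = win[::-1].copy()
    for f in (feat_iav, feat_mav, feat_rms, feat_wl):
        np.testing.assert_allclose(f(rev), f(win), rtol=1e-12)
    np.testing.assert_array_equal(feat_hist(rev), feat_hist(win))
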