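"""Sliding-window mechanics, smoothing, regime summaries, trend labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fisherinfo import (FIEntry, FISeries, InputError, SizeOfState,
                        TighteningSpec, TimeSeriesMatrix, WindowSpec,
                        block_average, classify_trend, compute_fi_series,
                        regime_summary)


def make_series(values, labels=None):
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    labels = labels if labels is not None else np.arange(1, len(vals) + 1)
    names = [f"y{i+1}" for i in range(vals.shape[1])]
    return TimeSeriesMatrix(labels, names, vals)


def fi_series_from(values, labels=None):
    return FISeries([
        FIEntry(lab, float(v), 1, "strict") for lab, v in
        zip(labels or range(1, len(values) + 1), values)])


class TestWindowSpec:
    def test_increment_above_width_rejected(self):
        with pytest.raises(InputError, match="exceeds"):
            WindowSpec(8, 9)

    def test_equal_width_and_increment_warns(self):
        with pytest.warns(UserWarning, match="overlap"):
            WindowSpec(8, 8)

    def test_small_window_warns(self):
        with pytest.warns(UserWarning, match="recommended"):
            WindowSpec(4, 1)


class TestComputeFISeries:
    def test_yearly_window_labels_and_count(self):
        """136 yearly steps (1880..2015) with w=40, h=1: the first window
        covers 1880-1919 and is attributed to 1919; 97 entries follow."""
        ts = make_series(np.zeros(136), labels=np.arange(1880, 2016))
        series = compute_fi_series(ts, SizeOfState([1.0]), WindowSpec(40, 1))
        assert series[0].time_label == 1919
        assert len(series) == 97
        assert series[-1].time_label == 2015

    def test_window_equal_to_series_gives_one_entry(self):
        ts = make_series(np.arange(8.0))
        series = compute_fi_series(ts, SizeOfState([10.0]), WindowSpec(8, 1))
        assert len(series) == 1
        assert series[0].time_label == 8

    def test_series_shorter_than_window(self):
        ts = make_series(np.zeros(5))
        with pytest.raises(InputError, match="at least the window width"):
            compute_fi_series(ts, SizeOfState([1.0]), WindowSpec(8, 1))

    def test_straddling_window_closed_form(self):
        """Noiseless two-regime data: windows inside a regime give FI = 8;
        a window with fraction f of its points in the first regime gives
        FI = 4[f + (sqrt(f) - sqrt(1-f))^2 + (1-f)] = 8 - 8 sqrt(f(1-f))."""
        w = 8
        vals = np.concatenate([np.zeros(20), np.full(20, 100.0)])
        ts = make_series(vals)
        series = compute_fi_series(ts, SizeOfState([1.0]), WindowSpec(w, 1))
        for e in series:
            t = int(e.time_label)  # window covers steps t-w+1 .. t
            n_a = max(0, min(20, t) - (t - w))  # points from regime A
            f = n_a / w
            if f in (0.0, 1.0):
                expected = 8.0
            else:
                expected = 8 - 8 * np.sqrt(f * (1 - f))
            assert e.fi == pytest.approx(expected, rel=1e-12), t

    def test_averaged_mode_means_over_level_set(self, table1_points,
                                                table1_deltas):
        """With the walkthrough window, averaged mode means the FI at
        TL = 1.0 (four states) and TL = 0.5 (two states)."""
        ts = make_series(table1_points)
        sos = SizeOfState(table1_deltas)
        strict = compute_fi_series(ts, sos, WindowSpec(8, 1),
                                   TighteningSpec("strict"))
        avg = compute_fi_series(ts, sos, WindowSpec(8, 1),
                                TighteningSpec("averaged"))
        # FI at tl=0.5: p = (0.75, 0.25)
        q = np.sqrt([0.75, 0.25])
        fi_half = 4 * (q[0] ** 2 + (q[0] - q[1]) ** 2 + q[1] ** 2)
        assert avg[0].fi == pytest.approx((strict[0].fi + fi_half) / 2,
                                          rel=1e-12)
        assert avg[0].tl_levels == (1.0, 0.5)
        assert avg[0].n_states == 4  # strict-mode count is what is reported

    def test_increment_strides_windows(self):
        ts = make_series(np.zeros(20))
        series = compute_fi_series(ts, SizeOfState([1.0]), WindowSpec(8, 4))
        assert [e.time_label for e in series] == [8, 12, 16, 20]


class TestBlockAverage:
    def test_identity_at_block_one(self):
        s = fi_series_from([2.0, 4.0, 6.0])
        out = block_average(s, 1)
        np.testing.assert_allclose(out.fi_values, s.fi_values)

    def test_full_block_mean(self):
        out = block_average(fi_series_from([2.0, 4.0, 6.0]), 3)
        np.testing.assert_allclose(out.fi_values, [4.0, 4.0, 4.0])

    def test_trailing_partial_block(self):
        out = block_average(fi_series_from([1.0, 2.0, 3.0, 4.0, 5.0]), 2)
        np.testing.assert_allclose(out.fi_values, [1.5, 1.5, 3.5, 3.5, 5.0])

    def test_labels_preserved_and_mean_preserving(self):
        s = fi_series_from([1.0, 2.0, 3.0, 4.0], labels=[10, 11, 12, 13])
        out = block_average(s, 2)
        assert list(out.time_labels) == [10, 11, 12, 13]
        assert out.fi_values[:2].mean() == s.fi_values[:2].mean()

    def test_bad_block(self):
        with pytest.raises(InputError):
            block_average(fi_series_from([1.0]), 0)


class TestRegimeSummary:
    def test_constant_series(self):
        s = regime_summary(fi_series_from([5.0] * 4), (1, 4))
        assert s.mu_fi == 5.0 and s.sigma_fi == 0.0 and s.n == 4

    def test_two_values(self):
        s = regime_summary(fi_series_from([4.0, 6.0]), (1, 2))
        assert s.mu_fi == pytest.approx(5.0)
        assert s.sigma_fi == pytest.approx(np.sqrt(2.0))

    def test_single_entry_sigma_zero(self):
        s = regime_summary(fi_series_from([4.0, 6.0]), (2, 2))
        assert s.n == 1 and s.sigma_fi == 0.0

    def test_empty_period_rejected(self):
        with pytest.raises(InputError, match="no FI entries"):
            regime_summary(fi_series_from([4.0, 6.0]), (10, 20))


class TestClassifyTrend:
    def test_constant_is_stable_everywhere(self):
        labels = classify_trend(fi_series_from([5.0] * 10), span=5)
        assert labels == ["stable"] * 10

    def test_declining_ramp(self):
        vals = 8.0 - 0.5 * np.arange(10)
        labels = classify_trend(fi_series_from(vals), slope_tolerance=0.1,
                                drop_threshold=10.0, span=5)
        assert labels[-1] == "declining"
        assert all(lab == "declining" for lab in labels[2:])

    def test_increasing_ramp(self):
        vals = 1.0 + 0.5 * np.arange(10)
        labels = classify_trend(fi_series_from(vals), slope_tolerance=0.1,
                                drop_threshold=10.0, span=5)
        assert labels[-1] == "increasing"

    def test_sharp_drop_takes_precedence(self):
        vals = [6.0, 6.0, 6.0, 6.0, 2.0, 2.0]
        labels = classify_trend(fi_series_from(vals), slope_tolerance=0.1,
                                drop_threshold=2.0, span=4)
        assert labels[4] == "sharp_drop"

    def test_span_longer_than_series(self):
        with pytest.raises(InputError, match="span"):
            classify_trend(fi_series_from([1.0, 2.0]), span=5)


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(shift=st.floats(-100, 100),
           seed=st.integers(0, 2**16))
    def test_translation_invariance(self, shift, seed):
        """Adding a constant to every variable leaves the FI series
        unchanged: binning uses differences only."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(20, 2))
        sos = SizeOfState([0.5, 0.5])
        win = WindowSpec(8, 1)
        base = compute_fi_series(make_series(vals), sos, win)
        moved = compute_fi_series(make_series(vals + shift), sos, win)
        np.testing.assert_allclose(moved.fi_values, base.fi_values)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 2**16))
    def test_joint_scaling_invariance(self, scale, seed):
        """Scaling all variables AND deltas by the same c > 0 leaves the FI
        series unchanged."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(20, 2))
        win = WindowSpec(8, 1)
        base = compute_fi_series(make_series(vals),
                                 SizeOfState([0.5, 0.5]), win)
        scaled = compute_fi_series(make_series(vals * scale),
                                   SizeOfState([0.5 * scale, 0.5 * scale]),
                                   win)
        np.testing.assert_allclose(scaled.fi_values, base.fi_values,
                                   rtol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(T=st.integers(8, 60), w=st.integers(8, 60), h=st.integers(1, 60))
    def test_entry_count_formula(self, T, w, h):
        """floor((T - w)/h) + 1 entries for any valid (T, w, h)."""
        if w > T or h > w:
            return
        ts = make_series(np.zeros(T))
        series = compute_fi_series(ts, SizeOfState([1.0]), WindowSpec(w, h))
        assert len(series) == (T - w) // h + 1
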