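"""NPSD, recurrence/LVM and the KS screen against brute-force oracles."""

import numpy as np
import pytest


from osaprog.errors import InsufficientDataError, OsaprogError
from osaprog.hrv_features import (FeatureSeries, RecurrenceParams,
                                  compute_npsd, extract_feature_series,
                                  ks_feature_screen, longest_vertical_line,
                                  recurrence_matrix)
from osaprog.io_formats import RRSeries


def _tone_window(freq, amp=100.0, dur=300.0, mean=1000.0, offset=0.0, rng=None):
    t = np.arange(0.0, dur, 1.0)
    rr = mean + offset + amp * np.sin(2 * np.pi * freq * t)
    if rng is not None:
        rr = rr + rng.normal(0, 5, len(t))
    return np.append(t, dur), rr


class TestNpsd:
    def test_in_band_tone_near_one(self):
        assert compute_npsd(_tone_window(0.08)) >= 0.95

    def test_out_of_band_tone_near_zero(self):
        assert compute_npsd(_tone_window(0.30)) <= 0.05

    def test_white_noise_matches_bandwidth_ratio(self):
        """Flat spectrum ⇒ NPSD ≈ band width / total width ≈ 0.161."""
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 300.0, 0.25)
            rr = 1000 + rng.normal(0, 50, len(t))
            vals.append(compute_npsd((np.append(t, 300.0), rr)))
        expected = (0.12 - 0.04) / (0.5 - 0.003)
        assert abs(np.mean(vals) - expected) < 0.03

    def test_invariant_to_scaling_and_offset(self):
        bt, rr = _tone_window(0.08, rng=np.random.default_rng(1))
        base = compute_npsd((bt, rr))
        scaled = compute_npsd((bt, 3.0 * rr))
        shifted = compute_npsd((bt, rr + 250.0))
        assert base == pytest.approx(scaled, abs=1e-9)
        assert base == pytest.approx(shifted, abs=1e-9)

    def test_too_few_beats_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(InsufficientDataError):
            compute_npsd((t, np.full(4, 1000.0)))

    def test_constant_signal_warns_and_returns_zero(self):
        t = np.arange(100.0)
        with pytest.warns(UserWarning):
            assert compute_npsd((t, np.full(99, 1000.0))) == 0.0


class TestRecurrenceMatrix:
    def test_constant_signal_fixed_epsilon_all_ones(self):
        params = RecurrenceParams(threshold_mode="fixed_epsilon",
                                  epsilon_or_rate=0.5, exclude_loi=False)
        R = recurrence_matrix(np.zeros(30), params)
        assert R.all()

    def test_rate_mode_hits_requested_rate(self, rng):
        params = RecurrenceParams(epsilon_or_rate=0.10)
        R = recurrence_matrix(rng.normal(size=200), params)
        off = ~np.eye(len(R), dtype=bool)
        assert abs(R[off].mean() - 0.10) < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_thresholding(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        params = RecurrenceParams(embed_dim=3, delay=2,
                                  threshold_mode="fixed_epsilon",
                                  epsilon_or_rate=1.0, exclude_loi=True)
        R = recurrence_matrix(x, params)
        n = len(x) - 2 * 2
        emb = np.column_stack([x[:n], x[2:n + 2], x[4:n + 4]])
        expected = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                if i != j and np.linalg.norm(emb[i] - emb[j]) <= 1.0:
                    expected[i, j] = 1
        np.testing.assert_array_equal(R, expected)


class TestLongestVerticalLine:
    def test_planted_run(self):
        R = np.zeros((20, 20), dtype=int)
        R[5:12, 3] = 1
        assert longest_vertical_line(R, exclude_loi=False) == 7

    def test_identity_with_loi_excluded_is_zero(self):
        assert longest_vertical_line(np.eye(10, dtype=int), exclude_loi=True) == 0

    def test_runs_below_min_line_ignored(self):
        R = np.zeros((5, 5), dtype=int)
        R[2, 4] = 1  # isolated point: run of 1 < min_line=2
        assert longest_vertical_line(R, min_line=2, exclude_loi=False) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_column_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            R = (rng.random((30, 30)) < 0.3).astype(int)
            got = longest_vertical_line(R, min_line=2, exclude_loi=True)
            assert got == _column_scan_oracle(R, 2, True)


def _column_scan_oracle(R, min_line, exclude_loi):
    R = R.copy()
    if exclude_loi:
        np.fill_diagonal(R, 0)
    best = 0
    for col in range(R.shape[1]):
        run = 0
        for v in R[:, col]:
            run = run + 1 if v else 0
            best = max(best, run)
    return best if best >= min_line else 0


class TestExtractFeatures:
    def test_four_minutes_rejected(self):
        t = np.arange(0.0, 240.0, 0.8)
        s = RRSeries(t, np.diff(t) * 1000.0)
        with pytest.raises(InsufficientDataError):
            extract_feature_series(s)

    def test_silent_minute_is_skipped_not_fatal(self):
        # remove all beats of minute 2; other minutes survive
        t = np.arange(0.0, 360.0, 0.8)
        t = t[(t < 120.0) | (t >= 180.0)]
        s = RRSeries(t, np.diff(t) * 1000.0)
        f = extract_feature_series(s)
        assert 2 not in f.minutes
        assert {0, 1, 3, 4} <= set(f.minutes)

    def test_deterministic(self, series60):
        a = extract_feature_series(series60)
        b = extract_feature_series(series60)
        np.testing.assert_array_equal(a.npsd, b.npsd)
        np.testing.assert_array_equal(a.lvm, b.lvm)


class TestKsScreen:
    def test_identical_samples_not_selected(self):
        x = np.arange(50.0)
        selected, details = ks_feature_screen({"f": (x, x.copy())})
        assert selected == []
        assert details["f"]["statistic"] == 0.0

    def test_shifted_gaussians_selected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        selected, details = ks_feature_screen({"f": (a, b)})
        assert selected == ["f"]
        # statistic equals the brute-force ECDF sup-distance
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert details["f"]["statistic"] == pytest.approx(
            np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            ks_feature_screen({"f": (np.array([]), np.arange(5.0))})


def test_feature_series_validates_alignment():
    with pytest.raises(OsaprogError):
        FeatureSeries(np.arange(3), np.zeros(3), np.zeros(2))
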