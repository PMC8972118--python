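"""ENMO, nonwear scoring and pre-beep summaries."""

import numpy as np
import pytest

import emanet as en
from emanet.actigraphy import EnmoSeries, NonwearScores, RawAccelSignal


def make_signal(x, y, z, rate=10.0):
    n = len(x)
    t = np.arange(n) / rate
    return RawAccelSignal(t, np.asarray(x, float), np.asarray(y, float), np.asarray(z, float), rate)


class TestComputeEnmo:
    @pytest.mark.parametrize(
        "sample,expected",
        [
            ((600.0, 800.0, 0.0), 0.0),  # 3-4-5 triple: norm exactly 1 g
            ((300.0, 400.0, 1200.0), 300.0),  # 3-4-12 triple: norm 1300 mg
            ((0.0, 0.0, 500.0), 0.0),  # -500 truncated to zero
        ],
    )
    def test_known_triples(self, sample, expected):
        sig = make_signal([sample[0]] * 10, [sample[1]] * 10, [sample[2]] * 10)
        series = en.compute_enmo(sig, epoch_length=1.0)
        assert series.enmo == pytest.approx(expected, abs=1e-12)

    def test_truncation_can_be_disabled(self):
        sig = make_signal([0.0], [0.0], [500.0])
        series = en.compute_enmo(sig, epoch_length=1.0, truncate=False)
        assert series.enmo[0] == pytest.approx(-500.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(50, 400))
            a = rng.normal(0, 400, size=(n, 3))
            sig = make_signal(a[:, 0], a[:, 1], a[:, 2])
            series = en.compute_enmo(sig, epoch_length=2.0)
            # independent per-sample oracle: explicit loop, then epoch means
            per_sample = []
            for i in range(n):
                v = (a[i, 0] ** 2 + a[i, 1] ** 2 + a[i, 2] ** 2) ** 0.5 - 1000.0
                per_sample.append(max(v, 0.0))
            expected = []
            for e in range(int(np.ceil(n / 20))):
                expected.append(np.mean(per_sample[e * 20 : (e + 1) * 20]))
            assert np.allclose(series.enmo, expected, atol=1e-9)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            en.compute_enmo(make_signal([], [], []))
        with pytest.raises(ValueError):
            en.compute_enmo(make_signal([np.nan], [0.0], [0.0]))


class TestScoreNonwear:
    def test_constant_signal_scores_three(self):
        n = 10 * 3600 * 2  # 2 h at 10 Hz
        sig = make_signal([100.0] * n, [200.0] * n, [970.0] * n)
        scores = en.score_nonwear(sig)
        assert np.all(scores.score == 3)

    def test_one_still_axis_scores_one(self):
        rng = np.random.default_rng(0)
        n = 10 * 3600 * 2
        sig = make_signal(
            np.full(n, 500.0),
            rng.normal(0, 200, n),
            rng.normal(0, 200, n),
        )
        scores = en.score_nonwear(sig)
        assert np.all(scores.score == 1)

    def test_high_variance_noise_scores_zero(self):
        rng = np.random.default_rng(1)
        n = 10 * 3600 * 2
        a = rng.normal(0, 130.0, size=(n, 3))  # std 10x the 13 mg threshold
        sig = make_signal(a[:, 0], a[:, 1], a[:, 2])
        scores = en.score_nonwear(sig)
        assert np.all(scores.score == 0)

    def test_window_longer_than_signal_rejected(self):
        sig = make_signal(*np.zeros((3, 100)))
        with pytest.raises(ValueError):
            en.score_nonwear(sig, window_minutes=60.0)


class TestSummarizePrebeep:
    def _flat_enmo(self, value, hours=3.0, epoch=5.0):
        n = int(hours * 3600 / epoch)
        return EnmoSeries(np.arange(n) * epoch, np.full(n, float(value)), epoch)

    def test_constant_hour_gives_constant_mean(self):
        acts = en.summarize_prebeep(self._flat_enmo(50.0), None, [7200.0])
        assert acts[0].mean_enmo == pytest.approx(50.0)

    def test_half_zero_half_hundred_gives_fifty(self):
        epoch = 5.0
        # beep at 7200 s: window covers epochs 720-1439; first half 0, second 100
        enmo = np.concatenate([np.zeros(1080), np.full(360, 100.0)])
        series = EnmoSeries(np.arange(1440) * epoch, enmo, epoch)
        acts = en.summarize_prebeep(series, None, [7200.0])
        assert acts[0].mean_enmo == pytest.approx(50.0)

    def test_fully_nonwear_window_is_missing(self):
        nonwear = NonwearScores(np.array([0.0, 3600.0]), np.array([3, 3]), 3600.0)
        acts = en.summarize_prebeep(self._flat_enmo(50.0), nonwear, [7200.0])
        assert acts[0].missing

    def test_score_at_cutoff_is_kept(self):
        nonwear = NonwearScores(np.array([3600.0]), np.array([1]), 3600.0)
        acts = en.summarize_prebeep(self._flat_enmo(50.0), nonwear, [7200.0], score_cutoff=1)
        assert acts[0].mean_enmo == pytest.approx(50.0)

    def test_no_overlapping_signal_is_missing_not_error(self):
        acts = en.summarize_prebeep(self._flat_enmo(50.0, hours=1.0), None, [90000.0])
        assert acts[0].missing

    def test_low_coverage_is_missing(self):
        # only 20 min of epochs inside the hour: below the 50% coverage rule
        series = self._flat_enmo(50.0, hours=1.0)
        acts = en.summarize_prebeep(series, None, [3600.0 + 40 * 60.0])
        assert acts[0].missing

    def test_epoch_refinement_invariance_on_piecewise_constant(self):
        # piecewise-constant signal: 1 s and 10 s epochs give identical means
        rng = np.random.default_rng(3)
        segments = rng.uniform(0, 80, size=6)
        sig_vals = np.repeat(segments, 6000)  # 6 x 600 s at 10 Hz
        n = len(sig_vals)
        # build a signal whose norm-1000 equals sig_vals exactly: z = 1000 + v
        sig = make_signal(np.zeros(n), np.zeros(n), 1000.0 + sig_vals)
        beep = [3600.0]
        means = []
        for epoch in (1.0, 10.0):
            series = en.compute_enmo(sig, epoch_length=epoch)
            means.append(en.summarize_prebeep(series, None, beep)[0].mean_enmo)
        assert means[0] == pytest.approx(means[1], abs=1e-9)


class TestNonwearRecovery:
    def test_known_segments_recovered(self):
        """Windows inside true nonwear score high; wear windows score low."""
        hits = misses = false_flags = wear_windows = 0
        for seed in range(10):
            prof = en.AccelProfile(
                duration=6 * 3600.0,
                rest_segments=[(0, 2 * 3600.0), (4 * 3600.0, 5 * 3600.0)],
                activity_segments=[(2 * 3600.0, 3 * 3600.0)],
                nonwear_segments=[(3 * 3600.0, 4 * 3600.0), (5 * 3600.0, 6 * 3600.0)],
            )
            sig = en.generate_raw_accel(prof, seed=seed)
            scores = en.score_nonwear(sig)
            for start, score in zip(scores.window_start, scores.score):
                end = start + scores.window_length
                in_nonwear = any(s <= start and end <= e for s, e, k in prof.all_segments() if k == "nonwear")
                in_wear = any(s <= start and end <= e for s, e, k in prof.all_segments() if k != "nonwear")
                if in_nonwear:
                    hits += score > 1
                    misses += score <= 1
                elif in_wear:
                    wear_windows += 1
                    false_flags += score > 1
        assert hits / (hits + misses) >= 0.95
        assert false_flags / wear_windows <= 0.05
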