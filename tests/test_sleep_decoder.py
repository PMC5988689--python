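"""Sliding-lag decoding, longest-run voting, and the permutation test."""

import numpy as np
import pytest

import tmrdecode as td
from tmrdecode.sleep_decoder import shuffled_ccrs
from tmrdecode.synth import class_templates, tone_erp


def longest_run_oracle(seq, start):
    """Exhaustive run enumeration: (class, run_len, first_pos) ranking."""
    seq = list(seq)[start:]
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((seq[i], j - i, i))
        i = j
    best = {}
    for cls, length, pos in runs:
        if cls not in best or length > best[cls][0]:
            best[cls] = (length, pos)
    return sorted(((c, l) for c, (l, p) in best.items()),
                  key=lambda cl: (-cl[1], best[cl[0]][1]))


def template_trial(cls, lag, amp=5.0, with_tone=True):
    """A noise-free full epoch holding one wake template at the given lag."""
    data = np.zeros((1, 16, 300))
    data[0, :, 100 + lag:100 + lag + 80] += amp * class_templates()[cls]
    if with_tone:
        data[0, :, 100:180] += 2.0 * tone_erp()
    return data


class TestLagSeries:
    def test_120_labels_per_trial(self, trained_model, sleep_epochs):
        ll, post = td.lag_label_series(trained_model, sleep_epochs)
        assert ll.shape == (sleep_epochs.n_trials, 120)
        assert post.shape[:2] == ll.shape
        assert set(np.unique(ll)) <= {1, 2, 3, 4, 5}

    def test_template_self_match_at_alignment(self, trained_model):
        for cls in (1, 2, 3, 4):
            data = template_trial(cls, lag=0)
            ep = td.EpochSet(data, [cls], epoch_kind="full_1500ms")
            ll, _ = td.lag_label_series(trained_model, ep)
            assert ll[0, 0] == cls

    def test_latency_shift_shifts_labels_by_20_lags(self, trained_model):
        """A 100 ms latency shifts the lag-label series by 20 grid steps."""
        for cls in (2, 3):
            a = td.EpochSet(template_trial(cls, 0, with_tone=False), [cls],
                            epoch_kind="full_1500ms")
            b = td.EpochSet(template_trial(cls, 20, with_tone=False), [cls],
                            epoch_kind="full_1500ms")
            la, _ = td.lag_label_series(trained_model, a)
            lb, _ = td.lag_label_series(trained_model, b)
            # shift-equivariance of windowed extraction on a noise-free trial
            np.testing.assert_array_equal(lb[0, 20:], la[0, :100])
            assert lb[0, 20] == la[0, 0] == cls

    def test_analysis_epochs_rejected(self, trained_model, sleep_epochs):
        short = td.EpochSet(sleep_epochs.data[:, :, 100:180],
                            sleep_epochs.labels, epoch_kind="analysis_400ms")
        with pytest.raises(ValueError, match="full 1500 ms"):
            td.lag_label_series(trained_model, short)


class TestVoting:
    def test_unanimous_series(self):
        assert td.vote_longest_run([3] * 120, 0)[0][0] == 3

    def test_run_of_three_beats_shorter_runs(self):
        series = [1, 1, 2, 2, 2] + [3, 4, 3, 4, 3]
        ranked = td.vote_longest_run(series, 0)
        assert ranked[0] == (2, 3)
        assert ranked[1] == (1, 2)

    def test_window_start_restricts_view(self):
        series = [1] * 10 + [2] * 5
        assert td.vote_longest_run(series, 0)[0][0] == 1
        assert td.vote_longest_run(series, 10)[0][0] == 2

    def test_matches_bruteforce_scanner_on_random_series(self, rng):
        for _ in range(1000):
            series = rng.integers(1, 6, size=rng.integers(5, 121))
            start = int(rng.integers(0, len(series) - 1))
            assert td.vote_longest_run(series, start) == longest_run_oracle(series, start)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            td.vote_longest_run([1, 2], 2)


class TestDecodeSession:
    def test_twelve_windows_enumerated(self, sleep_decoding):
        cfg = td.SleepDecoderConfig()
        assert len(cfg.window_starts) == 12
        np.testing.assert_array_equal(cfg.window_starts, np.arange(0, 120, 10))
        assert sleep_decoding.per_window_predictions.shape[0] == 12
        assert sleep_decoding.chosen_window == np.argmax(sleep_decoding.window_ccrs)
        assert sleep_decoding.chosen_start_ms == sleep_decoding.chosen_start_lag * 5

    def test_no_adjacent_repetitions_within_blocks(self, sleep_decoding, sleep_epochs):
        order = np.argsort(sleep_epochs.trial_order)
        preds = sleep_decoding.trial_predictions[order]
        blocks = sleep_epochs.blocks[order]
        same_block = blocks[1:] == blocks[:-1]
        assert not np.any((preds[1:] == preds[:-1]) & same_block)

    def test_second_choice_fallback_toy(self):
        """Both trials favour class 2; the second must fall back to class 4."""
        t1 = np.array([2] * 6 + [1, 3, 1, 3] + [5, 4] * 55)[:120]
        t2 = np.array([2] * 7 + [4] * 5 + [1, 3] * 54)[:120]
        lag_labels = np.stack([t1, t2])
        res = td.decode_lag_labels(lag_labels, true_labels=[2, 4])
        assert res.per_window_predictions[0, 0] == 2
        assert res.per_window_predictions[0, 1] == 4

    def test_single_class_series_falls_back_to_posterior(self):
        lag_labels = np.full((2, 120), 3)
        post = np.zeros((2, 120, 5))
        post[:, :, 2] = 0.6   # class 3 dominant
        post[:, :, 4] = 0.3   # class 5 runner-up
        res = td.decode_lag_labels(lag_labels, true_labels=[3, 5], posteriors=post)
        assert res.per_window_predictions[0, 0] == 3
        assert res.per_window_predictions[0, 1] == 5  # forced off 3, best posterior

    def test_high_snr_recovery(self, trained_model, sleep_session, sleep_epochs,
                               sleep_decoding):
        """Strong sustained reactivation is recovered almost perfectly."""
        assert td.ccr(sleep_epochs.labels, sleep_decoding.trial_predictions) >= 0.95

    def test_zero_jitter_keeps_first_lag_in_chosen_window(self, trained_model):
        cfg = td.SynthConfig(seed=31, n_sequences=3, snr=5.0,
                             sleep_latency_jitter_ms=0, interblock_s=20.0)
        sess = td.generate_sleep_session(cfg)
        out = td.decode_session(trained_model, td.segment_epochs(sess.recording))
        assert out.chosen_start_lag == 0


class TestPermutation:
    def test_p_value_is_exceedance_fraction(self, sleep_decoding):
        cfg = td.SleepDecoderConfig(seed=5, n_resamples=200, n_permutations=200)
        res = td.permutation_test(sleep_decoding, config=cfg)
        count = int(np.sum(res.permutation_ccrs >= res.true_ccr_mean))
        assert res.p_value == count / 200
        assert 0 <= res.p_value <= 1
        cfg2 = td.SleepDecoderConfig(seed=5, n_resamples=200, n_permutations=200,
                                     add_one_p=True)
        res2 = td.permutation_test(sleep_decoding, config=cfg2)
        assert res2.p_value == (count + 1) / 201

    def test_signal_trumps_shuffles(self, sleep_decoding):
        cfg = td.SleepDecoderConfig(seed=6, n_resamples=300, n_permutations=300)
        res = td.permutation_test(sleep_decoding, config=cfg)
        assert res.true_ccr_mean > 0.9
        assert res.p_value < 0.02

    def test_shuffled_ccr_concentrates_at_chance(self, rng):
        """Label shuffles on balanced 5-class data give CCR near 0.20.

        The fixed-window null is a plain binomial at 1/5; re-optimising
        the window per shuffle can only sit above it (checked separately).
        """
        true = np.repeat(np.arange(1, 6), 40)
        res = td.decode_lag_labels(rng.integers(1, 6, (200, 120)), true)
        draws = shuffled_ccrs(res, rng, 400, reoptimize=False)
        assert abs(draws.mean() - 0.2) < 0.02

    def test_window_reoptimization_is_conservative(self, rng):
        """Re-optimised shuffled CCRs dominate fixed-window shuffled CCRs."""
        true = rng.integers(1, 6, size=100)
        res = td.decode_lag_labels(rng.integers(1, 6, (100, 120)), true)
        reopt = shuffled_ccrs(res, np.random.default_rng(1), 300, reoptimize=True)
        fixed = shuffled_ccrs(res, np.random.default_rng(1), 300, reoptimize=False)
        assert reopt.mean() >= fixed.mean()
        assert np.all(reopt >= fixed)

    def test_too_few_trials_rejected(self, rng):
        res = td.decode_lag_labels(rng.integers(1, 6, (3, 120)), [1, 2, 3])
        with pytest.raises(ValueError, match="4 trials"):
            td.permutation_test(res)
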