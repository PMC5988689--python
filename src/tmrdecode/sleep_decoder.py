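"""Decoding post-cue sleep EEG with a wake-trained classifier.

Reactivation latency after a cue is unknown, so each cued sleep trial is
classified repeatedly at 120 lags: 400 ms windows whose onsets step by
5 ms (one sample at 200 Hz) over 0–595 ms post-cue, the last window
ending exactly 1000 ms after the cue.  Features are extracted per lag,
normalised with the *training* statistics, restricted to the selected
feature subset and classified, giving a 120-long label series per trial.

A modified majority vote turns the series into one prediction: within a
voting window the class with the longest uninterrupted run wins (ties go
to the run occurring earliest).  Twelve candidate voting windows are
considered, starting at lags 1, 11, …, 111 (1-based) and all ending at
lag 120; the window with the highest classification rate across all
trials is kept.  Because the trained sequence never repeats a class in
adjacent positions, a prediction equal to the previous trial's
prediction is replaced by the class with the next-longest run (the
constraint state resets at stimulation-block boundaries).

Significance: the "true" CCR is the mean over 1000 draws of 50 % of the
trials; 1000 label shuffles — each re-optimising the voting window on
the shuffled labels — give the null distribution, and
``p = #(shuffled ≥ true) / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import FS, FULL_KIND, N_ANALYSIS, STIM_SAMPLE, EpochSet
from .features import extract_feature_array, normalize_array
from .classifier import TrainedModel, ccr, predict


@dataclass
class SleepDecoderConfig:
    """Lag grid, voting-window and permutation-test settings."""

    lag_window_ms: int = 400
    lag_step_ms: int = 5
    n_lags: int = 120          # onsets 0, 5, ..., 595 ms post-cue
    post_cue_span_ms: int = 1000
    n_voting_windows: int = 12
    voting_shift: int = 10     # lags between successive window starts
    resample_fraction: float = 0.5
    n_resamples: int = 1000
    n_permutations: int = 1000
    seed: int = 0
    add_one_p: bool = False    # (count+1)/(N+1) p-value variant

    @property
    def window_starts(self) -> np.ndarray:
        """0-based start lags of the voting windows: 0, 10, ..., 110."""
        return np.arange(self.n_voting_windows) * self.voting_shift


@dataclass
class SleepDecodingResult:
    """Per-lag labels, voting outcomes and permutation statistics."""

    lag_labels: np.ndarray               # (trials, n_lags)
    posteriors: np.ndarray               # (trials, n_lags, n_classes)
    classes: np.ndarray
    per_window_predictions: np.ndarray   # (n_windows, trials)
    window_ccrs: np.ndarray
    chosen_window: int
    chosen_start_lag: int                # 0-based
    chosen_start_ms: float
    trial_predictions: np.ndarray
    true_labels: np.ndarray
    true_ccr_mean: float | None = None
    true_ccr_sd: float | None = None
    permutation_ccrs: np.ndarray | None = None
    p_value: float | None = None
    config: SleepDecoderConfig = field(default_factory=SleepDecoderConfig)


def lag_label_series(
    model: TrainedModel,
    sleep_epochs: EpochSet,
    config: SleepDecoderConfig | None = None,
    batch: int = 32,
):
    """Per-trial, per-lag predicted labels (and posteriors).

    Sleep epochs must be full 1500 ms epochs (500 ms baseline context +
    1000 ms post-cue).  Returns ``(lag_labels, posteriors)`` with shapes
    ``(trials, 120)`` and ``(trials, 120, n_classes)``.
    """
    config = config or SleepDecoderConfig()
    if sleep_epochs.epoch_kind != FULL_KIND:
        raise ValueError("sleep decoding requires full 1500 ms epochs")
    if model.selected is None or model.norm_stats is None:
        raise ValueError("model must carry selected feature indices and norm_stats")
    step = config.lag_step_ms * FS // 1000  # 1 sample
    n_lags = config.n_lags
    data = sleep_epochs.data
    need = STIM_SAMPLE + (n_lags - 1) * step + N_ANALYSIS
    if data.shape[2] < need:
        raise ValueError(
            f"trial epochs have {data.shape[2]} samples; lag decoding needs {need}"
        )
    T = data.shape[0]
    lag_labels = np.empty((T, n_lags), dtype=np.int64)
    posteriors = np.empty((T, n_lags, len(model.classes)))
    windows = np.lib.stride_tricks.sliding_window_view(data, N_ANALYSIS, axis=2)
    starts = STIM_SAMPLE + step * np.arange(n_lags)
    for lo in range(0, T, batch):
        hi = min(lo + batch, T)
        w = windows[lo:hi][:, :, starts]              # (b, 16, n_lags, 80)
        w = np.swapaxes(w, 1, 2)                      # (b, n_lags, 16, 80)
        feats = extract_feature_array(w.reshape(-1, *w.shape[2:]))
        feats = normalize_array(feats, model.norm_stats)[:, model.selected]
        labels, post = predict(model, feats)
        lag_labels[lo:hi] = labels.reshape(hi - lo, n_lags)
        posteriors[lo:hi] = post.reshape(hi - lo, n_lags, -1)
    return lag_labels, posteriors


def vote_longest_run(labels, window_start_lag: int):
    """Rank classes by their longest uninterrupted run within a voting window.

    The window is ``[window_start_lag, end]`` (0-based, to the end of the
    series).  Returns a list of ``(class, run_length)`` pairs sorted by
    decreasing run length; among equal runs, the run occurring earliest
    in the window ranks first.
    """
    seq = np.asarray(labels)[window_start_lag:]
    if seq.size == 0:
        raise ValueError("empty voting window")
    best = {}  # class -> (run_len, first_pos_of_best_run)
    run_class, run_len, run_start = None, 0, 0
    for pos, lab in enumerate(seq):
        if lab == run_class:
            run_len += 1
        else:
            run_class, run_len, run_start = lab, 1, pos
        cur = best.get(lab)
        if cur is None or run_len > cur[0]:
            best[lab] = (run_len, run_start)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
    return [(int(c), int(rl)) for c, (rl, _) in ranked]


def _constrained_prediction(ranking, prev, mean_posterior, classes):
    """Apply the no-adjacent-repetition constraint to a run ranking."""
    if prev is None or ranking[0][0] != prev:
        return ranking[0][0]
    for c, _ in ranking[1:]:
        if c != prev:
            return c
    # single-class lag series: fall back to the highest mean posterior
    # among the other classes
    if mean_posterior is not None:
        order = np.argsort(-mean_posterior, kind="stable")
        for k in order:
            if int(classes[k]) != prev:
                return int(classes[k])
    return int(min(c for c in classes if c != prev))


def decode_lag_labels(
    lag_labels: np.ndarray,
    true_labels,
    config: SleepDecoderConfig | None = None,
    posteriors: np.ndarray | None = None,
    classes=(1, 2, 3, 4, 5),
    blocks=None,
    trial_order=None,
) -> SleepDecodingResult:
    """Voting-window search on precomputed lag label series.

    Trials are processed in presentation order (``trial_order``), with the
    adjacent-repetition constraint chained through each voting window and
    reset at block boundaries.  The chosen window maximises the all-trial
    CCR; ties go to the earliest window.
    """
    config = config or SleepDecoderConfig()
    lag_labels = np.asarray(lag_labels)
    true_labels = np.asarray(true_labels)
    T = lag_labels.shape[0]
    classes = np.asarray(classes)
    if trial_order is None:
        trial_order = np.arange(T)
    order = np.argsort(np.asarray(trial_order), kind="stable")
    starts = config.window_starts
    preds = np.empty((len(starts), T), dtype=np.int64)
    for w, start in enumerate(starts):
        prev, prev_block = None, None
        for t in order:
            blk = None if blocks is None else blocks[t]
            if blk is not None and blk != prev_block:
                prev = None
            ranking = vote_longest_run(lag_labels[t], start)
            mp = None
            if posteriors is not None:
                mp = posteriors[t, start:].mean(axis=0)
            preds[w, t] = _constrained_prediction(ranking, prev, mp, classes)
            prev, prev_block = preds[w, t], blk
    window_ccrs = (preds == true_labels[None, :]).mean(axis=1)
    chosen = int(np.argmax(window_ccrs))  # first max = earliest window
    start_lag = int(starts[chosen])
    return SleepDecodingResult(
        lag_labels=lag_labels,
        posteriors=posteriors if posteriors is not None else np.empty((T, lag_labels.shape[1], 0)),
        classes=classes,
        per_window_predictions=preds,
        window_ccrs=window_ccrs,
        chosen_window=chosen,
        chosen_start_lag=start_lag,
        chosen_start_ms=start_lag * config.lag_step_ms,
        trial_predictions=preds[chosen].copy(),
        true_labels=true_labels,
        config=config,
    )


def decode_session(
    model: TrainedModel,
    sleep_epochs: EpochSet,
    config: SleepDecoderConfig | None = None,
) -> SleepDecodingResult:
    """Full sleep decoding: lag series, voting-window search, constraint."""
    config = config or SleepDecoderConfig()
    lag_labels, posteriors = lag_label_series(model, sleep_epochs, config)
    return decode_lag_labels(
        lag_labels,
        sleep_epochs.labels,
        config=config,
        posteriors=posteriors,
        classes=model.classes,
        blocks=sleep_epochs.blocks,
        trial_order=sleep_epochs.trial_order,
    )


def shuffled_ccrs(result: SleepDecodingResult, rng, n_permutations, reoptimize=True):
    """Label-shuffle null CCRs (optionally re-optimising the window per shuffle)."""
    preds = result.per_window_predictions
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = rng.permutation(result.true_labels)
        per_window = (preds == shuffled[None, :]).mean(axis=1)
        out[i] = per_window.max() if reoptimize else per_window[result.chosen_window]
    return out


def permutation_test(
    result: SleepDecodingResult,
    true_labels=None,
    config: SleepDecoderConfig | None = None,
) -> SleepDecodingResult:
    """50 %-resampled true CCR and label-shuffle significance test.

    Fills ``true_ccr_mean``/``sd``, ``permutation_ccrs`` and ``p_value``
    on the result (in place) and returns it.
    """
    config = config or result.config
    true = result.true_labels if true_labels is None else np.asarray(true_labels)
    T = len(true)
    if T < 4:
        raise ValueError("permutation test needs at least 4 trials")
    resample_rng, shuffle_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(2)
    )
    correct = (result.trial_predictions == true).astype(float)
    k = max(1, int(round(config.resample_fraction * T)))
    draws = np.empty(config.n_resamples)
    for i in range(config.n_resamples):
        idx = resample_rng.choice(T, size=k, replace=False)
        draws[i] = correct[idx].mean()
    result.true_ccr_mean = float(draws.mean())
    result.true_ccr_sd = float(draws.std(ddof=1))
    result.permutation_ccrs = shuffled_ccrs(result, shuffle_rng, config.n_permutations)
    count = int(np.sum(result.permutation_ccrs >= result.true_ccr_mean))
    if config.add_one_p:
        result.p_value = (count + 1) / (config.n_permutations + 1)
    else:
        result.p_value = count / config.n_permutations
    return result
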