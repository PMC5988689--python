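"""Epoching of continuous EEG recordings.

Continuous 16-channel, 200 Hz recordings are cut into stimulus-locked
epochs of 1500 ms (500 ms pre-stimulus baseline + 1000 ms post-stimulus).
The post-stimulus part is baseline-corrected by subtracting the mean of
the 500 ms preceding the stimulus, per channel and per trial.  The
classifier itself operates on the first 400 ms after the stimulus
(80 samples), extracted by :func:`analysis_window`.

A fifth "null" class (label 5, no cue present) is built from randomly
drawn 400 ms segments of cue-free intervals, baseline-corrected the same
way (:func:`make_null_epochs`).

Sample indexing is 0-based and windows are half-open ``[start, end)``:
a full epoch has 300 samples with the stimulus at index 100; the
analysis window is samples ``[100, 180)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical 10-20 montage used throughout, in this fixed order.
CHANNELS = (
    "F3", "F4", "C5", "C3", "Cz", "C4", "C6",
    "CP5", "CP3", "CP4", "CP6", "P7", "Pz", "P8", "O1", "O2",
)
N_CHANNELS = 16
FS = 200  # Hz

#: Full epoch geometry: 500 ms baseline + 1000 ms post-stimulus at 200 Hz.
N_BASELINE = 100
N_POST = 200
N_FULL = N_BASELINE + N_POST
STIM_SAMPLE = N_BASELINE

#: Analysis window: first 400 ms post-stimulus.
N_ANALYSIS = 80

NULL_CLASS = 5
CLASSES = (1, 2, 3, 4, 5)

FULL_KIND = "full_1500ms"
ANALYSIS_KIND = "analysis_400ms"


class EdgeEventError(ValueError):
    """An event lies too close to a recording edge to epoch."""


@dataclass
class Recording:
    """Continuous multichannel EEG with event markers.

    Parameters
    ----------
    data : ndarray, shape (16, n_samples)
        Channel-by-time signal in microvolts, channels in :data:`CHANNELS`
        order.
    fs : int
        Sampling rate; must equal 200 Hz.
    channel_names : sequence of str
        Must match :data:`CHANNELS` (case-insensitively).
    events : ndarray, shape (n_events, 2) or list of (onset, label)
        Integer sample onsets (strictly increasing, in bounds) and class
        labels in {1..5}.
    blocks : ndarray, optional
        Per-event block index (used to reset the sequence constraint at
        block boundaries during sleep decoding).
    """

    data: np.ndarray
    fs: int = FS
    channel_names: tuple = CHANNELS
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    blocks: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"expected (16, n_samples) data, got {self.data.shape}")
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS} Hz, got {self.fs}")
        names = tuple(str(c).lower() for c in self.channel_names)
        canon = tuple(c.lower() for c in CHANNELS)
        if names != canon:
            raise ValueError("channel names/order do not match the canonical montage")
        self.channel_names = CHANNELS
        ev = np.asarray(self.events)
        if ev.size == 0:
            ev = np.empty((0, 2), dtype=np.int64)
        if not np.issubdtype(ev.dtype, np.integer):
            if not np.all(ev == np.round(ev)):
                raise ValueError("event onsets/labels must be integers (no rounding)")
            ev = ev.astype(np.int64)
        self.events = ev.astype(np.int64).reshape(-1, 2)
        onsets = self.events[:, 0]
        if onsets.size and (np.any(np.diff(onsets) <= 0)):
            raise ValueError("event onsets must be strictly increasing")
        if onsets.size and (onsets.min() < 0 or onsets.max() >= self.n_samples):
            raise ValueError("event onsets out of recording bounds")
        if not np.all(np.isin(self.events[:, 1], CLASSES)):
            raise ValueError("event labels must lie in {1..5}")
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)
            if self.blocks.shape != (len(self.events),):
                raise ValueError("blocks must have one entry per event")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length labelled EEG trials.

    ``data`` has shape (trials, 16, samples); ``epoch_kind`` is either
    ``"full_1500ms"`` (300 samples, stimulus at index 100) or
    ``"analysis_400ms"`` (80 samples).  ``trial_order`` holds the original
    presentation index of each trial; ``blocks`` (optional) the stimulation
    block each trial belongs to.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: int = FS
    epoch_kind: str = FULL_KIND
    trial_order: np.ndarray | None = None
    blocks: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (trials, channels, samples) matching labels")
        if self.data.shape[1] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels")
        expected = {FULL_KIND: N_FULL, ANALYSIS_KIND: N_ANALYSIS}[self.epoch_kind]
        if self.data.shape[2] != expected:
            raise ValueError(
                f"{self.epoch_kind} epochs must have {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if self.labels.size and not np.all(np.isin(self.labels, CLASSES)):
            raise ValueError("labels must lie in {1..5}")
        if self.trial_order is None:
            self.trial_order = np.arange(len(self.labels))
        else:
            self.trial_order = np.asarray(self.trial_order, dtype=np.int64)
            if sorted(self.trial_order) != list(range(len(self.labels))):
                raise ValueError("trial_order must be a permutation of 0..T-1")
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)
            if self.blocks.shape != self.labels.shape:
                raise ValueError("blocks must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return len(self.labels)


def segment_epochs(recording: Recording, events=None) -> EpochSet:
    """Cut 1500 ms stimulus-locked epochs and baseline-correct them.

    Samples 0–99 of each epoch are the raw pre-stimulus baseline; samples
    100–299 are the raw post-stimulus signal minus the per-channel mean of
    the baseline.

    Raises
    ------
    EdgeEventError
        If any event has fewer than 100 samples before it or 200 after it.
    """
    ev = recording.events if events is None else np.asarray(events, dtype=np.int64).reshape(-1, 2)
    onsets, labels = ev[:, 0], ev[:, 1]
    bad = np.flatnonzero((onsets < N_BASELINE) | (onsets + N_POST > recording.n_samples))
    if bad.size:
        i = bad[0]
        raise EdgeEventError(
            f"event {i} (onset sample {onsets[i]}, class {labels[i]}) is too close "
            f"to a recording edge for a {N_FULL}-sample epoch"
        )
    idx = onsets[:, None] + np.arange(-N_BASELINE, N_POST)[None, :]
    data = recording.data[:, idx]            # (16, trials, 300)
    data = np.transpose(data, (1, 0, 2)).copy()
    baseline = data[:, :, :N_BASELINE].mean(axis=2, keepdims=True)
    data[:, :, N_BASELINE:] -= baseline
    blocks = recording.blocks if events is None else None
    return EpochSet(data, labels, fs=recording.fs, epoch_kind=FULL_KIND, blocks=blocks)


def analysis_window(epochs: EpochSet) -> EpochSet:
    """Restrict full epochs to the 400 ms analysis window (samples [100, 180))."""
    if epochs.epoch_kind != FULL_KIND:
        raise ValueError(
            f"analysis_window requires {FULL_KIND} epochs, got {epochs.epoch_kind}"
        )
    return replace(
        epochs,
        data=epochs.data[:, :, STIM_SAMPLE:STIM_SAMPLE + N_ANALYSIS].copy(),
        epoch_kind=ANALYSIS_KIND,
    )


def make_null_epochs(recording: Recording, quiet_intervals, n: int, seed) -> EpochSet:
    """Draw ``n`` class-5 (no cue) epochs from cue-free intervals.

    Each epoch is a 400 ms segment with the mean of the preceding 500 ms
    subtracted, mirroring the baseline correction of the cued classes.
    Onset positions are drawn uniformly (with replacement across draws)
    from every sample position at which both the 500 ms baseline and the
    400 ms segment fit inside a quiet interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    need = N_BASELINE + N_ANALYSIS  # 900 ms
    starts = []
    for lo, hi in quiet_intervals:
        lo, hi = int(lo), int(hi)
        if hi - lo < need:
            raise ValueError(
                f"quiet interval [{lo}, {hi}) shorter than the required "
                f"{need} samples (500 ms baseline + 400 ms segment)"
            )
        # segment onset s must satisfy s - 100 >= lo and s + 80 <= hi
        starts.append(np.arange(lo + N_BASELINE, hi - N_ANALYSIS + 1))
    positions = np.concatenate(starts)
    capacity = sum((hi - lo) // need for lo, hi in quiet_intervals)
    if n > capacity:
        warnings.warn(
            f"requested {n} null epochs but non-overlapping capacity is only "
            f"{capacity}; sampling onsets with replacement", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    onsets = np.sort(rng.choice(positions, size=n, replace=True))
    idx = onsets[:, None] + np.arange(-N_BASELINE, N_ANALYSIS)[None, :]
    seg = np.transpose(recording.data[:, idx], (1, 0, 2))
    base = seg[:, :, :N_BASELINE].mean(axis=2, keepdims=True)
    data = seg[:, :, N_BASELINE:] - base
    return EpochSet(
        data, np.full(n, NULL_CLASS), fs=recording.fs, epoch_kind=ANALYSIS_KIND
    )


def concat_epochs(a: EpochSet, b: EpochSet) -> EpochSet:
    """Stack two epoch sets with identical geometry (trial order renumbered)."""
    if a.epoch_kind != b.epoch_kind or a.fs != b.fs:
        raise ValueError("epoch sets differ in kind or sampling rate")
    blocks = None
    if a.blocks is not None and b.blocks is not None:
        blocks = np.concatenate([a.blocks, b.blocks])
    return EpochSet(
        np.concatenate([a.data, b.data]),
        np.concatenate([a.labels, b.labels]),
        fs=a.fs,
        epoch_kind=a.epoch_kind,
        blocks=blocks,
    )


def prepare_wake_epochs(
    recording: Recording, quiet_intervals, seed, n_null: int | None = None
) -> EpochSet:
    """Full wake preparation: epoch, window, and append balanced null trials.

    ``n_null`` defaults to the per-class cue count so the five classes stay
    balanced for training and evaluation.
    """
    cued = analysis_window(segment_epochs(recording))
    if n_null is None:
        counts = np.bincount(recording.events[:, 1], minlength=6)[1:5]
        n_null = int(counts.max()) if counts.size else 0
    null = make_null_epochs(recording, quiet_intervals, n_null, seed)
    return concat_epochs(cued, null)
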