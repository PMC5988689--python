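"""Trial feature extraction: wavelet, spectral and time-domain families.

Each 16-channel, 400 ms (80 sample) analysis epoch is summarised by three
concatenated feature families:

* **DWT** — a 5-level Daubechies-4 decomposition per channel (symmetric
  half-point extension); the detail coefficients at levels 2–5 are kept
  (covering roughly 3.1–50 Hz at 200 Hz sampling) and concatenated in the
  order D2, D3, D4, D5 per channel, channels ascending.  With 80-sample
  input the detail lengths are 25/16/11/9, i.e. 61 coefficients per
  channel and 976 columns in total.
* **Spectral** — Welch band power per channel in theta (4–8 Hz), alpha
  (8–12 Hz) and beta (16–24 Hz): 64-sample Hann-windowed segments
  advanced by 6 samples (58/64 ≈ 90.6 % overlap, the closest integer
  realization of a 90 % ratio; 3 segments fit an 80-sample window), band
  power by the rectangle rule over PSD bins whose centre frequency lies
  in [low, high).  48 columns.
* **Time-domain** — a moving average of length 4 (valid positions only)
  down-sampled by 4 (valid indices 3, 7, …, 75), i.e. 19 coarse ERP
  amplitude samples per channel; 304 columns.

Columns are ordered all-DWT, then all-spectral, then all-time.  Features
are normalised to zero mean / unit variance using statistics fitted on
the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal

from .epochs import ANALYSIS_KIND, FS, N_ANALYSIS, N_CHANNELS, EpochSet

WAVELET = "db4"
DWT_MODE = "symmetric"
DWT_LEVELS = 5
DWT_KEPT_LEVELS = (2, 3, 4, 5)

BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (16.0, 24.0)}
BAND_ORDER = ("theta", "alpha", "beta")
WELCH_NPERSEG = 64
WELCH_STEP = 6  # samples; 58/64 overlap

MAVG_N = 4
DECIM = 4
DECIM_OFFSET = 3  # keep valid moving-average indices 3, 7, ..., 75
N_TIME_PER_CHANNEL = 19


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column."""

    family: str                      # "dwt" | "spectral" | "time"
    channel: int                     # 1..16
    detail_level: int | None = None  # dwt: 2..5
    coeff_index: int | None = None   # dwt: 0-based index within the level
    band: str | None = None          # spectral: theta/alpha/beta
    time_index: int | None = None    # time: 1..19

    def __str__(self):
        if self.family == "dwt":
            return f"dwt.ch{self.channel:02d}.D{self.detail_level}.c{self.coeff_index:02d}"
        if self.family == "spectral":
            return f"spec.ch{self.channel:02d}.{self.band}"
        return f"time.ch{self.channel:02d}.t{self.time_index:02d}"


@dataclass
class FeatureMatrix:
    """Trials × features matrix with per-column descriptors."""

    values: np.ndarray
    descriptors: list
    labels: np.ndarray | None = None
    normalized: bool = False
    norm_stats: tuple | None = None  # (mean, sd) per column

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.descriptors):
            raise ValueError("values must be (trials, m) with one descriptor per column")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length must match trial count")

    @property
    def n_trials(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]


def _dwt_detail_lengths(n: int = N_ANALYSIS) -> dict:
    """Detail coefficient length per level for the pinned cascade."""
    flen = pywt.Wavelet(WAVELET).dec_len
    lengths, cur = {}, n
    for level in range(1, DWT_LEVELS + 1):
        cur = pywt.dwt_coeff_len(cur, flen, DWT_MODE)
        lengths[level] = cur
    return lengths


def _check_epoch_array(arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape[-2:] != (N_CHANNELS, N_ANALYSIS):
        raise ValueError(
            f"expected (..., {N_CHANNELS}, {N_ANALYSIS}) analysis epochs, got {arr.shape}"
        )
    return arr


def dwt_features(epoch):
    """DWT detail coefficients D2–D5 per channel (channel-major order).

    Accepts a single (16, 80) epoch or a stacked (..., 16, 80) array;
    returns (features, descriptors) with features shaped (..., 976).
    """
    arr = _check_epoch_array(epoch)
    with warnings.catch_warnings():
        # level 5 on 80 samples is intentionally at the boundary-effect limit
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(arr, WAVELET, mode=DWT_MODE, level=DWT_LEVELS, axis=-1)
    # coeffs = [A5, D5, D4, D3, D2, D1]
    by_level = {level: coeffs[DWT_LEVELS - level + 1] for level in DWT_KEPT_LEVELS}
    per_channel = np.concatenate([by_level[lv] for lv in DWT_KEPT_LEVELS], axis=-1)
    values = per_channel.reshape(arr.shape[:-2] + (-1,))
    lengths = _dwt_detail_lengths()
    descriptors = [
        FeatureDescriptor("dwt", ch, detail_level=lv, coeff_index=i)
        for ch in range(1, N_CHANNELS + 1)
        for lv in DWT_KEPT_LEVELS
        for i in range(lengths[lv])
    ]
    return values, descriptors


def spectral_features(epoch):
    """Welch band power (theta, alpha, beta) per channel; 48 columns."""
    arr = _check_epoch_array(epoch)
    freqs, psd = signal.welch(
        arr,
        fs=FS,
        window="hann",
        nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NPERSEG - WELCH_STEP,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    bin_width = FS / WELCH_NPERSEG
    bands = []
    for name in BAND_ORDER:
        lo, hi = BANDS[name]
        mask = (freqs >= lo) & (freqs < hi)
        bands.append(psd[..., mask].sum(axis=-1) * bin_width)
    values = np.stack(bands, axis=-1).reshape(arr.shape[:-2] + (-1,))
    descriptors = [
        FeatureDescriptor("spectral", ch, band=name)
        for ch in range(1, N_CHANNELS + 1)
        for name in BAND_ORDER
    ]
    return values, descriptors


def time_features(epoch):
    """Length-4 moving average down-sampled by 4; 19 values per channel."""
    arr = _check_epoch_array(epoch)
    # valid moving average along the last axis via cumulative sums
    cs = np.cumsum(arr, axis=-1)
    total = np.concatenate(
        [cs[..., MAVG_N - 1 : MAVG_N], cs[..., MAVG_N:] - cs[..., : -MAVG_N]], axis=-1
    )
    avg = total / MAVG_N                       # (..., 16, 77)
    picked = avg[..., DECIM_OFFSET::DECIM]     # (..., 16, 19)
    values = picked.reshape(arr.shape[:-2] + (-1,))
    descriptors = [
        FeatureDescriptor("time", ch, time_index=t)
        for ch in range(1, N_CHANNELS + 1)
        for t in range(1, N_TIME_PER_CHANNEL + 1)
    ]
    return values, descriptors


def extract_feature_array(arr) -> np.ndarray:
    """All three families for a stacked (..., 16, 80) array, DWT→spectral→time."""
    d, _ = dwt_features(arr)
    s, _ = spectral_features(arr)
    t, _ = time_features(arr)
    return np.concatenate([d, s, t], axis=-1)


def feature_descriptors() -> list:
    """Column descriptors for :func:`extract_feature_array` output."""
    zero = np.zeros((N_CHANNELS, N_ANALYSIS))
    return dwt_features(zero)[1] + spectral_features(zero)[1] + time_features(zero)[1]


def assemble_features(epochs: EpochSet) -> FeatureMatrix:
    """Extract the full per-trial feature vector for an analysis epoch set."""
    if epochs.epoch_kind != ANALYSIS_KIND:
        raise ValueError("assemble_features requires 400 ms analysis epochs")
    values = extract_feature_array(epochs.data)
    return FeatureMatrix(values, feature_descriptors(), labels=epochs.labels)


def fit_normalizer(train: FeatureMatrix):
    """Per-column mean and standard deviation of the training split.

    Columns whose spread is at floating-point noise level relative to
    their mean are treated as constant (sd set to 0 so they normalise
    to 0).
    """
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0)
    sd[sd <= 1e-12 * np.maximum(1.0, np.abs(mean))] = 0.0
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} constant feature column(s); normalised to 0",
            stacklevel=2,
        )
    return mean, sd


def apply_normalizer(fm: FeatureMatrix, norm_stats) -> FeatureMatrix:
    """Standardise columns with training statistics (constant columns → 0)."""
    mean, sd = norm_stats
    safe = np.where(sd == 0, 1.0, sd)
    values = (fm.values - mean) / safe
    values[:, sd == 0] = 0.0
    return replace(fm, values=values, normalized=True, norm_stats=(mean, sd))


def normalize_array(values: np.ndarray, norm_stats) -> np.ndarray:
    """Array-level counterpart of :func:`apply_normalizer` (sleep lag paths)."""
    mean, sd = norm_stats
    safe = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / safe
    out[..., sd == 0] = 0.0
    return out
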