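"""Synthetic experiment sessions with known ground truth.

The generators emulate the statistical structure the decoding pipeline
assumes, for a serial-reaction-time experiment in which a fixed 12-item
cue sequence (1-2-1-4-2-3-4-1-3-2-4-3, no adjacent repeats, each finger
class three times) is presented at 1500 ms spacing:

* **wake** sessions — blocks of 10 sequences separated by 2-minute quiet
  intervals; every cue embeds a class-specific 16-channel template
  (left-hand classes 1–2 weighted to right-central electrodes, classes
  3–4 to left-central ones; the "face" classes 1 and 3 add a posterior
  P7/P8 deflection) plus a class-shared tone-evoked response, in 1/f
  background noise;
* **sleep** TMR sessions — blocks of 5 sequences followed by 2-minute
  silent gaps; each cue's template is embedded at an unknown latency
  drawn uniformly from a jitter range, with amplitude decaying
  multiplicatively across cue repetitions;
* **control** sessions — 140 sequence presentations whose tone response
  is identical for all four classes (nothing class-specific to decode).

All generators are pure functions of their configuration (including its
seed).  Template amplitude is ``snr × noise_sd``, so ``snr`` is the
template-to-noise amplitude ratio; the tone response has its own ratio
``tone_snr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .epochs import FS, N_ANALYSIS, N_CHANNELS, Recording

SEQUENCE = (1, 2, 1, 4, 2, 3, 4, 1, 3, 2, 4, 3)
WAKE_SEQUENCES_PER_BLOCK = 10
SLEEP_SEQUENCES_PER_BLOCK = 5

# canonical channel indices used by the templates
_RIGHT_CENTRAL = (5, 6, 9, 10)   # C4, C6, CP4, CP6
_LEFT_CENTRAL = (2, 3, 7, 8)     # C5, C3, CP5, CP3
_POSTERIOR = (11, 13)            # P7, P8
_FRONTOCENTRAL = (0, 1, 4)       # F3, F4, Cz


@dataclass
class SynthConfig:
    """Session-generation settings (the defaults are the study design)."""

    seed: int = 0
    n_sequences: int = 70
    sequence: tuple = SEQUENCE
    iti_ms: int = 1500
    sequences_per_block: int | None = None  # None -> 10 wake / 5 sleep
    interblock_s: float = 120.0
    snr: float = 1.0              # class-template amplitude / noise sd
    tone_snr: float = 2.0         # shared tone-response amplitude / noise sd
    sleep_latency_jitter_ms: float = 200.0
    sleep_response_ms: float = 800.0  # duration of the sustained reactivation
    decay_per_cue: float = 1.0
    noise_exponent: float = 1.0   # 1/f^alpha background
    noise_sd: float = 1.0
    fs: int = FS

    def __post_init__(self):
        seq = tuple(self.sequence)
        if len(seq) != 12:
            raise ValueError("sequence must have 12 items")
        if any(seq.count(c) != 3 for c in (1, 2, 3, 4)):
            raise ValueError("each class must appear 3 times in the sequence")
        if any(a == b for a, b in zip(seq, seq[1:] + seq[:1])):
            raise ValueError("sequence must have no adjacent repeats (incl. wrap-around)")
        if self.snr < 0 or self.tone_snr < 0:
            raise ValueError("snr must be non-negative")
        self.sequence = seq


@dataclass
class SynthSession:
    """A generated recording plus its ground truth."""

    recording: Recording
    truth: pd.DataFrame          # per cue: onset, label, block, cue_index, ...
    quiet_intervals: list        # [(start_sample, end_sample), ...] cue-free


def _spatial_pattern(cls: int) -> np.ndarray:
    """Per-class channel weights: a lateralized-central + posterior code.

    Left-hand classes (1, 2) load the right-central electrodes and
    right-hand classes (3, 4) the left-central ones; the face-cued
    classes (1, 3) add a negative posterior (P7/P8) weight, mimicking an
    N170-like component.  The four patterns are linearly separable, and
    being purely spatial they are what makes sleep-lag decoding tolerant
    to window misalignment.
    """
    w = np.zeros(N_CHANNELS)
    side = _RIGHT_CENTRAL if cls in (1, 2) else _LEFT_CENTRAL
    w[list(side)] = 1.0
    if cls in (1, 3):
        w[list(_POSTERIOR)] = -1.0
    return w


def class_templates(fs: int = FS) -> dict:
    """Deterministic per-class 16 × 80 wake templates, unit peak amplitude.

    Each template is the class's spatial pattern modulated by a smooth
    400 ms bump (central channels) and a 170 ms-latency Gaussian
    deflection (posterior channels).
    """
    t = np.arange(N_ANALYSIS) / fs
    bump = _signal.windows.hann(N_ANALYSIS)
    post = np.exp(-((t - 0.17) ** 2) / (2 * 0.05**2))
    out = {}
    for cls in (1, 2, 3, 4):
        tpl = np.zeros((N_CHANNELS, N_ANALYSIS))
        central = _RIGHT_CENTRAL if cls in (1, 2) else _LEFT_CENTRAL
        tpl[list(central), :] = bump[None, :]
        if cls in (1, 3):
            tpl[list(_POSTERIOR), :] = -post[None, :]
        out[cls] = tpl / np.max(np.abs(tpl))
    return out


def class_response(cls: int, n_samples: int) -> np.ndarray:
    """Sustained reactivation response: spatial pattern × plateau envelope.

    Used by the sleep generator; a Tukey envelope (25 % taper) keeps the
    onset/offset smooth while the class's channel topography persists
    for the whole response duration.
    """
    env = _signal.windows.tukey(n_samples, alpha=0.25)
    return _spatial_pattern(cls)[:, None] * env[None, :]


def tone_erp(fs: int = FS) -> np.ndarray:
    """Class-shared auditory evoked response (fronto-central), unit peak."""
    t = np.arange(N_ANALYSIS) / fs
    wave = np.exp(-t / 0.12) * np.sin(2 * np.pi * 5.0 * t)
    tpl = np.zeros((N_CHANNELS, N_ANALYSIS))
    tpl[list(_FRONTOCENTRAL), :] = wave
    return tpl / np.max(np.abs(tpl))


def sequence_events(config: SynthConfig, sequences_per_block: int | None = None) -> pd.DataFrame:
    """Cue schedule: onset sample, class label, block and cue index.

    ``config.n_sequences`` repetitions of the 12-item sequence at
    ``iti_ms`` spacing, grouped into blocks of ``sequences_per_block``
    sequences separated by ``interblock_s`` of silence.  A 2-second
    lead-in precedes the first cue.
    """
    spb = sequences_per_block or config.sequences_per_block or WAKE_SEQUENCES_PER_BLOCK
    iti = config.iti_ms * config.fs // 1000
    gap = int(round(config.interblock_s * config.fs))
    lead = 2 * config.fs
    rows = []
    onset = lead
    for s in range(config.n_sequences):
        if s > 0:
            onset += iti if s % spb else gap
        block = s // spb
        for item, label in enumerate(config.sequence):
            rows.append((onset + item * iti, label, block, len(rows)))
        onset += (len(config.sequence) - 1) * iti
    return pd.DataFrame(rows, columns=["onset", "label", "block", "cue_index"])


def _pink_noise(rng, n_samples: int, exponent: float, sd: float) -> np.ndarray:
    """16-channel Gaussian 1/f^alpha noise with per-channel sd."""
    white = rng.standard_normal((N_CHANNELS, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2)
    noise = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return noise * sd


def _quiet_intervals(events: pd.DataFrame, config: SynthConfig, n_samples: int) -> list:
    """Cue-free stretches between blocks (and the trailing gap)."""
    iti = config.iti_ms * config.fs // 1000
    out = []
    for block, grp in events.groupby("block"):
        end_of_block = int(grp["onset"].iloc[-1]) + iti
        nxt = events[events["block"] == block + 1]
        stop = int(nxt["onset"].iloc[0]) - 100 if len(nxt) else n_samples
        if stop - end_of_block >= N_ANALYSIS + 100:
            out.append((end_of_block, stop))
    return out


def _assemble(config: SynthConfig, events: pd.DataFrame, embed) -> SynthSession:
    iti = config.iti_ms * config.fs // 1000
    gap = int(round(config.interblock_s * config.fs))
    n_samples = int(events["onset"].iloc[-1]) + iti + gap
    rng = np.random.default_rng(config.seed)
    data = _pink_noise(rng, n_samples, config.noise_exponent, config.noise_sd)
    truth = embed(data, events, rng)
    rec = Recording(
        data=data,
        fs=config.fs,
        events=truth[["onset", "label"]].to_numpy(),
        blocks=truth["block"].to_numpy(),
    )
    return SynthSession(rec, truth, _quiet_intervals(events, config, n_samples))


def generate_wake_session(config: SynthConfig) -> SynthSession:
    """Wake imagery session: class templates + tone response at every cue."""
    events = sequence_events(config, config.sequences_per_block or WAKE_SEQUENCES_PER_BLOCK)
    templates = class_templates(config.fs)
    tone = tone_erp(config.fs)
    amp = config.snr * config.noise_sd
    tone_amp = config.tone_snr * config.noise_sd

    def embed(data, ev, rng):
        for onset, label in zip(ev["onset"], ev["label"]):
            data[:, onset:onset + N_ANALYSIS] += amp * templates[label] + tone_amp * tone
        return ev.copy()

    return _assemble(config, events, embed)


def generate_sleep_session(config: SynthConfig) -> SynthSession:
    """Sleep TMR session: jittered, decaying sustained reactivation.

    Each cue inserts the class's sustained spatial response
    (:func:`class_response`, duration ``sleep_response_ms``) at
    ``onset + latency`` with latency ~ U[0, sleep_latency_jitter_ms]
    (rounded to the 5 ms lag grid) and amplitude
    ``snr × noise_sd × decay_per_cue^cue_index``.  The class-shared tone
    response stays locked to the cue onset at full amplitude.
    """
    events = sequence_events(config, config.sequences_per_block or SLEEP_SEQUENCES_PER_BLOCK)
    tone = tone_erp(config.fs)
    tone_amp = config.tone_snr * config.noise_sd
    step = 5 * config.fs // 1000  # latency lives on the lag grid
    max_lag = int(round(config.sleep_latency_jitter_ms * config.fs / 1000)) // step
    n_resp = int(round(config.sleep_response_ms * config.fs / 1000))
    responses = {c: class_response(c, n_resp) for c in (1, 2, 3, 4)}

    def embed(data, ev, rng):
        lat = rng.integers(0, max_lag + 1, size=len(ev)) * step
        amps = config.snr * config.noise_sd * config.decay_per_cue ** ev["cue_index"].to_numpy(dtype=float)
        for (onset, label), lag, a in zip(zip(ev["onset"], ev["label"]), lat, amps):
            data[:, onset:onset + N_ANALYSIS] += tone_amp * tone
            data[:, onset + lag:onset + lag + n_resp] += a * responses[label]
        out = ev.copy()
        out["latency_ms"] = lat * 1000 // config.fs
        out["amplitude"] = amps
        return out

    return _assemble(config, events, embed)


def generate_control_session(config: SynthConfig | None = None) -> SynthSession:
    """Control session: identical tone response for all four classes."""
    if config is None:
        config = SynthConfig(n_sequences=140)
    events = sequence_events(config, config.sequences_per_block or WAKE_SEQUENCES_PER_BLOCK)
    tone = tone_erp(config.fs)
    tone_amp = config.tone_snr * config.noise_sd

    def embed(data, ev, rng):
        for onset in ev["onset"]:
            data[:, onset:onset + N_ANALYSIS] += tone_amp * tone
        return ev.copy()

    return _assemble(config, events, embed)
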