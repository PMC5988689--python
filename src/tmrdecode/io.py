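"""Recording and epoch-set I/O.

Two on-disk forms are supported:

* the array-archive format — a single ``.npz`` file holding the signal
  matrix plus header arrays (sampling rate, channel names, events).  This
  round-trips bit-exactly and is what the ``simulate`` CLI writes;
* EDF(+) reading for continuous EEG, via :mod:`mne` when it is installed
  (``pip install tmrdecode[edf]``).  Channels are matched to the canonical
  16-channel montage case-insensitively and reordered; extra channels are
  ignored with a logged notice.
"""

from __future__ import annotations

import logging

import numpy as np

from .epochs import CHANNELS, EpochSet, Recording

logger = logging.getLogger(__name__)


def save_recording(path, recording: Recording) -> None:
    np.savez(
        path,
        kind=np.array("recording"),
        data=recording.data,
        fs=np.array(recording.fs),
        channel_names=np.array(recording.channel_names),
        events=recording.events,
        blocks=recording.blocks if recording.blocks is not None else np.array([]),
    )


def load_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        if str(z["kind"]) != "recording":
            raise ValueError(f"{path} is not a recording archive")
        blocks = z["blocks"]
        return Recording(
            data=z["data"],
            fs=int(z["fs"]),
            channel_names=tuple(z["channel_names"]),
            events=z["events"],
            blocks=blocks.astype(np.int64) if blocks.size else None,
        )


def save_epochs(path, epochs: EpochSet) -> None:
    np.savez(
        path,
        kind=np.array("epochs"),
        data=epochs.data,
        labels=epochs.labels,
        fs=np.array(epochs.fs),
        epoch_kind=np.array(epochs.epoch_kind),
        trial_order=epochs.trial_order,
        blocks=epochs.blocks if epochs.blocks is not None else np.array([]),
    )


def load_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        if str(z["kind"]) != "epochs":
            raise ValueError(f"{path} is not an epoch archive")
        blocks = z["blocks"]
        return EpochSet(
            data=z["data"],
            labels=z["labels"],
            fs=int(z["fs"]),
            epoch_kind=str(z["epoch_kind"]),
            trial_order=z["trial_order"],
            blocks=blocks.astype(np.int64) if blocks.size else None,
        )


def read_edf(path, events) -> Recording:
    """Read a continuous EDF(+) recording into the canonical montage.

    ``events`` is a list/array of ``(onset_sample, label)`` pairs (EDF
    annotation conventions vary by acquisition system, so markers are
    supplied explicitly).  Requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires mne; install with `pip install tmrdecode[edf]`"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    lower = {name.lower(): name for name in raw.ch_names}
    missing = [c for c in CHANNELS if c.lower() not in lower]
    if missing:
        raise ValueError(f"EDF file lacks required channels: {missing}")
    extra = [n for n in raw.ch_names if n.lower() not in {c.lower() for c in CHANNELS}]
    if extra:
        logger.info("ignoring %d non-montage channels: %s", len(extra), extra)
    picks = [lower[c.lower()] for c in CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # mne uses volts; montage is in µV
    return Recording(data=data, fs=int(round(raw.info["sfreq"])), events=events)


def save_model(path, model) -> None:
    """Serialise a trained discriminant to a portable JSON file."""
    import json

    mean, sd = model.norm_stats if model.norm_stats is not None else (None, None)
    payload = {
        "classes": model.classes.tolist(),
        "class_means": model.class_means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "ridge": model.ridge,
        "priors": model.priors.tolist(),
        "selected": None if model.selected is None else np.asarray(model.selected).tolist(),
        "norm_mean": None if mean is None else np.asarray(mean).tolist(),
        "norm_sd": None if sd is None else np.asarray(sd).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    import json

    from .classifier import TrainedModel

    with open(path) as fh:
        p = json.load(fh)
    norm_stats = None
    if p["norm_mean"] is not None:
        norm_stats = (np.asarray(p["norm_mean"]), np.asarray(p["norm_sd"]))
    return TrainedModel(
        classes=np.asarray(p["classes"]),
        class_means=np.asarray(p["class_means"]),
        pooled_covariance=np.asarray(p["pooled_covariance"]),
        ridge=p["ridge"],
        priors=np.asarray(p["priors"]),
        selected=None if p["selected"] is None else np.asarray(p["selected"]),
        norm_stats=norm_stats,
    )


def save_features(path, fm) -> None:
    """Write a feature matrix as a TSV (descriptor-string header) plus a
    JSON sidecar holding labels and normalisation statistics."""
    import json

    import pandas as pd

    path = str(path)
    df = pd.DataFrame(fm.values, columns=[str(d) for d in fm.descriptors])
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "labels": None if fm.labels is None else fm.labels.tolist(),
        "normalized": fm.normalized,
        "norm_mean": None if fm.norm_stats is None else np.asarray(fm.norm_stats[0]).tolist(),
        "norm_sd": None if fm.norm_stats is None else np.asarray(fm.norm_stats[1]).tolist(),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)
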