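"""Post-hoc analyses: behaviour, cue-repetition decay, selection consistency.

* Behavioural composite score per block of 10 sequences (120 trials):
  trials with reaction time above 1000 ms are excluded, then
  ``CS = mean(RT) / accuracy`` (lower is better).
* Decay of decoding success across repeated cues: a 240-trial sliding
  mean of per-trial correctness, correlated (Pearson) against window
  position.
* Consistency of feature selection across the 5 training repeats:
  selection-count matrices (participants × items) for features,
  electrodes, families or bands, clustered column-wise with Euclidean
  distance and average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .epochs import N_CHANNELS
from .features import BAND_ORDER, DWT_KEPT_LEVELS

RT_CUTOFF_MS = 1000.0
TRIALS_PER_BLOCK = 120  # 10 sequences x 12 items
DECAY_WINDOW = 240


@dataclass
class DecaySeries:
    """Sliding-window CCR means and their trend across cue repetitions."""

    window_means: np.ndarray
    window_length: int
    r: float
    p_value: float


@dataclass
class ConsistencyMatrix:
    """Selection counts (0–5) per participant × item, with a UPGMA tree."""

    counts: np.ndarray
    item_kind: str
    item_names: list
    linkage: np.ndarray

    def dendrogram_dict(self) -> dict:
        """The cluster tree as a nested dict (names at the leaves)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return {"leaf": self.item_names[node.id]}
            return {
                "height": float(node.dist),
                "children": [walk(node.left), walk(node.right)],
            }

        return walk(tree)


def composite_score(rt_ms, correct, trials_per_block: int = TRIALS_PER_BLOCK) -> pd.DataFrame:
    """Per-block composite score CS = mean RT / accuracy.

    Trials with RT > 1000 ms are dropped from both the RT mean and the
    accuracy denominator.  A block whose retained trials are all errors
    has an undefined CS (NaN, flagged in the ``defined`` column).
    """
    rt_ms = np.asarray(rt_ms, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if rt_ms.shape != correct.shape:
        raise ValueError("rt_ms and correct must have equal length")
    n_blocks = int(np.ceil(len(rt_ms) / trials_per_block))
    rows = []
    for b in range(n_blocks):
        sl = slice(b * trials_per_block, (b + 1) * trials_per_block)
        keep = rt_ms[sl] <= RT_CUTOFF_MS
        rt_kept, ok_kept = rt_ms[sl][keep], correct[sl][keep]
        if rt_kept.size == 0 or ok_kept.mean() == 0:
            rows.append((b, int(keep.sum()), np.nan, np.nan, np.nan, False))
            continue
        acc = ok_kept.mean()
        mean_rt = rt_kept.mean()
        rows.append((b, int(keep.sum()), mean_rt, acc, mean_rt / acc, True))
    return pd.DataFrame(
        rows, columns=["block", "n_kept", "mean_rt_ms", "accuracy", "cs", "defined"]
    )


def ccr_decay(correct_flags, window: int = DECAY_WINDOW) -> DecaySeries:
    """Sliding mean of decoding correctness across cue repetitions.

    ``correct_flags`` must be in presentation order.  Window means are
    taken at step 1; a Pearson correlation of mean vs. window start
    index quantifies the trend (NaN when the series is constant).
    """
    flags = np.asarray(correct_flags, dtype=np.float64)
    if len(flags) < window + 1:
        raise ValueError(f"need at least {window + 1} trials, got {len(flags)}")
    cs = np.concatenate([[0.0], np.cumsum(flags)])
    means = (cs[window:] - cs[:-window]) / window
    if np.ptp(means) == 0:
        return DecaySeries(means, window, np.nan, np.nan)
    r, p = stats.pearsonr(means, np.arange(len(means)))
    return DecaySeries(means, window, float(r), float(p))


def _item_mapper(item_kind: str, descriptors):
    if item_kind == "feature":
        names = [str(d) for d in descriptors]
        return names, np.arange(len(descriptors))
    if item_kind == "electrode":
        names = [f"ch{c:02d}" for c in range(1, N_CHANNELS + 1)]
        return names, np.array([d.channel - 1 for d in descriptors])
    if item_kind == "family":
        fams = ["dwt", "spectral", "time"]
        return fams, np.array([fams.index(d.family) for d in descriptors])
    if item_kind == "band":
        # DWT detail levels and spectral bands, jointly
        names = [f"D{lv}" for lv in DWT_KEPT_LEVELS] + list(BAND_ORDER)
        idx = []
        for d in descriptors:
            if d.family == "dwt":
                idx.append(DWT_KEPT_LEVELS.index(d.detail_level))
            elif d.family == "spectral":
                idx.append(len(DWT_KEPT_LEVELS) + BAND_ORDER.index(d.band))
            else:
                idx.append(-1)  # time features carry no band
        return names, np.array(idx)
    raise ValueError(f"unknown item_kind {item_kind!r}")


def selection_consistency(
    selection_results, descriptors, item_kind: str = "feature"
) -> ConsistencyMatrix:
    """Selection-frequency matrix across participants, plus its UPGMA tree.

    ``selection_results`` is a list (one entry per participant) of lists
    of :class:`~tmrdecode.selection.SelectionResult`, one per training
    repeat (5 in the standard protocol).  Counts say in how many repeats
    at least one feature mapping to the item was selected — for
    ``item_kind="feature"`` this is simply whether the feature itself was
    selected.  Columns are clustered with Euclidean distance and average
    linkage.
    """
    names, mapping = _item_mapper(item_kind, descriptors)
    m = len(descriptors)
    n_items = len(names)
    counts = np.zeros((len(selection_results), n_items), dtype=np.int64)
    for p, repeats in enumerate(selection_results):
        for sel in repeats:
            selected = np.asarray(sel.selected)
            if selected.max(initial=-1) >= m:
                raise ValueError("selection result refers to unknown feature columns")
            items = np.unique(mapping[selected])
            items = items[items >= 0]
            counts[p, items] += 1
    link = hierarchy.linkage(counts.T, method="average", metric="euclidean")
    return ConsistencyMatrix(counts=counts, item_kind=item_kind, item_names=names, linkage=link)
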