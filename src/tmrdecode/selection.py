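"""Hybrid feature selection: tertile discretization, JMI filter, wrapper.

Feature values are first discretized into three levels at the empirical
1/3 and 2/3 quantiles of each training column.  A filter stage then
greedily ranks all columns by joint mutual information (JMI) with the
class label: the first feature maximises the plug-in estimate of
``I(X; Y)``; each subsequent feature maximises the sum, over the
already-ranked features X_j, of the joint information ``I(X_k, X_j; Y)``.
Finally a wrapper stage scans the ranked list once in order, starting
from the top two features, and accepts a candidate only if it strictly
lowers the stratified 10-fold cross-validated error of the discriminant
classifier — producing a monotonically decreasing error curve and the
selected subset.

Mutual information is the plug-in (empirical-frequency) estimate in
bits, with ``0·log 0 := 0`` and no bias correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

N_LEVELS = 3
CV_FOLDS = 10


@dataclass
class SelectionResult:
    """Outcome of the filter+wrapper search on one training split."""

    ranking: np.ndarray     # full JMI ordering of all columns
    selected: np.ndarray    # accepted subset, in acceptance order
    error_curve: np.ndarray  # CV error after the initial pair and each acceptance
    cv_folds: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ranking": self.ranking.tolist(),
                    "selected": self.selected.tolist(),
                    "error_curve": self.error_curve.tolist(),
                    "cv_folds": self.cv_folds,
                    "seed": self.seed,
                },
                fh,
            )


class Discretizer:
    """Tertile discretization with cutpoints fitted on the training split."""

    def __init__(self):
        self.cutpoints_ = None

    def fit(self, values: np.ndarray) -> "Discretizer":
        values = np.asarray(values, dtype=np.float64)
        q = np.quantile(values, [1 / 3, 2 / 3], axis=0)  # linear interpolation
        self.cutpoints_ = q
        n_const = int(np.sum(q[0] == q[1]))
        if n_const:
            logger.info("%d constant/degenerate columns discretize to a single level", n_const)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.cutpoints_ is None:
            raise ValueError("Discretizer not fitted")
        values = np.asarray(values, dtype=np.float64)
        q1, q2 = self.cutpoints_
        return np.where(values <= q1, 0, np.where(values <= q2, 1, 2)).astype(np.int8)


def discretize_tertiles(fm) -> np.ndarray:
    """Fit-and-transform convenience: three quantile levels per column."""
    values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    return Discretizer().fit(values).transform(values)


def _encode_labels(labels) -> tuple[np.ndarray, int]:
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (single class)")
    return y, len(classes)


def _entropy_from_counts(counts: np.ndarray, n: int, axis=-1) -> np.ndarray:
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=axis)


def mutual_information(levels: np.ndarray, labels) -> np.ndarray:
    """Plug-in ``I(X_k; Y)`` in bits for every column of ``levels``."""
    levels = np.asarray(levels)
    y, n_classes = _encode_labels(labels)
    n, m = levels.shape
    joint = levels.astype(np.int64) + N_LEVELS * y[:, None]  # 0 .. 3*C-1
    flat = joint + (N_LEVELS * n_classes) * np.arange(m)[None, :]
    counts = np.bincount(flat.ravel(), minlength=N_LEVELS * n_classes * m)
    counts = counts.reshape(m, n_classes, N_LEVELS)
    h_xy = _entropy_from_counts(counts.reshape(m, -1), n)
    h_x = _entropy_from_counts(counts.sum(axis=1), n)
    h_y = _entropy_from_counts(counts.sum(axis=2), n)
    return h_x + h_y - h_xy


def joint_mutual_information(levels: np.ndarray, j: int, labels) -> np.ndarray:
    """Plug-in ``I((X_k, X_j); Y)`` in bits for every column k."""
    levels = np.asarray(levels)
    y, n_classes = _encode_labels(labels)
    n, m = levels.shape
    pair = levels.astype(np.int64) * N_LEVELS + levels[:, j][:, None]  # 0..8
    cells = N_LEVELS * N_LEVELS
    joint = pair + cells * y[:, None]
    flat = joint + (cells * n_classes) * np.arange(m)[None, :]
    counts = np.bincount(flat.ravel(), minlength=cells * n_classes * m)
    counts = counts.reshape(m, n_classes, cells)
    h_xy = _entropy_from_counts(counts.reshape(m, -1), n)
    h_x = _entropy_from_counts(counts.sum(axis=1), n)
    h_y = _entropy_from_counts(counts.sum(axis=2), n)
    return h_x + h_y - h_xy


def jmi_rank(levels: np.ndarray, labels) -> np.ndarray:
    """Greedy JMI ranking of all columns (deterministic, ties → lower index)."""
    levels = np.asarray(levels)
    n, m = levels.shape
    mi = mutual_information(levels, labels)
    ranking = np.empty(m, dtype=np.int64)
    remaining = np.ones(m, dtype=bool)
    first = int(np.argmax(mi))  # argmax takes the lowest index on ties
    ranking[0] = first
    remaining[first] = False
    cum = np.zeros(m)
    last = first
    for step in range(1, m):
        cum += joint_mutual_information(levels, last, labels)
        scores = np.where(remaining, cum, -np.inf)
        nxt = int(np.argmax(scores))
        ranking[step] = nxt
        remaining[nxt] = False
        last = nxt
    return ranking


def _cv_error(X, y, feature_idx, cv_folds, seed) -> float:
    """Stratified k-fold error of the discriminant on the given columns."""
    from .classifier import predict, train_ldc

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    Xs = X[:, feature_idx]
    wrong = 0
    for tr, va in skf.split(Xs, y):
        model = train_ldc(Xs[tr], y[tr])
        pred, _ = predict(model, Xs[va])
        wrong += int(np.sum(pred != y[va]))
    return wrong / len(y)


def wrapper_select(
    ranking,
    train_fm,
    labels=None,
    seed: int = 0,
    cv_folds: int = CV_FOLDS,
    scan_limit: int | None = None,
) -> SelectionResult:
    """Single forward scan of the JMI ranking with strict-decrease acceptance.

    The initial subset is the two top-ranked features.  Each remaining
    ranked feature (up to ``scan_limit`` candidates when set) is accepted
    iff it strictly lowers the stratified ``cv_folds``-fold CV error of
    the discriminant classifier; otherwise it is discarded.
    """
    ranking = np.asarray(ranking)
    if len(ranking) < 2:
        raise ValueError("ranking must contain at least two features")
    if isinstance(train_fm, FeatureMatrix):
        X = train_fm.values
        y = train_fm.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(train_fm, dtype=np.float64)
        y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < cv_folds):
        raise ValueError(
            f"stratified {cv_folds}-fold CV needs at least {cv_folds} trials per class"
        )
    selected = [int(ranking[0]), int(ranking[1])]
    best = _cv_error(X, y, selected, cv_folds, seed)
    curve = [best]
    candidates = ranking[2:]
    if scan_limit is not None:
        candidates = candidates[:scan_limit]
    for cand in candidates:
        err = _cv_error(X, y, selected + [int(cand)], cv_folds, seed)
        if err < best:
            selected.append(int(cand))
            best = err
            curve.append(err)
    return SelectionResult(
        ranking=ranking,
        selected=np.asarray(selected),
        error_curve=np.asarray(curve),
        cv_folds=cv_folds,
        seed=seed,
    )
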