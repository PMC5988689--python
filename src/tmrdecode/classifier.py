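"""Normal-density linear discriminant classification and its evaluation.

The classifier is a Gaussian class-conditional model with a shared
(pooled) covariance matrix: class posteriors are proportional to
``prior_c * N(x | mean_c, Sigma)``, which yields linear decision
boundaries and, importantly, calibrated posterior probabilities that the
sleep decoder's fallback rules consume.  The pooled covariance is
ridge-stabilised with ``lambda = 1e-6 × mean(diag)``.

Evaluation follows a repeated class-balanced hold-out protocol: the
trials of each class are split 60 % / 40 % into training and evaluation
sets, the complete pipeline (normalisation → discretization → JMI
ranking → wrapper selection → training) is run on the 60 %, and the
correct classification rate

    CCR = n_correct / n_total

is measured on the held-out 40 %.  The whole process is repeated five
times with fresh random splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .epochs import ANALYSIS_KIND, EpochSet
from .features import FeatureMatrix, apply_normalizer, assemble_features, fit_normalizer

RIDGE_SCALE = 1e-6


@dataclass
class TrainedModel:
    """Fitted discriminant: per-class means, pooled covariance, priors."""

    classes: np.ndarray
    class_means: np.ndarray          # (n_classes, d)
    pooled_covariance: np.ndarray    # (d, d), ridge included
    ridge: float
    priors: np.ndarray
    selected: np.ndarray | None = None   # column indices into the full feature space
    norm_stats: tuple | None = None
    _chol: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self._chol is None:
            self._chol = linalg.cholesky(self.pooled_covariance, lower=True)


@dataclass
class EvaluationResult:
    """Per-repeat hold-out CCRs with the selection result of each repeat."""

    per_repeat_ccr: np.ndarray
    mean_ccr: float
    sd_ccr: float
    selections: list
    models: list
    split: tuple = (0.6, 0.4)


def train_ldc(fm, labels=None) -> TrainedModel:
    """Fit the shared-covariance Gaussian discriminant.

    ``fm`` may be a :class:`FeatureMatrix` (labels taken from it unless
    given) or a plain (n, d) array with explicit ``labels``.
    """
    if isinstance(fm, FeatureMatrix):
        X = fm.values
        y = fm.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(fm, dtype=np.float64)
        y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("need at least 2 trials per class")
    n, d = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    resid = X - means[np.searchsorted(classes, y)]
    cov = resid.T @ resid / max(n - len(classes), 1)
    ridge = RIDGE_SCALE * float(np.mean(np.diag(cov))) if d else 0.0
    cov = cov + ridge * np.eye(d)
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance singular even after ridge "
            f"(condition number ~{np.linalg.cond(cov):.3g})"
        ) from exc
    return TrainedModel(
        classes=classes,
        class_means=means,
        pooled_covariance=cov,
        ridge=ridge,
        priors=counts / n,
        _chol=chol,
    )


def predict(model: TrainedModel, fm):
    """Class labels and posterior matrix for rows of ``fm``.

    Rows must already be normalised with ``model.norm_stats`` and
    restricted to ``model.selected`` columns when those are set.
    Ties break toward the lowest class label.
    """
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"feature mismatch: model expects {model.class_means.shape[1]} columns, "
            f"got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    # log N(x|mu,Sigma) up to a shared constant, via the Cholesky factor
    z = linalg.solve_triangular(
        model._chol, (X[:, :, None] - model.class_means.T[None]), lower=True
    )
    log_like = -0.5 * np.einsum("ndc,ndc->nc", z, z)
    log_post = log_like + np.log(model.priors)[None]
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(post, axis=1)]
    return labels, post


def ccr(y_true, y_pred) -> float:
    """Correct classification rate, as a fraction in [0, 1]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty label vector")
    return float(np.mean(y_true == y_pred))


def balanced_split(labels, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced random split; returns (train_idx, eval_idx).

    Per class, ``round(train_frac × n_c)`` trials go to the training set;
    counts are required to be equal across classes so both sets stay
    balanced.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(set(counts)) > 1:
        raise ValueError(
            f"per-class counts must be equal for a balanced split, got {dict(zip(classes, counts))}"
        )
    train_idx, eval_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        k = int(round(train_frac * len(idx)))
        train_idx.append(idx[:k])
        eval_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(eval_idx))


def evaluate_repeated_splits(
    epochs: EpochSet,
    repeats: int = 5,
    seed: int = 0,
    scan_limit: int | None = None,
    train_frac: float = 0.6,
    cv_folds: int = 10,
) -> EvaluationResult:
    """Repeated class-balanced 60/40 evaluation of the full pipeline.

    Each repeat draws a fresh balanced split, runs normalisation,
    tertile discretization, JMI ranking and the wrapper search on the
    training 60 %, then scores the resulting model on the held-out 40 %.
    ``scan_limit`` caps the number of wrapper candidates examined (None
    scans the whole ranking).
    """
    from .selection import Discretizer, jmi_rank, wrapper_select

    if epochs.epoch_kind != ANALYSIS_KIND:
        raise ValueError("evaluation requires 400 ms analysis epochs")
    fm = assemble_features(epochs)
    streams = np.random.SeedSequence(seed).spawn(repeats)
    ccrs, selections, models = [], [], []
    for rep in range(repeats):
        rng = np.random.default_rng(streams[rep])
        rep_seed = int(streams[rep].generate_state(1)[0] % (2**31))
        tr, ev = balanced_split(fm.labels, train_frac, rng)
        train = FeatureMatrix(fm.values[tr], fm.descriptors, labels=fm.labels[tr])
        evalu = FeatureMatrix(fm.values[ev], fm.descriptors, labels=fm.labels[ev])
        stats = fit_normalizer(train)
        train_n = apply_normalizer(train, stats)
        eval_n = apply_normalizer(evalu, stats)
        disc = Discretizer().fit(train_n.values)
        ranking = jmi_rank(disc.transform(train_n.values), train_n.labels)
        sel = wrapper_select(
            ranking, train_n, train_n.labels,
            seed=rep_seed, scan_limit=scan_limit, cv_folds=cv_folds,
        )
        model = train_ldc(train_n.values[:, sel.selected], train_n.labels)
        model.selected = np.asarray(sel.selected)
        model.norm_stats = stats
        pred, _ = predict(model, eval_n.values[:, sel.selected])
        ccrs.append(ccr(eval_n.labels, pred))
        selections.append(sel)
        models.append(model)
    ccrs = np.asarray(ccrs)
    return EvaluationResult(
        per_repeat_ccr=ccrs,
        mean_ccr=float(ccrs.mean()),
        sd_ccr=float(ccrs.std(ddof=1)) if repeats > 1 else 0.0,
        selections=selections,
        models=models,
        split=(train_frac, 1 - train_frac),
    )
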