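"""Shrinkage-regularized LDA and temporal-generalization decoding.

A two-class linear discriminant is trained on sensor patterns at one
time bin and evaluated at every time bin, giving a train-time x
test-time accuracy matrix (50 x 50 on the default grid).  The pooled
within-class covariance is ridge-regularized by adding the identity
scaled by a fraction (default 0.01) of the mean of its diagonal, which
guarantees invertibility for rank-deficient pattern sets.

The design is pure transfer — training and testing sets are always
disjoint trial sets (old scenes -> new scenes within the localizer, the
full localizer -> each degraded condition) — so there is no
cross-validation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochsSet

CATEGORY_LABELS = ("outdoor", "indoor")  # class 0, class 1


@dataclass
class DecoderConfig:
    #: ridge strength as a fraction of mean(diag(pooled covariance))
    shrinkage_fraction: float = 0.01
    #: radius (in bins) of the diagonal time-course average
    diagonal_radius_bins: int = 2

    def __post_init__(self) -> None:
        if self.shrinkage_fraction <= 0:
            raise ValueError("shrinkage_fraction must be > 0 for invertibility")
        if self.diagonal_radius_bins < 0:
            raise ValueError("diagonal_radius_bins must be >= 0")


@dataclass
class LDAModel:
    weights: np.ndarray  # one weight per channel
    bias: float
    class_labels: tuple = (0, 1)


@dataclass
class DecodingMatrix:
    """Train-time x test-time accuracy grid for one subject/condition."""

    accuracy: np.ndarray
    times_ms: np.ndarray
    subject_id: str = ""
    train_set_label: str = ""
    test_condition_label: str = ""
    n_train: int = 0
    n_test: int = 0

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy, dtype=float)
        if acc.min() < 0 or acc.max() > 1:
            raise ValueError("accuracies must lie in [0, 1]")
        self.accuracy = acc


def train_lda(
    patterns: np.ndarray, labels: np.ndarray, config: DecoderConfig | None = None
) -> LDAModel:
    """Fit the two-class shrinkage LDA.

    ``patterns`` is samples x channels; ``labels`` binary (0/1).  The
    pooled within-class covariance uses the unbiased two-class
    denominator ``n - 2``; the bias places the decision boundary at the
    midpoint of the projected class means (equal priors — the design is
    balanced throughout).
    """
    config = config or DecoderConfig()
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("patterns must be samples x channels, aligned with labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    mu0 = X[y == classes[0]].mean(axis=0)
    mu1 = X[y == classes[1]].mean(axis=0)
    R0 = X[y == classes[0]] - mu0
    R1 = X[y == classes[1]] - mu1
    cov = (R0.T @ R0 + R1.T @ R1) / max(n - 2, 1)
    ridge = config.shrinkage_fraction * float(np.mean(np.diag(cov)))
    if ridge == 0.0:
        raise ValueError(
            "all-zero within-class scatter: mean(diag) = 0 leaves the "
            "regularized covariance singular"
        )
    cov_reg = cov + ridge * np.eye(cov.shape[0])
    w = np.linalg.solve(cov_reg, mu1 - mu0)
    b = -float(w @ (mu0 + mu1)) / 2.0
    return LDAModel(weights=w, bias=b, class_labels=(classes[0], classes[1]))


def decision_scores(model: LDAModel, patterns: np.ndarray) -> np.ndarray:
    X = np.asarray(patterns, dtype=float)
    if X.shape[-1] != model.weights.size:
        raise ValueError(
            f"pattern width {X.shape[-1]} does not match model "
            f"({model.weights.size} channels)"
        )
    return X @ model.weights + model.bias


def predict(model: LDAModel, patterns: np.ndarray) -> np.ndarray:
    """Predicted class labels; exact ties on the boundary go to class 0."""
    scores = decision_scores(model, patterns)
    c0, c1 = model.class_labels
    return np.where(scores > 0, c1, c0)


def accuracy_score(model: LDAModel, patterns: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(predict(model, patterns) == np.asarray(labels)))


def time_generalization(
    train_epochs: EpochsSet,
    train_labels: np.ndarray,
    test_epochs: EpochsSet,
    test_labels: np.ndarray,
    config: DecoderConfig | None = None,
    train_ids: np.ndarray | None = None,
    test_ids: np.ndarray | None = None,
    allow_overlap: bool = False,
    subject_id: str = "",
    train_set_label: str = "",
    test_condition_label: str = "",
) -> DecodingMatrix:
    """Train at every time bin, test at every time bin.

    Entry (i, j) is the accuracy of the classifier trained on patterns
    at train bin i and evaluated on patterns at test bin j.  When trial
    identifiers are supplied for both sides, overlapping identities are
    rejected unless ``allow_overlap`` is set: the scheme is transfer
    decoding, not cross-validation.
    """
    config = config or DecoderConfig()
    if train_epochs.channel_ids != test_epochs.channel_ids:
        raise ValueError("train and test must share the channel set")
    if not np.array_equal(train_epochs.times_ms, test_epochs.times_ms):
        raise ValueError("train and test must share the time grid")
    if train_ids is not None and test_ids is not None and not allow_overlap:
        overlap = set(np.asarray(train_ids).tolist()) & set(np.asarray(test_ids).tolist())
        if overlap:
            raise ValueError(
                f"train and test share {len(overlap)} trial identities; "
                "pass allow_overlap=True only if this is intended"
            )
    n_t = train_epochs.n_times
    y_test = np.asarray(test_labels)
    acc = np.empty((n_t, n_t))
    test_data = test_epochs.data  # (n_test, n_ch, n_t)
    for i in range(n_t):
        model = train_lda(train_epochs.data[:, :, i], train_labels, config)
        scores = np.einsum("nct,c->nt", test_data, model.weights) + model.bias
        c0, c1 = model.class_labels
        pred = np.where(scores > 0, c1, c0)
        acc[i] = (pred == y_test[:, None]).mean(axis=0)
    return DecodingMatrix(
        accuracy=acc,
        times_ms=train_epochs.times_ms.copy(),
        subject_id=subject_id,
        n_train=train_epochs.n_trials,
        n_test=test_epochs.n_trials,
        train_set_label=train_set_label,
        test_condition_label=test_condition_label,
    )


def category_labels(table: pd.DataFrame) -> np.ndarray:
    """Binary labels from the category column (outdoor -> 0, indoor -> 1)."""
    cats = table["category"].to_numpy()
    unknown = set(cats) - set(CATEGORY_LABELS)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return (cats == CATEGORY_LABELS[1]).astype(int)


def cross_decode_subject(
    localizer: tuple[EpochsSet, pd.DataFrame],
    main: tuple[EpochsSet, pd.DataFrame],
    config: DecoderConfig | None = None,
    main_conditions: tuple[str, ...] = ("scene", "scene_with_object", "object"),
) -> dict[str, DecodingMatrix]:
    """The study's four matrices for one subject.

    * ``"intact"`` — within-localizer: train on old scenes (60 averaged
      exemplars), test on new scenes (60);
    * one matrix per main-experiment condition — train on the full
      localizer (120), test on that condition's 30 averaged exemplars.

    Inputs must already be preprocessed (exemplar-averaged, smoothed,
    channel-selected).  Sample counts deviating from the canonical
    design are tolerated with a warning; missing conditions are errors.
    """
    import warnings

    config = config or DecoderConfig()
    loc_epochs, loc_table = localizer
    main_epochs, main_table = main
    out: dict[str, DecodingMatrix] = {}

    is_old = loc_table["condition"].to_numpy() == "old"
    old = loc_epochs.select_trials(is_old)
    new = loc_epochs.select_trials(~is_old)
    if old.n_trials != 60 or new.n_trials != 60:
        warnings.warn(
            f"localizer has {old.n_trials} old / {new.n_trials} new samples "
            "(canonical design: 60/60)",
            stacklevel=2,
        )
    out["intact"] = time_generalization(
        old,
        category_labels(loc_table.loc[is_old]),
        new,
        category_labels(loc_table.loc[~is_old]),
        config,
        subject_id=loc_epochs.subject_id,
        train_set_label="localizer-old",
        test_condition_label="localizer-new",
    )

    loc_labels = category_labels(loc_table)
    for cond in main_conditions:
        sel = main_table["condition"].to_numpy() == cond
        if not sel.any():
            raise ValueError(f"main experiment lacks condition {cond!r}")
        test = main_epochs.select_trials(sel)
        if test.n_trials != 30:
            warnings.warn(
                f"condition {cond!r} has {test.n_trials} samples "
                "(canonical design: 30)",
                stacklevel=2,
            )
        out[cond] = time_generalization(
            loc_epochs,
            loc_labels,
            test,
            category_labels(main_table.loc[sel]),
            config,
            subject_id=main_epochs.subject_id,
            train_set_label="localizer-all",
            test_condition_label=cond,
        )
    return out


def diagonal_timecourse(matrix: DecodingMatrix, radius_bins: int = 2) -> np.ndarray:
    """Same-time decoding: the matrix diagonal averaged over the square
    window of entries (i, j) with ``|i - t| <= r`` and ``|j - t| <= r``,
    truncated at the matrix edges."""
    acc = matrix.accuracy
    if acc.shape[0] != acc.shape[1]:
        raise ValueError("diagonal time course needs a square matrix")
    n = acc.shape[0]
    out = np.empty(n)
    for t in range(n):
        lo, hi = max(t - radius_bins, 0), min(t + radius_bins, n - 1)
        out[t] = acc[lo : hi + 1, lo : hi + 1].mean()
    return out
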