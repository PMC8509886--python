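"""Random-undersampling boosting (RUSBoost) and leave-one-freezer-out
cross-validation.

The classifier is a boosted ensemble of split-limited CART trees in
which every boosting iteration first randomly undersamples the majority
class to exact class balance, fits the weak learner on the balanced
subset, and then applies AdaBoost.M1-style weight updates on the full
training set. This keeps the weak learners honest on heavily imbalanced
window data (FOG windows are a small minority of a walking session).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core import Session
from .labeling import build_label_track, merge_episodes
from .windowing import detection_labels, prediction_labels, segment
from .features import feature_matrix

TASKS = ("detection", "prediction")

_EPS = 1e-10


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Boosted decision-tree ensemble with per-iteration random
    undersampling of the majority class.

    Parameters
    ----------
    n_estimators : int
        Number of boosting rounds (trees), default 100.
    max_splits : int
        Maximum internal splits per tree (equivalently ``max_splits + 1``
        leaves), default 5.
    learning_rate : float
        Shrinkage applied to the AdaBoost weight updates, default 1.0.
    random_state : int or None
        Seed for undersampling and tree fitting; fixed seed gives
        bit-identical models.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    estimators_ : list of fitted trees
    estimator_weights_ : ndarray of boosting weights (log(1/beta))
    n_features_in_ : int
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_splits: int = 5,
        learning_rate: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_splits = max_splits
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_estimators < 1 or self.max_splits < 1:
            raise ValueError("n_estimators and max_splits must be >= 1")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                "training data contains a single class; need both classes"
            )
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        n = len(y_enc)
        counts = np.bincount(y_enc, minlength=2)
        minority = int(np.argmin(counts))
        idx_min = np.flatnonzero(y_enc == minority)
        idx_maj = np.flatnonzero(y_enc != minority)

        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        weights: list[float] = []
        failures = 0
        for _ in range(self.n_estimators):
            sel = rng.choice(idx_maj, size=len(idx_min), replace=False)
            idx = np.concatenate([idx_min, sel])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            sw = w[idx]
            tree.fit(X[idx], y_enc[idx], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            miss = pred != y_enc
            err = float(w[miss].sum() / w.sum())
            if err >= 0.5:
                # weak learner no better than chance on the weighted set;
                # redraw the undersample (deterministically via rng state)
                failures += 1
                if failures >= 25:
                    break
                continue
            failures = 0
            err = max(err, _EPS)
            beta = err / (1.0 - err)
            alpha = self.learning_rate * np.log(1.0 / beta)
            self.estimators_.append(tree)
            weights.append(alpha)
            w = w * np.power(beta, self.learning_rate * (~miss))
            w /= w.sum()
            if err <= _EPS:
                break  # perfect weak learner; further rounds are no-ops
        if not self.estimators_:
            raise RuntimeError("boosting failed: no usable weak learner found")
        self.estimator_weights_ = np.asarray(weights)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Weighted vote margin for the positive (``classes_[1]``) class."""
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        score = np.zeros(len(X))
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            score += alpha * (2.0 * tree.predict(X) - 1.0)
        return score

    def predict(self, X) -> np.ndarray:
        """Hard binary output by the sign of the weighted vote."""
        score = self.decision_function(X)
        return self.classes_[(score > 0).astype(int)]


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble hyperparameters: 100 trees, at most 5 splits each."""

    n_trees: int = 100
    max_splits: int = 5
    learning_rate: float = 1.0
    seed: int = 0

    def classifier(self, random_state: int | None = None) -> RUSBoostClassifier:
        return RUSBoostClassifier(
            n_estimators=self.n_trees,
            max_splits=self.max_splits,
            learning_rate=self.learning_rate,
            random_state=self.seed if random_state is None else random_state,
        )


@dataclass
class FoldResult:
    """Held-out predictions for one leave-one-freezer-out fold."""

    participant_id: str
    predictions: np.ndarray  # binary, aligned with the held-out windows
    truths: np.ndarray
    window_start_s: np.ndarray
    window_end_s: np.ndarray
    merged_episodes: list = field(default_factory=list)
    n_training_windows: int = 0
    training_participants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.predictions) != len(self.truths):
            raise ValueError("predictions and truths must be equal length")


def _session_table(
    session: Session,
    mt_s: float,
    task: str,
    prefog_s: float,
    length_s: float,
    shift_s: float,
    feature_cache: dict | None,
):
    windows = segment(session.duration_s, session.fs, length_s, shift_s)
    if feature_cache is not None and session.participant_id in feature_cache:
        X = feature_cache[session.participant_id]
    else:
        X = feature_matrix(session, windows)
        if feature_cache is not None:
            feature_cache[session.participant_id] = X
    merged = merge_episodes(session.episodes, mt_s)
    if task == "detection":
        track = build_label_track(merged, session.duration_s, session.fs, prefog_s)
        y = detection_labels(windows, track)
    else:
        y = prediction_labels(windows, merged, prefog_s)
    starts = np.array([w.start_s for w in windows])
    ends = np.array([w.end_s for w in windows])
    return X, y, starts, ends, merged


def loso_cv(
    cohort: list[Session],
    task: str,
    mt_s: float = 0.0,
    config: EnsembleConfig | None = None,
    prefog_s: float = 2.0,
    length_s: float = 1.0,
    shift_s: float = 0.2,
    feature_cache: dict | None = None,
) -> list[FoldResult]:
    """Leave-one-freezer-out cross-validation for one task and threshold.

    One fold per participant who froze; the training pool for a fold is
    every *other* participant's windows — freezers and non-freezers
    alike. Merging with ``mt_s`` and ternary labeling are applied before
    windowing, identically on the training and test side. Fold model
    seeds derive from ``config.seed`` and the fold index only, so the
    same fold uses the same model seed across thresholds and tasks.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    config = config or EnsembleConfig()
    freezers = [s for s in cohort if s.is_freezer]
    if len(freezers) < 2:
        raise ValueError("leave-one-freezer-out needs at least 2 freezers")

    tables = {
        s.participant_id: _session_table(
            s, mt_s, task, prefog_s, length_s, shift_s, feature_cache
        )
        for s in cohort
    }

    results = []
    for fold_idx, held_out in enumerate(freezers):
        train_ids = [s.participant_id for s in cohort if s is not held_out]
        X_train = np.vstack([tables[pid][0] for pid in train_ids])
        y_train = np.concatenate([tables[pid][1] for pid in train_ids])
        seed = int(
            np.random.SeedSequence([config.seed, fold_idx]).generate_state(1)[0]
            % 2**31
        )
        clf = config.classifier(random_state=seed)
        clf.fit(X_train, y_train.astype(int))
        X_test, y_test, starts, ends, merged = tables[held_out.participant_id]
        preds = clf.predict(X_test).astype(bool)
        results.append(
            FoldResult(
                participant_id=held_out.participant_id,
                predictions=preds,
                truths=y_test.astype(bool),
                window_start_s=starts,
                window_end_s=ends,
                merged_episodes=merged,
                n_training_windows=len(X_train),
                training_participants=tuple(train_ids),
            )
        )
    return results
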