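"""Movement separability via multinomial logistic (SoftMax) regression.

Separability of a representation — the original 20-D signals, a k-D latent
manifold, or the reconstructed 20-D signals — is measured as the
cross-validated accuracy of a plain linear SoftMax classifier: higher
accuracy means movement classes occupy more linearly separable regions of
that space.  The classifier is deliberately simple (no hyperparameters to
tune); it probes the geometry of the representation, not ceiling
performance.

The model is unregularized multinomial logistic regression fit by L-BFGS to
gradient tolerance 1e-6 (capped at 5,000 iterations; predictions stabilize
long before the weights do on separable data).  Folds are stratified by
class by default, preserving class balance in small datasets; a trial-
grouped mode is available to keep whole trials on one side of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold


class SeparabilityError(ValueError):
    """Raised on degenerate classification inputs."""


@dataclass
class SeparabilityResult:
    """Cross-validated SoftMax accuracy for one representation of one dataset."""

    space: str
    method: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    n_folds: int = 5


def _validate(X: np.ndarray, labels: np.ndarray):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise SeparabilityError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise SeparabilityError("features contain non-finite values")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SeparabilityError("need at least 2 movement classes")
    return X, labels, classes, counts


def softmax_fit(X: np.ndarray, labels: np.ndarray, seed: int = 0) -> LogisticRegression:
    """Fit an unregularized multinomial logistic model (one weight vector and
    bias per class, softmax link) by minimizing multiclass cross-entropy."""
    X, labels, _, counts = _validate(X, labels)
    if counts.min() < 1:
        raise SeparabilityError("every class needs at least one sample")
    # C=inf disables the L2 penalty: plain unregularized cross-entropy
    clf = LogisticRegression(
        C=np.inf,
        solver="lbfgs",
        tol=1e-6,
        max_iter=5_000,
        random_state=seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # on linearly separable classes the unregularized weights diverge in
        # norm and lbfgs stops at the iteration cap; the decision boundary
        # (hence accuracy) stabilizes long before, so the cap is benign
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    return clf


def softmax_cv_accuracy(
    X: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    space: str = "original_20d",
    method: str = "none",
    groups: np.ndarray | None = None,
) -> SeparabilityResult:
    """Stratified k-fold cross-validated SoftMax accuracy (percent).

    Pass ``groups`` (e.g., trial ids) to use grouped folds instead of
    stratified ones, keeping each trial's autocorrelated samples on a single
    side of every split.
    """
    X, labels, _, counts = _validate(X, labels)
    if groups is None:
        if counts.min() < folds:
            raise SeparabilityError(
                f"smallest class has {counts.min()} samples, fewer than folds={folds}; "
                "use fewer folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, labels)
    else:
        groups = np.asarray(groups)
        if len(np.unique(groups)) < folds:
            raise SeparabilityError("fewer groups than folds")
        split_iter = GroupKFold(n_splits=folds).split(X, labels, groups)

    accuracies = []
    for train_idx, test_idx in split_iter:
        if len(np.unique(labels[train_idx])) < 2:
            raise SeparabilityError("a training fold lost all but one class")
        clf = softmax_fit(X[train_idx], labels[train_idx], seed=seed)
        accuracies.append(100.0 * clf.score(X[test_idx], labels[test_idx]))
    accuracies = np.asarray(accuracies)
    return SeparabilityResult(
        space=space,
        method=method,
        fold_accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        n_folds=folds,
    )
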