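"""Fisher's Linear Discriminant odor classification from color patterns.

The stability of color-odor associations within a group is assessed by
training an FLD on the color patterns of two of three participant folds
and classifying the held-out fold's patterns by odor.  Rotating the test
fold and refolding many times yields a stable accuracy sample; a
color-permutation null (independent per-trial permutations of color
identity) yields the accuracy distribution under the hypothesis that
associations are not stable.  Chance level is ``1 / n_odors``.

With 72 features and ~28 training patterns the pooled within-class
covariance is singular, so shrinkage toward ``(trace/d) * I`` is
mandatory; the default coefficient is the analytic variance-minimizing
(Ledoit-Wolf) estimate on the pooled within-class deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage

from .data import Dataset
from .errors import ValidationError
from .patterns import participant_counts, permute_colors

Shrinkage = Union[str, float]


@dataclass(frozen=True)
class FldModel:
    """Shared-covariance Gaussian classifier with equal class priors."""

    class_labels: tuple
    class_means: np.ndarray  # (k, d)
    covariance: np.ndarray  # (d, d), positive definite after shrinkage
    shrinkage: float

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("covariance must be symmetric")
        try:
            cho = linalg.cho_factor(cov, lower=True)
        except linalg.LinAlgError:
            raise ValidationError(
                "shrunk covariance is not positive definite; "
                "increase the shrinkage coefficient"
            )
        object.__setattr__(self, "_cho", cho)


def fld_fit(
    X: np.ndarray, labels: Sequence, shrinkage: Shrinkage = "auto"
) -> FldModel:
    """Fit the FLD: class means + shrunk pooled within-class covariance.

    The pooled covariance uses the maximum-likelihood denominator ``n``
    (so duplicating every training pattern leaves the model unchanged) and
    is shrunk as ``(1 - s) * S + s * (trace(S)/d) * I``.  ``shrinkage``
    is a coefficient in [0, 1] or ``"auto"`` for the analytic
    variance-minimizing (Ledoit-Wolf) estimate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (n_samples, n_features)")
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValidationError("labels length does not match X")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    n, d = X.shape
    means = np.stack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
    D = X - means[y_idx]
    S = D.T @ D / n
    mu = float(np.trace(S)) / d
    if mu <= 0.0:
        # no within-class scatter at all: fall back to the identity metric,
        # i.e. nearest class mean
        return FldModel(tuple(classes.tolist()), means, np.eye(d), 1.0)
    if shrinkage == "auto":
        s = float(ledoit_wolf_shrinkage(D, assume_centered=True))
    else:
        s = float(shrinkage)
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"shrinkage must be in [0, 1], got {s}")
    if s == 0.0 and np.linalg.matrix_rank(D) < d:
        raise ValidationError(
            "pooled covariance is singular with shrinkage=0; "
            "use a positive shrinkage coefficient"
        )
    cov = (1.0 - s) * S + s * mu * np.eye(d)
    return FldModel(tuple(classes.tolist()), means, cov, s)


def fld_predict(model: FldModel, X: np.ndarray) -> np.ndarray:
    """Assign each pattern the class with the highest discriminant score.

    Scores are the equal-prior shared-covariance Gaussian discriminants
    ``x' S^-1 m_k - 0.5 m_k' S^-1 m_k``; ties go to the first label in
    class-label order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = model.class_means
    if X.shape[1] != means.shape[1]:
        raise ValidationError(
            f"pattern dimension {X.shape[1]} != model dimension {means.shape[1]}"
        )
    W = linalg.cho_solve(model._cho, means.T)  # (d, k)
    scores = X @ W - 0.5 * np.sum(means.T * W, axis=0)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum
    labels = np.asarray(model.class_labels)
    return labels[idx]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AccuracyResult:
    """Observed accuracy sample, permutation null, and p-value."""

    group: str
    accuracy_sample: np.ndarray
    null_distribution: np.ndarray
    p: float

    def __post_init__(self) -> None:
        for name in ("accuracy_sample", "null_distribution"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.size and not ((a >= 0).all() and (a <= 1).all()):
                raise ValidationError(f"{name}: accuracies must lie in [0, 1]")
            object.__setattr__(self, name, a)
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"p-value {self.p} outside (0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy_sample.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracy_sample.std(ddof=1))


def _partition(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    return np.array_split(rng.permutation(n), n_folds)


def _cv_pass(
    C: np.ndarray,
    folds: list[np.ndarray],
    shrinkage: Shrinkage,
    normalize: bool,
    feature_mask: Optional[np.ndarray],
) -> float:
    """One cross-validation pass: rotate every fold as the test fold once."""
    n_odors = C.shape[1]
    counts = np.stack([C[m].sum(axis=0) for m in folds]).astype(float)
    if normalize:
        sizes = np.array([len(m) for m in folds], dtype=float)
        counts /= sizes[:, None, None]
    if feature_mask is not None:
        counts = counts[:, :, feature_mask]
    y = np.arange(n_odors)
    correct = 0
    for t in range(len(folds)):
        train = [f for f in range(len(folds)) if f != t]
        X = counts[train].reshape(-1, counts.shape[-1])
        model = fld_fit(X, np.tile(y, len(train)), shrinkage=shrinkage)
        pred = fld_predict(model, counts[t])
        correct += int((pred == y).sum())
    return correct / (len(folds) * n_odors)


def _check_folds(n_parts: int, n_folds: int) -> None:
    if n_folds < 2 or n_folds > n_parts:
        raise ValidationError(
            f"n_folds={n_folds} invalid for {n_parts} participants"
        )


def cv_accuracy(
    dataset: Dataset,
    group: str,
    n_folds: int = 3,
    n_shuffles: int = 1000,
    seed: int = 0,
    shrinkage: Shrinkage = "auto",
    normalize: bool = True,
    feature_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Cross-validated accuracy sample over ``n_shuffles`` random refoldings.

    Per shuffling, participants are partitioned into ``n_folds`` near-equal
    folds, patterns are compiled per fold, and every fold serves as the
    test set once; the pass accuracy is the fraction of held-out
    (fold, odor) patterns classified correctly.  Deterministic given
    ``seed``.
    """
    _, C = participant_counts(dataset, group)
    _check_folds(C.shape[0], n_folds)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return np.array(
        [
            _cv_pass(C, _partition(C.shape[0], n_folds, rng), shrinkage,
                     normalize, feature_mask)
            for _ in range(n_shuffles)
        ]
    )


def permutation_test(
    dataset: Dataset,
    group: str,
    n_folds: int = 3,
    n_shuffles: int = 1000,
    n_permutations: int = 10000,
    seed: int = 0,
    shrinkage: Shrinkage = "auto",
    normalize: bool = True,
    feature_mask: Optional[np.ndarray] = None,
    per_trial: bool = True,
    nested: bool = False,
) -> AccuracyResult:
    """Observed accuracy sample versus the color-permutation null.

    Each null repetition permutes color identity independently per
    (participant, odor) trial (``per_trial=True``; a single shared
    permutation per repetition is available but preserves within-group
    agreement and is not a stability null), then runs one fresh
    cross-validation pass (``nested=True`` runs ``n_shuffles`` refoldings
    per repetition instead).  The p-value is the add-one-smoothed fraction
    of null accuracies at or above the observed mean:
    ``(1 + #{null >= mean}) / (1 + n_permutations)``.
    """
    _, C = participant_counts(dataset, group)
    _check_folds(C.shape[0], n_folds)
    obs_ss, null_ss = np.random.SeedSequence(seed).spawn(2)
    obs_rng = np.random.default_rng(obs_ss)
    n_parts = C.shape[0]
    sample = np.array(
        [
            _cv_pass(C, _partition(n_parts, n_folds, obs_rng), shrinkage,
                     normalize, feature_mask)
            for _ in range(n_shuffles)
        ]
    )
    null_rng = np.random.default_rng(null_ss)
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        Cp = permute_colors(C, null_rng, per_trial=per_trial)
        if nested:
            accs = [
                _cv_pass(Cp, _partition(n_parts, n_folds, null_rng), shrinkage,
                         normalize, feature_mask)
                for _ in range(n_shuffles)
            ]
            null[r] = float(np.mean(accs))
        else:
            null[r] = _cv_pass(Cp, _partition(n_parts, n_folds, null_rng),
                               shrinkage, normalize, feature_mask)
    mean_obs = float(sample.mean())
    p = (1 + int((null >= mean_obs).sum())) / (1 + n_permutations)
    return AccuracyResult(
        group=group.strip().lower(), accuracy_sample=sample,
        null_distribution=null, p=p,
    )
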