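"""Representational similarity analysis of color-odor association patterns.

First order: per group, a representational dissimilarity matrix (RDM) over
odors, where cell (i, j) is ``1 - Pearson r`` between the pooled
whole-group 72-feature color patterns of odors i and j; the diagonal is 0
by construction.  A null distribution of dissimilarities is obtained by
repeatedly shuffling color identity per trial and recomputing the RDM
(the same null scheme as the classifier); a participant-resampling
bootstrap is available for uncertainty (rather than null) estimation.

Second order: the between-group "isomorphism" RDM, where cell (a, b) is
the dissimilarity between groups a's and b's odor RDMs, computed as
``1 - r`` between their vectorized strict upper triangles (Pearson by
default, Spearman behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .errors import UndefinedCorrelationError, ValidationError
from .patterns import compile_pattern, participant_counts, permute_colors

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class Rdm:
    """Symmetric dissimilarity matrix with labeled rows/columns."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    null_distribution: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.labels)
        if m.shape != (k, k):
            raise ValidationError(f"matrix shape {m.shape} != ({k}, {k})")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("matrix must be symmetric")
        if (np.diag(m) != 0.0).any():
            raise ValidationError("diagonal must be exactly zero")
        if m.min() < -_RANGE_TOL or m.max() > 2.0 + _RANGE_TOL:
            raise ValidationError("dissimilarities must lie in [0, 2]")
        object.__setattr__(self, "matrix", np.clip(m, 0.0, 2.0))

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    def reordered(self, labels: tuple[str, ...]) -> "Rdm":
        """The same RDM with rows/columns permuted to a new label order."""
        if sorted(labels) != sorted(self.labels):
            raise ValidationError("labels are not a permutation of this RDM's")
        idx = [self.labels.index(l) for l in labels]
        return Rdm(tuple(labels), self.matrix[np.ix_(idx, idx)],
                   self.null_distribution)


def pattern_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - Pearson r`` between two pattern vectors (0 = identical shape)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape or a.size < 3:
        raise ValidationError("patterns must be equal-length 1-D vectors (>= 3)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant pattern"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def _rdm_from_patterns(labels: tuple[str, ...], X: np.ndarray) -> Rdm:
    """Build an RDM from a (k, n_features) pattern matrix."""
    if (np.ptp(X, axis=1) == 0).any():
        bad = labels[int(np.flatnonzero(np.ptp(X, axis=1) == 0)[0])]
        raise UndefinedCorrelationError(f"pattern for {bad!r} is constant")
    D = 1.0 - np.corrcoef(X)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return Rdm(labels, np.clip(D, 0.0, 2.0))


def compute_rdm(
    dataset: Dataset, group: str, feature_mask: Optional[np.ndarray] = None
) -> Rdm:
    """First-order RDM over odors from pooled whole-group patterns.

    ``feature_mask`` restricts the pattern features (e.g. the first 36
    positions for a congruent-choices-only RDM).
    """
    X = np.stack(
        [
            compile_pattern(dataset, group, odor).counts.astype(float)
            for odor in dataset.odors
        ]
    )
    if feature_mask is not None:
        X = X[:, feature_mask]
    return _rdm_from_patterns(tuple(dataset.odors), X)


def bootstrap_rdm_null(
    dataset: Dataset,
    group: str,
    n_reps: int = 1000,
    seed: int = 0,
    scheme: str = "color-shuffle",
    per_trial: bool = True,
    feature_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Null (or uncertainty) distribution of pairwise dissimilarities.

    ``scheme="color-shuffle"`` (the null): per repetition, permute color
    identity independently per trial, recompute the RDM, and collect its
    strict-upper-triangle values.  ``scheme="participant-bootstrap"``
    (uncertainty): resample participants with replacement instead.
    Returns an ``(n_reps, n_odors*(n_odors-1)/2)`` array; deterministic
    given ``seed``.
    """
    if scheme not in ("color-shuffle", "participant-bootstrap"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    _, C = participant_counts(dataset, group)
    labels = tuple(dataset.odors)
    k = len(labels)
    iu = np.triu_indices(k, k=1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.empty((n_reps, k * (k - 1) // 2))
    for r in range(n_reps):
        if scheme == "color-shuffle":
            pooled = permute_colors(C, rng, per_trial=per_trial).sum(axis=0)
        else:
            idx = rng.integers(0, C.shape[0], size=C.shape[0])
            pooled = C[idx].sum(axis=0)
        X = pooled.astype(float)
        if feature_mask is not None:
            X = X[:, feature_mask]
        out[r] = _rdm_from_patterns(labels, X).matrix[iu]
    return out


def second_order_rdm(
    rdms: Mapping[str, Rdm], method: str = "pearson"
) -> Rdm:
    """Between-group RDM: pairwise dissimilarity of the groups' odor RDMs.

    Each cell is ``1 - r`` between the two RDMs' vectorized strict upper
    triangles; ``method`` selects Pearson (default) or Spearman r.
    """
    if len(rdms) < 2:
        raise ValidationError("need at least 2 group RDMs")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    groups = tuple(rdms)
    first_labels = rdms[groups[0]].labels
    for g in groups:
        if rdms[g].labels != first_labels:
            raise ValidationError(
                f"group {g!r}: odor labels/order differ from {groups[0]!r}"
            )
    vecs = np.stack([rdms[g].upper_triangle() for g in groups])
    k = len(groups)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if method == "pearson":
                if np.ptp(vecs[i]) == 0 or np.ptp(vecs[j]) == 0:
                    raise UndefinedCorrelationError(
                        "constant RDM upper triangle; second-order "
                        "correlation undefined"
                    )
                r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
            else:
                r = float(stats.spearmanr(vecs[i], vecs[j]).statistic)
            D[i, j] = D[j, i] = 1.0 - r
    return Rdm(groups, np.clip(D, 0.0, 2.0))
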