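"""Compilation of response records into 72-feature color patterns.

A color pattern for one odor within one group (or one cross-validation
fold) is a count vector of length 72: positions 0..35 hold, per color, the
number of participants who chose it as congruent; positions 36..71 hold
the incongruent counts.  Pooling all participants of a group gives the
whole-group pattern used by the consistency tests and the RDMs; splitting
participants into folds gives the pattern samples used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import CHOICES_PER_TYPE, Dataset
from .errors import ValidationError
from .palette import N_COLORS

N_FEATURES = 2 * N_COLORS  # 72


@dataclass(frozen=True)
class ColorPattern:
    """72-feature congruent/incongruent count vector for one odor."""

    odor: str
    group: str
    counts: np.ndarray
    n_participants: int
    fold: Optional[int] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_FEATURES,):
            raise ValidationError(f"pattern must have {N_FEATURES} features")
        expected = CHOICES_PER_TYPE * self.n_participants
        if c[:N_COLORS].sum() != expected or c[N_COLORS:].sum() != expected:
            raise ValidationError(
                f"({self.group}, {self.odor}): each half must sum to "
                f"{expected} for {self.n_participants} participants"
            )
        if (c < 0).any() or (c > self.n_participants).any():
            raise ValidationError(
                f"({self.group}, {self.odor}): counts must lie in "
                f"[0, {self.n_participants}]"
            )
        object.__setattr__(self, "counts", c)

    @property
    def congruent(self) -> np.ndarray:
        return self.counts[:N_COLORS]

    @property
    def incongruent(self) -> np.ndarray:
        return self.counts[N_COLORS:]

    def normalized(self) -> np.ndarray:
        """Counts divided by the contributing participant count."""
        return self.counts / float(self.n_participants)


# ----------------------------------------------------------------------
def participant_counts(
    dataset: Dataset, group: str
) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-participant count tensor for one group.

    Returns ``(participants, C)`` with ``C[p, o, :]`` the participant's own
    72-feature count vector (each half sums to 3).  This compact form backs
    the fold compiler, the classifier and the color-shuffle nulls.
    """
    parts = dataset.participants(group)
    p_idx = {p: i for i, p in enumerate(parts)}
    o_idx = {o: i for i, o in enumerate(dataset.odors)}
    sub = dataset.records[dataset.records["group"] == group.strip().lower()]
    C = np.zeros((len(parts), len(dataset.odors), N_FEATURES), dtype=np.int64)
    pi = sub["participant"].map(p_idx).to_numpy()
    oi = sub["odor"].map(o_idx).to_numpy()
    ci = sub["color_id"].to_numpy() - 1 + N_COLORS * (
        sub["choice_type"] == "incongruent"
    ).to_numpy(dtype=np.int64)
    np.add.at(C, (pi, oi, ci), 1)
    return parts, C


def compile_pattern(
    dataset: Dataset,
    group: str,
    odor: str,
    participants: Optional[Sequence[str]] = None,
) -> ColorPattern:
    """Pool the selected participants' choices into one color pattern."""
    group = group.strip().lower()
    odor = odor.strip().lower()
    if odor not in dataset.odors:
        raise ValidationError(f"unknown odor {odor!r}")
    all_parts, C = participant_counts(dataset, group)
    if participants is None:
        sel = np.arange(len(all_parts))
    else:
        wanted = [str(p).strip().lower() for p in participants]
        if not wanted:
            raise ValidationError("participant subset is empty")
        missing = set(wanted) - set(all_parts)
        if missing:
            raise ValidationError(
                f"participants {sorted(missing)} not in group {group!r}"
            )
        index = {p: i for i, p in enumerate(all_parts)}
        sel = np.array([index[p] for p in wanted])
    oi = dataset.odors.index(odor)
    counts = C[sel, oi, :].sum(axis=0)
    return ColorPattern(odor=odor, group=group, counts=counts,
                        n_participants=len(sel))


@dataclass(frozen=True)
class FoldPatterns:
    """Per-fold pattern samples plus the participant partition behind them."""

    group: str
    n_folds: int
    assignment: dict[str, int]  # participant -> fold index
    patterns: dict[tuple[int, str], ColorPattern]  # (fold, odor) -> pattern

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


def compile_fold_patterns(
    dataset: Dataset, group: str, n_folds: int = 3, seed: int = 0
) -> FoldPatterns:
    """Randomly partition a group's participants and compile per-fold patterns.

    Participants are split into ``n_folds`` near-equal parts (seeded); one
    pattern is compiled per (fold, odor).  Elementwise, the per-fold
    patterns of an odor sum to the whole-group pattern.
    """
    parts, C = participant_counts(dataset, group)
    if n_folds < 2 or n_folds > len(parts):
        raise ValidationError(
            f"n_folds={n_folds} invalid for {len(parts)} participants"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(parts))
    folds = np.array_split(order, n_folds)
    assignment = {parts[i]: f for f, members in enumerate(folds) for i in members}
    patterns: dict[tuple[int, str], ColorPattern] = {}
    for f, members in enumerate(folds):
        counts = C[members].sum(axis=0)  # (n_odors, 72)
        for oi, odor in enumerate(dataset.odors):
            patterns[(f, odor)] = ColorPattern(
                odor=odor, group=group.strip().lower(),
                counts=counts[oi], n_participants=len(members), fold=f,
            )
    return FoldPatterns(group=group.strip().lower(), n_folds=n_folds,
                        assignment=assignment, patterns=patterns)


# ----------------------------------------------------------------------
def permute_colors(
    C: np.ndarray, rng: np.random.Generator, per_trial: bool = True
) -> np.ndarray:
    """Randomly permute color identity in a participant count tensor.

    With ``per_trial=True`` (the stability null), every (participant, odor)
    trial gets an independent random permutation of the 36 color ids,
    applied identically to its congruent and incongruent halves — this
    destroys cross-participant agreement while preserving each trial's
    3 + 3 structure.  With ``per_trial=False`` one shared permutation is
    applied to the whole tensor.
    """
    n_p, n_o, _ = C.shape
    if per_trial:
        pi = rng.random((n_p, n_o, N_COLORS)).argsort(axis=-1)
    else:
        one = rng.permutation(N_COLORS)
        pi = np.broadcast_to(one, (n_p, n_o, N_COLORS))
    out = np.empty_like(C)
    np.put_along_axis(out[:, :, :N_COLORS], pi, C[:, :, :N_COLORS], axis=-1)
    np.put_along_axis(out[:, :, N_COLORS:], pi, C[:, :, N_COLORS:], axis=-1)
    return out


def patterns_to_frame(patterns: Sequence[ColorPattern]) -> pd.DataFrame:
    """Export patterns as a delimited-ready matrix with metadata columns."""
    meta = {
        "group": [p.group for p in patterns],
        "odor": [p.odor for p in patterns],
        "fold": [p.fold if p.fold is not None else -1 for p in patterns],
        "n_participants": [p.n_participants for p in patterns],
    }
    mat = np.stack([p.counts for p in patterns]) if patterns else np.zeros((0, N_FEATURES), int)
    cols = [f"cong_{i + 1}" for i in range(N_COLORS)] + [
        f"incong_{i + 1}" for i in range(N_COLORS)
    ]
    return pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(mat, columns=cols)], axis=1
    )
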