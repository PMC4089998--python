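"""Response-table data model and delimited I/O.

A study dataset is a flat table of forced-choice records: each participant
smelled each odor once and selected the three most congruent and the three
most incongruent colors from the 36-color palette.  One row = one color
choice, so a complete trial is 6 rows and a complete participant is
``6 x n_odors`` rows.

The canonical file format is UTF-8 CSV with header
``group,participant,odor,choice_type,color_id`` and
``choice_type in {congruent, incongruent}``.  The reader tolerates common
column-name synonyms (e.g. ``culture`` for ``group``, ``subject`` for
``participant``) but rejects anything that breaks a structural invariant,
naming the offending (group, participant, odor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .palette import ColorPalette, N_COLORS, default_palette

CHOICES_PER_TYPE = 3
CHOICE_TYPES = ("congruent", "incongruent")
COLUMNS = ("group", "participant", "odor", "choice_type", "color_id")

# tolerant synonym map for the reader (lower-cased, trimmed header names)
_COLUMN_SYNONYMS = {
    "group": "group",
    "population": "group",
    "culture": "group",
    "country": "group",
    "participant": "participant",
    "participant_id": "participant",
    "subject": "participant",
    "subject_id": "participant",
    "id": "participant",
    "odor": "odor",
    "odour": "odor",
    "odorant": "odor",
    "choice_type": "choice_type",
    "choice": "choice_type",
    "congruency": "choice_type",
    "type": "choice_type",
    "color_id": "color_id",
    "colour_id": "color_id",
    "color": "color_id",
    "colour": "color_id",
}

#: The study's 14 odor labels (already in lexicographic order).
DEFAULT_ODORS: tuple[str, ...] = (
    "burnt", "candy", "fish", "flower", "fruity", "hazelnut", "meat",
    "musty", "plastic", "rice", "soap", "vegetable", "vinegar", "woody",
)


def _normalize_id(value: object) -> str:
    return str(value).strip().lower()


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's choice of one color for one odor."""

    group: str
    participant: str
    odor: str
    choice_type: str  # "congruent" | "incongruent"
    color_id: int


@dataclass
class Dataset:
    """A validated collection of response records.

    ``records`` is a DataFrame with the canonical columns; ``odors`` and
    ``groups`` fix the ordering used by every matrix-valued output.
    """

    records: pd.DataFrame
    palette: ColorPalette = field(default_factory=default_palette)
    odors: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.records.loc[:, list(COLUMNS)].copy()
        for col in ("group", "participant", "odor", "choice_type"):
            df[col] = df[col].map(_normalize_id)
        df["color_id"] = pd.to_numeric(df["color_id"], errors="raise").astype(int)
        self.records = df.reset_index(drop=True)
        if not self.odors:
            self.odors = tuple(sorted(df["odor"].unique()))
        else:
            self.odors = tuple(_normalize_id(o) for o in self.odors)
        if not self.groups:
            self.groups = tuple(sorted(df["group"].unique()))
        else:
            self.groups = tuple(_normalize_id(g) for g in self.groups)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Enforce every structural invariant; raise ValidationError."""
        df = self.records
        if df.empty:
            return
        bad_type = ~df["choice_type"].isin(CHOICE_TYPES)
        if bad_type.any():
            row = df[bad_type].iloc[0]
            raise ValidationError(
                f"unknown choice_type {row['choice_type']!r} at "
                f"(group={row['group']}, participant={row['participant']}, "
                f"odor={row['odor']})"
            )
        bad_color = ~df["color_id"].between(1, N_COLORS)
        if bad_color.any():
            row = df[bad_color].iloc[0]
            raise ValidationError(
                f"color_id {row['color_id']} outside 1..{N_COLORS} at "
                f"(group={row['group']}, participant={row['participant']}, "
                f"odor={row['odor']})"
            )
        unknown_odor = ~df["odor"].isin(self.odors)
        if unknown_odor.any():
            raise ValidationError(
                f"odor {df.loc[unknown_odor, 'odor'].iloc[0]!r} not in the "
                f"declared odor set {list(self.odors)}"
            )
        unknown_group = ~df["group"].isin(self.groups)
        if unknown_group.any():
            raise ValidationError(
                f"group {df.loc[unknown_group, 'group'].iloc[0]!r} not in the "
                f"declared group set {list(self.groups)}"
            )
        # exactly 3 distinct colors per (group, participant, odor, choice_type)
        per_type = df.groupby(
            ["group", "participant", "odor", "choice_type"], sort=False
        )["color_id"].agg(["size", "nunique"])
        bad = per_type[
            (per_type["size"] != CHOICES_PER_TYPE)
            | (per_type["nunique"] != CHOICES_PER_TYPE)
        ]
        if len(bad):
            g, p, o, t = bad.index[0]
            raise ValidationError(
                f"(group={g}, participant={p}, odor={o}): expected "
                f"{CHOICES_PER_TYPE} distinct {t} choices, found "
                f"{bad.iloc[0]['size']} rows / {bad.iloc[0]['nunique']} distinct"
            )
        # congruent and incongruent sets disjoint within a trial
        dup = df.duplicated(subset=["group", "participant", "odor", "color_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"(group={row['group']}, participant={row['participant']}, "
                f"odor={row['odor']}): color {row['color_id']} appears in both "
                "the congruent and incongruent set"
            )
        # every participant answered every declared odor
        per_part = df.groupby(["group", "participant"], sort=False)["odor"].agg(
            lambda s: frozenset(s)
        )
        expected = frozenset(self.odors)
        incomplete = per_part[per_part != expected]
        if len(incomplete):
            g, p = incomplete.index[0]
            missing = sorted(expected - incomplete.iloc[0])
            raise ValidationError(
                f"(group={g}, participant={p}): missing trials for odors {missing}"
            )

    # ------------------------------------------------------------------
    def participants(self, group: str) -> tuple[str, ...]:
        """Participant ids of one group, in stable sorted order."""
        group = _normalize_id(group)
        if group not in self.groups:
            raise ValidationError(f"unknown group {group!r}")
        sub = self.records.loc[self.records["group"] == group, "participant"]
        return tuple(sorted(sub.unique()))

    @property
    def n_participants(self) -> int:
        return len(self.records.groupby(["group", "participant"]).size())

    def iter_records(self) -> Iterable[ResponseRecord]:
        for row in self.records.itertuples(index=False):
            yield ResponseRecord(*row)

    def record_multiset(self) -> dict[ResponseRecord, int]:
        """Multiset view of the records (order-insensitive comparison)."""
        out: dict[ResponseRecord, int] = {}
        for rec in self.iter_records():
            out[rec] = out.get(rec, 0) + 1
        return out

    def relabel_colors(self, permutation: Sequence[int]) -> "Dataset":
        """Apply one global permutation of the 36 color ids.

        ``permutation`` maps old id ``i`` to ``permutation[i-1]`` and must be
        a permutation of 1..36.  Used for invariance checks.
        """
        perm = np.asarray(permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(1, N_COLORS + 1)):
            raise ValidationError("not a permutation of 1..36")
        df = self.records.copy()
        df["color_id"] = perm[df["color_id"].to_numpy() - 1]
        return Dataset(df, palette=self.palette, odors=self.odors, groups=self.groups)


# ----------------------------------------------------------------------
def read_responses(
    path: str,
    palette: Optional[ColorPalette] = None,
    odors: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[str]] = None,
) -> Dataset:
    """Read a response table into a validated :class:`Dataset`.

    Odor and group orderings are taken from ``odors`` / ``groups`` when
    provided, else inferred in stable lexicographic order.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ValidationError(f"cannot parse response table {path!r}: {exc}")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _COLUMN_SYNONYMS:
            rename[col] = _COLUMN_SYNONYMS[key]
    df = df.rename(columns=rename)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"response table missing columns {sorted(missing)} "
            f"(found: {list(df.columns)})"
        )
    try:
        df["color_id"] = pd.to_numeric(df["color_id"], errors="raise").astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer color_id in {path!r}: {exc}")
    return Dataset(
        df,
        palette=palette or default_palette(),
        odors=tuple(odors) if odors else (),
        groups=tuple(groups) if groups else (),
    )


def write_responses(dataset: Dataset, path: str) -> None:
    """Write a dataset as canonical CSV with deterministic row order."""
    df = dataset.records.sort_values(
        by=["group", "participant", "odor", "choice_type", "color_id"],
        kind="mergesort",
    )
    df.to_csv(path, index=False, columns=list(COLUMNS))
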