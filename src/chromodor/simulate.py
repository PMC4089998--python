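"""Synthetic study generator.

Real data of this kind are forced-choice selections: each participant picks
the 3 most congruent and 3 most incongruent colors for each odor.  The
generator emulates the population-level structure the downstream analyses
look for — each group holds a latent color-propensity profile per odor —
with two dials:

``kappa``
    Symmetric Dirichlet concentration of the profiles.  Small kappa gives
    spiky profiles (strong, consistent color-odor associations); large
    kappa approaches uniform (no association).
``rho``
    Cross-group sharing weight in [0, 1].  Each group's profile is the
    ``rho``-weighted mixture of a global per-odor profile with a
    group-specific draw, so ``rho=1`` makes all groups identical and
    ``rho=0`` makes them independent.

Choices are sampled per trial by sequential weighted sampling without
replacement: 3 congruent colors from ``p_cong``, then 3 incongruent colors
from ``p_incong`` restricted to the 33 colors not already chosen, which
guarantees the within-trial disjointness invariant.

Every trial uses its own RNG stream keyed by (seed, group index,
participant index, odor index), so generated datasets are invariant to the
order of the generation loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_ODORS, Dataset
from .errors import GenerationError, ValidationError
from .palette import ColorPalette, N_COLORS, default_palette

#: Study-scale default group sizes (five groups of 20 plus one of 22).
DEFAULT_GROUPS: dict[str, int] = {
    "dutch": 20,
    "german": 20,
    "malay": 20,
    "malaysian_chinese": 20,
    "nl_chinese": 20,
    "us": 22,
}

# stream tags keeping profile / trial / null RNG streams disjoint
_STREAM_GLOBAL, _STREAM_GROUP, _STREAM_TRIAL, _STREAM_NULL = 0, 1, 2, 3


@dataclass(frozen=True)
class GenerativeProfile:
    """Latent color-propensity pair for one (group, odor)."""

    group: str
    odor: str
    p_cong: np.ndarray
    p_incong: np.ndarray

    def __post_init__(self) -> None:
        for name, vec in (("p_cong", self.p_cong), ("p_incong", self.p_incong)):
            v = np.asarray(vec, dtype=float)
            if v.shape != (N_COLORS,):
                raise ValidationError(f"{name}: expected length {N_COLORS}")
            if (v < 0).any():
                raise ValidationError(f"{name}: negative mass")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValidationError(f"{name}: sums to {v.sum()}, not 1")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class GeneratorConfig:
    """Simulation control surface; defaults mirror the study design."""

    groups: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    odors: tuple[str, ...] = DEFAULT_ODORS
    kappa: float = 0.5
    rho: float = 0.3
    group_pairs_shared: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValidationError(f"kappa must be > 0, got {self.kappa}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho must be in [0, 1], got {self.rho}")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if not self.groups:
            raise ValidationError("at least one group required")
        for g, n in self.groups.items():
            if n < 1:
                raise ValidationError(f"group {g!r}: participant count {n} < 1")
        known = set(self.groups)
        for a, b in self.group_pairs_shared:
            if a not in known or b not in known:
                raise ValidationError(f"shared pair ({a}, {b}) names unknown group")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def n_participants(self) -> int:
        return sum(self.groups.values())


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _share_representatives(config: GeneratorConfig) -> dict[str, str]:
    """Map each group to the representative whose profile it copies."""
    names = list(config.group_names)
    parent = {g: g for g in names}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in config.group_pairs_shared:
        ra, rb = find(a), find(b)
        if ra != rb:
            # earliest-listed group wins, so sharing is order-stable
            first, second = sorted((ra, rb), key=names.index)
            parent[second] = first
    return {g: find(g) for g in names}


def draw_profiles(config: GeneratorConfig) -> list[GenerativeProfile]:
    """Draw the latent profiles for every (group, odor).

    Per odor, a global congruent/incongruent pair is drawn from a symmetric
    Dirichlet(kappa); each group's profile mixes that global pair (weight
    ``rho``) with a group-specific Dirichlet(kappa) draw.  Groups listed in
    ``group_pairs_shared`` receive identical profiles.  Fully determined by
    ``config.seed``.
    """
    alpha = np.full(N_COLORS, config.kappa)
    reps = _share_representatives(config)
    group_index = {g: i for i, g in enumerate(config.group_names)}
    profiles: list[GenerativeProfile] = []
    for oi, odor in enumerate(config.odors):
        g_rng = _rng(config.seed, _STREAM_GLOBAL, oi)
        global_cong = g_rng.dirichlet(alpha)
        global_incong = g_rng.dirichlet(alpha)
        per_group: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for group in config.group_names:
            rep = reps[group]
            if rep not in per_group:
                r = _rng(config.seed, _STREAM_GROUP, group_index[rep], oi)
                own_cong = r.dirichlet(alpha)
                own_incong = r.dirichlet(alpha)
                p_cong = config.rho * global_cong + (1 - config.rho) * own_cong
                p_incong = config.rho * global_incong + (1 - config.rho) * own_incong
                per_group[rep] = (p_cong / p_cong.sum(), p_incong / p_incong.sum())
            p_cong, p_incong = per_group[rep]
            profiles.append(GenerativeProfile(group, odor, p_cong, p_incong))
    return profiles


def _sample_trial(
    rng: np.random.Generator, p_cong: np.ndarray, p_incong: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample 3 distinct congruent then 3 distinct incongruent color indices."""
    if (p_cong > 0).sum() < 3:
        raise GenerationError("congruent profile has < 3 colors of positive mass")
    cong = rng.choice(N_COLORS, size=3, replace=False, p=p_cong)
    rest = p_incong.copy()
    rest[cong] = 0.0
    if (rest > 0).sum() < 3:
        raise GenerationError(
            "incongruent profile has < 3 positive-mass colors left after "
            "excluding the congruent choices"
        )
    rest /= rest.sum()
    incong = rng.choice(N_COLORS, size=3, replace=False, p=rest)
    return cong, incong


def _assemble(
    config: GeneratorConfig,
    trial_colors,  # callable (gi, pi, oi) -> (cong idx array, incong idx array)
    palette: ColorPalette,
) -> Dataset:
    rows: dict[str, list] = {c: [] for c in ("group", "participant", "odor",
                                             "choice_type", "color_id")}
    for gi, (group, n_part) in enumerate(config.groups.items()):
        for pi in range(n_part):
            participant = f"p{pi + 1:03d}"
            for oi, odor in enumerate(config.odors):
                cong, incong = trial_colors(gi, pi, oi)
                for kind, idx in (("congruent", cong), ("incongruent", incong)):
                    for c in idx:
                        rows["group"].append(group)
                        rows["participant"].append(participant)
                        rows["odor"].append(odor)
                        rows["choice_type"].append(kind)
                        rows["color_id"].append(int(c) + 1)
    return Dataset(
        pd.DataFrame(rows),
        palette=palette,
        odors=config.odors,
        groups=config.group_names,
    )


def generate_dataset(
    config: GeneratorConfig,
    profiles: Optional[Sequence[GenerativeProfile]] = None,
    palette: Optional[ColorPalette] = None,
) -> Dataset:
    """Generate a full study dataset under the profile model."""
    if profiles is None:
        profiles = draw_profiles(config)
    lookup = {(p.group, p.odor): p for p in profiles}
    for group in config.group_names:
        for odor in config.odors:
            if (group, odor) not in lookup:
                raise ValidationError(f"no profile supplied for ({group}, {odor})")

    groups = list(config.groups.items())

    def trial(gi: int, pi: int, oi: int):
        group = groups[gi][0]
        prof = lookup[(group, config.odors[oi])]
        rng = _rng(config.seed, _STREAM_TRIAL, gi, pi, oi)
        return _sample_trial(rng, prof.p_cong, prof.p_incong)

    return _assemble(config, trial, palette or default_palette())


def null_dataset(
    config: GeneratorConfig, palette: Optional[ColorPalette] = None
) -> Dataset:
    """Generate association-free data: 6 uniform distinct colors per trial.

    This is the no-association null in which any apparent color-odor
    structure is sampling noise; chance classification accuracy on it is
    1 / n_odors.
    """

    def trial(gi: int, pi: int, oi: int):
        rng = _rng(config.seed, _STREAM_NULL, gi, pi, oi)
        six = rng.choice(N_COLORS, size=6, replace=False)
        return six[:3], six[3:]

    return _assemble(config, trial, palette or default_palette())
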