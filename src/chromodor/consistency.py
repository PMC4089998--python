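"""Chi-square tests of non-random color choice, with Bonferroni correction.

For each odor within a group, the congruent and the incongruent 36-color
count vectors are each tested against the uniform expectation
``E = 3 * n_participants / 36`` per cell with a Pearson chi-square
(df = 35); a combined statistic (sum of the two chi-squares, df = 70) is
reported alongside, since both halves address the same "choices are
random" null.  Family-wise error over the ``groups x odors`` family is
controlled by Bonferroni: per-test threshold ``alpha / m``.

Caveat: with 3 forced choices per participant the expected count per cell
is below 5 until n_participants >= 60, and within-trial choices are
distinct (sampling without replacement), which makes the Pearson statistic
mildly conservative; a logged warning flags low expected counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .errors import ValidationError
from .palette import N_COLORS
from .patterns import compile_pattern

logger = logging.getLogger(__name__)

COMPONENTS = ("congruent", "incongruent", "combined")


@dataclass(frozen=True)
class ConsistencyResult:
    group: str
    odor: str
    component: str  # congruent | incongruent | combined
    chi2: float
    df: int
    p: float
    significant_bonferroni: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and self.chi2 >= 0 and self.df >= 1):
            raise ValidationError(
                f"invalid result (chi2={self.chi2}, df={self.df}, p={self.p})"
            )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold for a family of m comparisons."""
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def chi_square_uniform(
    counts: Sequence[float], expected: Optional[Sequence[float]] = None
) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against an expectation.

    When ``expected`` is omitted the expectation is uniform over the cells.
    Returns ``(chi2, df, p)`` with ``df = len(counts) - 1`` and ``p`` from
    the chi-square upper tail.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValidationError("counts must be a 1-D vector of length >= 2")
    total = obs.sum()
    if not total > 0:
        raise ValidationError("counts sum to zero")
    if expected is None:
        exp = np.full(obs.size, total / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValidationError("expected has a different length than counts")
        if (exp <= 0).any():
            raise ValidationError("expected counts must be strictly positive")
        if abs(exp.sum() - total) > 1e-8 * max(1.0, total):
            raise ValidationError(
                f"expected total {exp.sum()} differs from observed total {total}"
            )
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def test_group_consistency(
    dataset: Dataset,
    group: str,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> list[ConsistencyResult]:
    """Per-odor chi-square consistency tests for one group.

    For every odor, returns three :class:`ConsistencyResult` rows
    (congruent, incongruent, combined), each flagged at the Bonferroni
    threshold ``alpha / m``.  ``m`` defaults to ``|groups| * |odors|``
    (84 for the study design).
    """
    if m is None:
        m = len(dataset.groups) * len(dataset.odors)
    threshold = bonferroni_threshold(alpha, m)
    results: list[ConsistencyResult] = []
    for odor in dataset.odors:
        pattern = compile_pattern(dataset, group, odor)
        if pattern.n_participants * 3 / N_COLORS < 5:
            logger.warning(
                "(%s, %s): expected count per cell %.2f < 5; the chi-square "
                "approximation is conservative at this sample size",
                group, odor, pattern.n_participants * 3 / N_COLORS,
            )
        c_chi2, c_df, c_p = chi_square_uniform(pattern.congruent)
        i_chi2, i_df, i_p = chi_square_uniform(pattern.incongruent)
        comb = c_chi2 + i_chi2
        comb_df = c_df + i_df
        comb_p = float(stats.chi2.sf(comb, comb_df))
        for component, chi2, df, p in (
            ("congruent", c_chi2, c_df, c_p),
            ("incongruent", i_chi2, i_df, i_p),
            ("combined", comb, comb_df, comb_p),
        ):
            results.append(
                ConsistencyResult(
                    group=group.strip().lower(), odor=odor, component=component,
                    chi2=chi2, df=df, p=p,
                    significant_bonferroni=p < threshold,
                )
            )
    return results


def consistency_table(
    dataset: Dataset, alpha: float = 0.05, m: Optional[int] = None
) -> pd.DataFrame:
    """All groups' consistency results as one tidy table.

    Rows are (group, odor, component) with columns ``chi2, df, p,
    significant_bonferroni``; the labeling makes the test convention
    explicit rather than leaving a single ambiguous per-odor value.
    """
    rows = []
    for group in dataset.groups:
        for r in test_group_consistency(dataset, group, alpha=alpha, m=m):
            rows.append(r.__dict__)
    return pd.DataFrame(rows)
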