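"""Interobserver agreement statistics for spot annotations.

Several observers annotate the same spots independently; agreement is
summarised by (a) pairwise percent agreement — the share of spots a pair
labels identically — averaged over all pairs, and (b) Fleiss' kappa, which
corrects that observed agreement for the agreement expected by chance given
each category's overall prevalence:

    kappa = (P_obs - P_chance) / (1 - P_chance)

kappa = 0 means chance-level agreement, 1 unanimity; values above ~0.8 are
conventionally read as near-perfect agreement.

For exactly three raters with binary labels, the per-subject observed
agreement equals the fraction of agreeing rater pairs, so the mean pairwise
percent agreement *is* P_obs; kappa can then be reconstructed from published
summary numbers alone (per-rater positive proportions + mean agreement)
via :func:`fleiss_kappa_binary_from_summaries`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import read_ratings_csv

__all__ = [
    "RatingsMatrix",
    "AgreementSummary",
    "pairwise_percent_agreement",
    "average_pairwise_agreement",
    "fleiss_kappa",
    "fleiss_kappa_binary_from_summaries",
    "summarize_agreement",
    "load_ratings",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class RatingsMatrix:
    """N subjects x R raters categorical labels, with no missing entries."""

    subjects: list[str]
    labels: np.ndarray  # (N, R) object/str array
    raters: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D (subjects x raters) array")
        n, r = self.labels.shape
        if n < 1 or r < 2:
            raise ValueError("need at least 1 subject and 2 raters")
        if len(self.subjects) != n:
            raise ValueError("subjects length mismatch")
        if self.raters is None:
            self.raters = [f"rater_{i + 1}" for i in range(r)]

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]

    @property
    def n_raters(self) -> int:
        return self.labels.shape[1]


@dataclass(frozen=True)
class AgreementSummary:
    """Pairwise agreements (percent), their mean, and Fleiss' kappa."""

    pairwise: dict[tuple[str, str], float]
    average_pairwise: float
    kappa: float


def pairwise_percent_agreement(a: Sequence, b: Sequence) -> float:
    """Percent of positions where two label vectors agree exactly."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("label vectors must be 1-D, equal-length and non-empty")
    return 100.0 * float(np.mean(a == b))


def average_pairwise_agreement(ratings: RatingsMatrix) -> float:
    """Mean pairwise percent agreement over all rater pairs."""
    return float(np.mean(list(_pairwise(ratings).values())))


def _pairwise(ratings: RatingsMatrix) -> dict[tuple[str, str], float]:
    out = {}
    for i, j in combinations(range(ratings.n_raters), 2):
        out[(ratings.raters[i], ratings.raters[j])] = pairwise_percent_agreement(
            ratings.labels[:, i], ratings.labels[:, j]
        )
    return out


def fleiss_kappa(ratings: RatingsMatrix) -> float:
    """Fleiss' kappa for R raters over N subjects (any label alphabet).

    Standard formulation: with n_ij the number of raters assigning category
    j to subject i, per-subject agreement is
    ``P_i = (sum_j n_ij^2 - R) / (R (R - 1))``, chance agreement is
    ``P_e = sum_j p_j^2`` with ``p_j`` the overall category prevalence, and
    ``kappa = (mean P_i - P_e) / (1 - P_e)``.  Unanimous single-category
    data (P_e = 1) returns 1.0.
    """
    cats = sorted({str(v) for v in ratings.labels.ravel()})
    n, r = ratings.labels.shape
    counts = np.zeros((n, len(cats)), dtype=np.int64)
    index = {c: j for j, c in enumerate(cats)}
    for i in range(n):
        for v in ratings.labels[i]:
            counts[i, index[str(v)]] += 1
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n * r)
    p_e = float(np.sum(p_j**2))
    if p_e == 1.0:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa_binary_from_summaries(
    positive_props: Sequence[float], mean_pairwise_agreement: float
) -> float:
    """Fleiss' kappa for 3 raters / binary labels from summary statistics.

    With three raters and two categories the per-subject agreement is the
    fraction of agreeing rater pairs, so the mean pairwise percent agreement
    equals 100 * P_obs.  Chance agreement follows from the mean positive
    proportion p: ``P_e = p^2 + (1 - p)^2``.

    Parameters
    ----------
    positive_props
        Per-rater proportions of subjects labelled positive, in [0, 1].
    mean_pairwise_agreement
        Mean pairwise percent agreement, in [0, 100].
    """
    props = np.asarray(positive_props, dtype=float)
    if props.size != 3:
        raise ValueError("this reconstruction assumes exactly three raters")
    if np.any((props < 0) | (props > 1)):
        raise ValueError("positive proportions must lie in [0, 1]")
    if not 0 <= mean_pairwise_agreement <= 100:
        raise ValueError("mean pairwise agreement must lie in [0, 100]")
    p = float(props.mean())
    p_obs = mean_pairwise_agreement / 100.0
    p_e = p * p + (1 - p) * (1 - p)
    if p_e == 1.0:
        return 1.0
    return (p_obs - p_e) / (1.0 - p_e)


def summarize_agreement(ratings: RatingsMatrix) -> AgreementSummary:
    """All agreement statistics for one ratings matrix."""
    pairwise = _pairwise(ratings)
    return AgreementSummary(
        pairwise=pairwise,
        average_pairwise=float(np.mean(list(pairwise.values()))),
        kappa=fleiss_kappa(ratings),
    )


def load_ratings(paths: Sequence, rater_names: Sequence[str] | None = None) -> RatingsMatrix:
    """Build a RatingsMatrix from per-rater (id, label) CSVs.

    Subjects are inner-joined on id: a spot missing from any rater's file is
    dropped (the count is logged).  Subject order follows the first file.
    """
    if len(paths) < 2:
        raise ValueError("need at least two ratings files")
    series = [read_ratings_csv(p) for p in paths]
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    dropped = sum(len(s) for s in series) - len(series) * len(common)
    if dropped:
        logger.info("dropped %d ratings for subjects not shared by all raters", dropped)
    if len(common) == 0:
        raise ValueError("no subjects shared by all raters")
    ordered = [i for i in series[0].index if i in set(common)]
    labels = np.stack([s.loc[ordered].to_numpy(dtype=object) for s in series], axis=1)
    if rater_names is None:
        rater_names = [s.name or f"rater_{k + 1}" for k, s in enumerate(series)]
    return RatingsMatrix(subjects=list(ordered), labels=labels, raters=list(rater_names))
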