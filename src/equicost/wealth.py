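"""Asset-based wealth index, fractional ranks, and wealth quintiles.

Household living standards are proxied by the first principal component of
the standardised asset/housing indicator matrix (the Filmer–Pritchett
wealth index).  Patients are then ordered by score and given a fractional
socioeconomic rank ``R_i`` in (0, 1) — the cumulative population share up
to the midpoint of the observation — which is the rank variable entering
the concentration index.  Quintile 1 is the poorest fifth, quintile 5 the
least poor.

Tied scores receive the average of the ranks their positions would occupy,
which preserves the exact identity ``weighted mean of ranks = 1/2`` that
the concentration-index formula relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey_data import Dataset

__all__ = [
    "RankedSample",
    "wealth_scores",
    "fractional_ranks",
    "assign_quintiles",
    "ranked_sample",
    "wealth_audit_table",
]


@dataclass
class RankedSample:
    """Outcome values paired with fractional wealth ranks.

    Attributes
    ----------
    values : ndarray
        Outcome ``y_i`` in the outcome's own units.
    ranks : ndarray
        Fractional socioeconomic rank ``R_i`` in (0, 1); weighted mean 1/2.
    weights : ndarray
        Positive sampling weights (all 1 for the unweighted analysis).
    quintile : ndarray
        Integers 1..5; 1 = poorest, 5 = least poor.
    score : ndarray
        The wealth-index score the ranks were derived from.
    """

    values: np.ndarray
    ranks: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    quintile: np.ndarray = field(default=None)  # type: ignore[assignment]
    score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        n = self.values.size
        if n == 0:
            raise ValueError("empty sample")
        if self.ranks.size != n:
            raise ValueError("values and ranks lengths differ")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.any((self.ranks <= 0) | (self.ranks >= 1)):
            raise ValueError("ranks must lie strictly in (0, 1)")
        if self.quintile is None:
            self.quintile = assign_quintiles(self.ranks)
        if self.score is None:
            self.score = self.ranks.copy()

    def __len__(self) -> int:
        return self.values.size


def wealth_scores(dataset: Dataset | np.ndarray) -> np.ndarray:
    """First-principal-component wealth score per record.

    Each indicator is standardised to zero mean and unit variance
    (correlation-scale PCA, the standard choice for mixed binary/ordinal
    items); the score is the projection of the standardised rows onto the
    first principal component.  Constant indicators carry no information
    and are dropped with a warning.  The eigenvector sign is fixed so that
    the score correlates positively with the row sum of standardised
    indicators: higher score = wealthier.

    Deterministic for fixed input (SVD of the centred matrix).
    """
    X = dataset.asset_matrix() if isinstance(dataset, Dataset) else np.asarray(
        dataset, dtype=float)
    if X.ndim != 2:
        raise ValueError("asset matrix must be 2-dimensional")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 records for a wealth index")
    if np.isnan(X).any():
        raise ValueError(
            "missing asset indicator values: impute by mode or exclude the "
            "rows upstream before building the wealth index"
        )
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant asset indicator(s)",
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant asset indicators")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # First right-singular vector of the standardised matrix = leading
    # eigenvector of the correlation matrix.
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    score = Z @ v
    orientation = float(score @ Z.sum(axis=1))
    if orientation < 0 or (orientation == 0 and v.sum() < 0):
        score = -score
    return score


def fractional_ranks(scores: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Tie-aware (weighted) fractional ranks in (0, 1).

    Sorting by score ascending, an untied unit-weight observation at sort
    position ``i`` (1-based) gets ``R_i = (i - 1/2)/n``; in general each
    tie group gets the cumulative weight of all strictly poorer
    observations plus half the group's own weight, over total weight —
    i.e. the average of the ranks the tied positions would occupy.  The
    weighted mean of the returned ranks is exactly 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("empty input")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.size != n:
        raise ValueError("weights length mismatch")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    order = np.argsort(scores, kind="mergesort")
    w_sorted = weights[order]
    total = w_sorted.sum()
    # Midpoint rank per sorted position, then average within tie groups.
    cum = np.cumsum(w_sorted)
    mid = (cum - w_sorted / 2.0) / total

    ranks_sorted = np.empty(n)
    s_sorted = scores[order]
    start = 0
    for stop in range(1, n + 1):
        if stop == n or s_sorted[stop] != s_sorted[start]:
            block_w = w_sorted[start:stop]
            ranks_sorted[start:stop] = np.average(mid[start:stop], weights=block_w)
            start = stop
    ranks = np.empty(n)
    ranks[order] = ranks_sorted
    return ranks


def assign_quintiles(ranks: np.ndarray) -> np.ndarray:
    """Wealth quintile 1..5 from fractional ranks: ``min(floor(5R) + 1, 5)``.

    Cutting on the fractional rank (rather than raw score percentiles)
    guarantees tied scores share a quintile and that, absent ties, group
    sizes differ by at most one.
    """
    ranks = np.asarray(ranks, dtype=float)
    if np.any((ranks <= 0) | (ranks >= 1)):
        raise ValueError("ranks must lie strictly in (0, 1)")
    return np.minimum(np.floor(5.0 * ranks).astype(int) + 1, 5)


def ranked_sample(
    values: np.ndarray,
    scores: np.ndarray,
    weights: np.ndarray | None = None,
) -> RankedSample:
    """Bundle outcome values with ranks/quintiles derived from wealth scores."""
    scores = np.asarray(scores, dtype=float)
    ranks = fractional_ranks(scores, weights)
    return RankedSample(values=np.asarray(values, dtype=float), ranks=ranks,
                        weights=weights, quintile=assign_quintiles(ranks),
                        score=scores)


def wealth_audit_table(dataset: Dataset) -> pd.DataFrame:
    """Per-patient score / rank / quintile table for audit export."""
    score = wealth_scores(dataset)
    ranks = fractional_ranks(score)
    return pd.DataFrame(
        {
            "patient_id": dataset.df["patient_id"].to_numpy(),
            "wealth_score": score,
            "fractional_rank": ranks,
            "quintile": assign_quintiles(ranks),
        }
    )
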