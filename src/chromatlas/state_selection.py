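"""Choosing the number of chromatin states from a family of emission models.

Two complementary strategies are applied to a family of emission models
learned at k = k_min..k_max for each of two replicate series:

1. best-match correlation: each state of the richest (reference) model is
   correlated against every state of each simpler model; the per-model
   median of the best matches is tracked against k.
2. cluster separation: the emission rows of *all* models from both
   replicates are pooled and k-means-clustered for each candidate k; the
   mean BetweenSS/TotalSS ratio over repeated random initializations is
   tracked against k.

For both, the value at k_max serves as the maximum and the smallest k
reaching >= 95% of it is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionModel",
    "ModelFamily",
    "best_match_correlations",
    "median_correlation_series",
    "lloyd_kmeans",
    "separation_ratio",
    "select_state_number",
    "SelectionReport",
]


@dataclass
class EmissionModel:
    """Per-state emission probabilities over a fixed set of marks."""

    marks: list[str]
    emissions: np.ndarray

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != len(self.marks):
            raise ValueError("emissions must be n_states x n_marks")
        if np.any((self.emissions < 0) | (self.emissions > 1)):
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]


@dataclass
class ModelFamily:
    """One EmissionModel per (replicate series, k)."""

    models: dict[str, dict[int, EmissionModel]]

    def __post_init__(self) -> None:
        marks = None
        for rep in self.models.values():
            for m in rep.values():
                if marks is None:
                    marks = m.marks
                elif m.marks != marks:
                    raise ValueError("inconsistent mark sets across the family")

    def k_values(self, replicate: str) -> list[int]:
        return sorted(self.models[replicate])

    def k_max(self, replicate: str) -> int:
        return max(self.models[replicate])

    def pooled_emissions(self) -> np.ndarray:
        """All states from all models of all replicate series, stacked."""
        rows = [m.emissions
                for rep in self.models.values()
                for _, m in sorted(rep.items())]
        return np.vstack(rows)


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of a against every row of b;
    constant rows correlate as 0 (logged)."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((ac**2).sum(axis=1))
    bn = np.sqrt((bc**2).sum(axis=1))
    if np.any(an == 0) or np.any(bn == 0):
        logger.warning("constant emission row: correlation defined as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(an, bn)
    return np.nan_to_num(r, nan=0.0)


def best_match_correlations(
    reference: EmissionModel, other: EmissionModel
) -> np.ndarray:
    """For each reference state, the maximum Pearson correlation of its
    emission row against any state of ``other``."""
    if reference.marks != other.marks:
        raise ValueError("models must share the same mark set")
    return _row_correlations(reference.emissions, other.emissions).max(axis=1)


def median_correlation_series(
    family: ModelFamily, replicate: str, reference_k: int | None = None
) -> dict[int, float]:
    """Median best-match correlation of the reference model's states against
    each simpler model, per k."""
    models = family.models[replicate]
    ref_k = reference_k if reference_k is not None else family.k_max(replicate)
    if ref_k not in models:
        raise ValueError(f"reference model k={ref_k} missing")
    reference = models[ref_k]
    return {
        k: float(np.median(best_match_correlations(reference, m)))
        for k, m in sorted(models.items())
    }


def lloyd_kmeans(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm with random distance-weighted (k-means++) seeding.

    Uniform-random seeding merges well-separated clusters so often that the
    averaged separation ratio loses its plateau; ++-style seeding keeps the
    initial centroids distinct and spread out while remaining stochastic
    across realizations.

    Returns (assignments, within-cluster sum of squares).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of points")
    uniq = np.unique(pts, axis=0)
    if k > len(uniq):
        raise ValueError("k exceeds the number of distinct points")
    centroids = np.empty((k, pts.shape[1]))
    centroids[0] = pts[rng.integers(n)]
    d2min = cdist(pts, centroids[:1], metric="sqeuclidean")[:, 0]
    for j in range(1, k):
        total = d2min.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            centroids[j] = uniq[rng.integers(len(uniq))]
            continue
        centroids[j] = pts[rng.choice(n, p=d2min / total)]
        d2min = np.minimum(
            d2min, cdist(pts, centroids[j:j + 1], metric="sqeuclidean")[:, 0])
    prev = np.inf
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(pts, centroids, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        wss = float(d2[np.arange(n), assign].sum())
        for j in range(k):
            members = pts[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                centroids[j] = pts[d2.min(axis=1).argmax()]
        if prev - wss <= tol * max(prev, 1e-300):
            break
        prev = wss
    d2 = cdist(pts, centroids, metric="sqeuclidean")
    assign = d2.argmin(axis=1)
    wss = float(d2[np.arange(n), assign].sum())
    return assign, wss


def separation_ratio(
    pooled_emissions: np.ndarray,
    k: int,
    n_realizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean BetweenSS/TotalSS of k-means over repeated random inits."""
    pts = np.asarray(pooled_emissions, dtype=float)
    if k > pts.shape[0]:
        raise ValueError("k exceeds the number of points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tss = float(((pts - pts.mean(axis=0)) ** 2).sum())
    if tss == 0:
        return 0.0 if k == 1 else 1.0
    if k >= len(np.unique(pts, axis=0)):
        return 1.0  # one centroid per distinct point: zero within-cluster SS
    ratios = []
    for _ in range(n_realizations):
        _, wss = lloyd_kmeans(pts, k, rng)
        ratios.append(1.0 - wss / tss)
    return float(np.mean(ratios))


@dataclass
class SelectionReport:
    threshold: float
    correlation_series: dict[str, dict[int, float]]
    separation_series: dict[int, float]
    k_opt_correlation: dict[str, int] = field(default_factory=dict)
    k_opt_separation: int = 0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "strategy1_median_correlation": {
                rep: {str(k): v for k, v in series.items()}
                for rep, series in self.correlation_series.items()
            },
            "strategy1_k_opt": self.k_opt_correlation,
            "strategy2_separation_ratio": {
                str(k): v for k, v in self.separation_series.items()
            },
            "strategy2_k_opt": self.k_opt_separation,
            "note": ("strategy 1's plateau is judged by the same "
                     "fraction-of-maximum rule as strategy 2"),
        }


def _smallest_k(series: dict[int, float], threshold: float) -> int:
    k_max = max(series)
    cutoff = threshold * series[k_max]
    for k in sorted(series):
        if series[k] >= cutoff:
            return k
    logger.warning("no k reaches the threshold; returning k_max")
    return k_max


def select_state_number(
    family: ModelFamily,
    threshold: float = 0.95,
    n_realizations: int = 100,
    seed: int = 0,
) -> SelectionReport:
    """Optimal state number by both strategies.

    Strategy 1 (per replicate series): smallest k whose median best-match
    correlation against the k_max reference reaches >= threshold x its
    value at k_max. Strategy 2 (pooled): smallest k whose mean
    BetweenSS/TotalSS reaches >= threshold x the ratio at k_max.
    """
    corr_series = {
        rep: median_correlation_series(family, rep)
        for rep in family.models
    }
    k_opt_corr = {rep: _smallest_k(s, threshold) for rep, s in corr_series.items()}

    pooled = family.pooled_emissions()
    any_rep = next(iter(family.models))
    ks = family.k_values(any_rep)
    rng = np.random.default_rng(seed)
    sep_series = {
        k: separation_ratio(pooled, k, n_realizations=n_realizations, seed=rng)
        for k in ks
    }
    k_opt_sep = _smallest_k(sep_series, threshold)
    return SelectionReport(
        threshold=threshold,
        correlation_series=corr_series,
        separation_series=sep_series,
        k_opt_correlation=k_opt_corr,
        k_opt_separation=k_opt_sep,
    )
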