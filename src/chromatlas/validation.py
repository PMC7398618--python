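"""In vivo validation rate as a function of epigenomic rank.

The rank-vs-validation relationship is modelled by a cubic smoothing
spline whose smoothing parameter is solved so the effective degrees of
freedom (trace of the smoother matrix) equal a target (2 by default);
background rates come from the elements missed by the ranked feature set;
replicate datasets are combined by rank sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, eigh, solve_triangular
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationCurve",
    "fit_validation_curve",
    "background_rate",
    "combine_ranks",
    "cumulative_positive_curve",
    "tier_report",
]


def _bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    # design_matrix treats the right boundary inclusively
    return BSpline.design_matrix(x, knots, degree).toarray()


@dataclass
class ValidationCurve:
    """A fitted rank -> validation-rate function."""

    knots: np.ndarray
    coefficients: np.ndarray
    effective_df: float
    lam: float
    x_range: tuple[float, float]
    fitted: np.ndarray = field(repr=False)
    constant: bool = False

    def predict(self, ranks) -> np.ndarray:
        x = np.clip(np.asarray(ranks, dtype=float), *self.x_range)
        if self.constant:
            return np.full(x.shape, float(self.coefficients[0]))
        b = _bspline_basis(x, self.knots)
        return np.nan_to_num(b) @ self.coefficients

    def rate(self, ranks) -> np.ndarray:
        """Predicted rate clipped to [0, 1] for reporting."""
        return np.clip(self.predict(ranks), 0.0, 1.0)

    def __call__(self, ranks) -> np.ndarray:
        return self.rate(ranks)


def fit_validation_curve(
    ranks,
    labels,
    effective_df: float = 2.0,
    n_knots: int = 20,
) -> ValidationCurve:
    """Smoothing spline of 0/1 validation labels against rank.

    A cubic B-spline basis with a second-difference coefficient penalty is
    fitted with the penalty weight solved (Demmler-Reinsch) so that the
    trace of the smoother matrix equals ``effective_df``. Constant labels
    return a flagged constant fit.
    """
    x = np.asarray(ranks, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.size != y.size:
        raise ValueError("ranks and labels must align")
    if x.size < 10:
        raise ValueError("need at least 10 elements")
    if np.all(y == y[0]):
        logger.warning("constant labels: returning a constant fit")
        return ValidationCurve(
            knots=np.array([]), coefficients=np.array([y[0]]),
            effective_df=1.0, lam=float("inf"),
            x_range=(float(x.min()), float(x.max())),
            fitted=np.full(x.shape, y[0]), constant=True)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    lo, hi = float(xs[0]), float(xs[-1])
    m = min(n_knots, max(4, x.size // 4))
    inner = np.quantile(xs, np.linspace(0, 1, m))
    inner = np.unique(inner)
    knots = np.concatenate([[lo] * 3, inner, [hi] * 3])
    B = np.nan_to_num(_bspline_basis(xs, knots))
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    P = D.T @ D
    C = B.T @ B + 1e-9 * np.eye(nb)
    L = cholesky(C, lower=True)
    Linv_P = solve_triangular(L, P, lower=True)
    M = solve_triangular(L, Linv_P.T, lower=True)  # L^-1 P L^-T
    M = (M + M.T) / 2
    svals, U = eigh(M)
    svals = np.clip(svals, 0, None)
    bty = B.T @ ys
    z = U.T @ solve_triangular(L, bty, lower=True)

    def trace(lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * svals)))

    target = float(effective_df)
    lo_l, hi_l = 1e-12, 1e16
    if trace(lo_l) <= target:
        lam = lo_l
    elif trace(hi_l) >= target:
        lam = hi_l  # limit: penalty null space, trace -> its dimension
    else:
        lam = brentq(lambda t: trace(np.exp(t)) - target,
                     np.log(lo_l), np.log(hi_l), xtol=1e-12)
        lam = float(np.exp(lam))
    theta = solve_triangular(
        L, U @ (z / (1.0 + lam * svals)), lower=True, trans="T")
    fitted_sorted = B @ theta
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted
    return ValidationCurve(
        knots=knots, coefficients=theta, effective_df=trace(lam), lam=lam,
        x_range=(lo, hi), fitted=np.clip(fitted, 0.0, 1.0))


def background_rate(missed_labels) -> float:
    """Validation rate among elements missed by the ranked feature set."""
    y = np.asarray(missed_labels, dtype=float)
    if y.size == 0:
        logger.warning("empty missed set: background rate undefined")
        return float("nan")
    return float(y.mean())


def combine_ranks(
    rank_lists: list, tiebreak_keys=None
) -> np.ndarray:
    """Combined ranking by rank sums across replicate datasets.

    ``rank_lists`` holds one rank vector per dataset over the same element
    universe. Ties in the rank sum are broken by ``tiebreak_keys``
    (element coordinates) when given, else by element index. Returns the
    combined rank (1 = best) per element.
    """
    arrays = [np.asarray(r) for r in rank_lists]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("rank lists cover different element universes")
    if any(a.min() < 1 for a in arrays):
        raise ValueError("ranks must be >= 1")
    sums = np.sum(arrays, axis=0)
    if tiebreak_keys is None:
        tiebreak_keys = np.arange(n)
    order = sorted(range(n), key=lambda i: (sums[i], tiebreak_keys[i]))
    combined = np.empty(n, dtype=int)
    for rank, i in enumerate(order, start=1):
        combined[i] = rank
    return combined


def cumulative_positive_curve(ranks, labels) -> pd.DataFrame:
    """Cumulative number of positive elements as a function of rank."""
    r = np.asarray(ranks)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(r, kind="stable")
    return pd.DataFrame({
        "rank": r[order],
        "cumulative_positives": np.cumsum(y[order]),
    })


def tier_report(results: pd.DataFrame) -> pd.DataFrame:
    """Validation-rate summary per tier with pairwise Fisher's exact tests.

    ``results`` needs columns ``tier`` and ``positive`` (0/1).
    """
    tiers = sorted(results["tier"].unique())
    summary = []
    counts = {}
    for t in tiers:
        sub = results[results["tier"] == t]
        pos = int(sub["positive"].sum())
        counts[t] = (pos, len(sub))
        summary.append({"tier": t, "n": len(sub), "positive": pos,
                        "rate": pos / len(sub)})
    df = pd.DataFrame(summary).set_index("tier")
    for i, a in enumerate(tiers):
        for b in tiers[i + 1:]:
            (pa, na), (pb, nb) = counts[a], counts[b]
            _, p = sps.fisher_exact([[pa, na - pa], [pb, nb - pb]],
                                    alternative="two-sided")
            df.loc[a, f"fisher_p_vs_{b}"] = p
    return df
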