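"""Shared statistics: multiple testing, contingency tests, count tests and
the moderated t-statistic used for differential enhancer calling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "chi2_independence_2x2",
    "rate_ratio_test",
    "ModeratedTestResult",
    "moderated_t_test",
    "rank_transform",
    "pairwise_pearson",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * n / j for sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def chi2_independence_2x2(
    a_pos: int, a_tot: int, b_pos: int, b_tot: int
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, no continuity
    correction. Cells: (pos, neg) x (group a, group b).

    Returns ``(chi2, p)`` with p from the chi-square distribution, 1 df.
    """
    a, b = a_pos, a_tot - a_pos
    c, d = b_pos, b_tot - b_pos
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative and totals >= positives")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan"), float("nan")
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def rate_ratio_test(
    x1: int, x2: int, size1: float, size2: float
) -> tuple[float, float]:
    """Two-sided exact rate-ratio test for two count totals.

    Conditional on ``x1 + x2``, ``x1`` is binomial with success probability
    ``size1 / (size1 + size2)`` when the underlying normalized rates are
    equal; the exact two-sided binomial test supplies the p-value.

    Returns ``(log2_fold_change, p)`` where the fold change compares the
    library-size-normalized rates ``(x2/size2) / (x1/size1)``.
    """
    if size1 <= 0 or size2 <= 0:
        raise ValueError("library sizes must be positive")
    n = x1 + x2
    if n == 0:
        return 0.0, 1.0
    p0 = size1 / (size1 + size2)
    p = float(sps.binomtest(int(x1), int(n), p0, alternative="two-sided").pvalue)
    r1 = x1 / size1
    r2 = x2 / size2
    if r1 == 0 and r2 == 0:
        lfc = 0.0
    elif r1 == 0:
        lfc = float("inf")
    elif r2 == 0:
        lfc = float("-inf")
    else:
        lfc = float(np.log2(r2 / r1))
    return lfc, p


@dataclass
class ModeratedTestResult:
    t: np.ndarray
    p: np.ndarray
    log_fc: np.ndarray
    df_prior: float
    s2_prior: float
    df_total: float


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Matches the mean and variance of log(s2) against the theoretical
    moments of log of a scaled F(df, df_prior) variate, via digamma /
    trigamma identities. Returns ``(df_prior, s2_prior)``; ``df_prior`` is
    ``inf`` when the variances are (near-)exchangeable.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float("inf"), float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    n = z.size
    mean_e = float(np.mean(e))
    var_e = float(np.sum((e - mean_e) ** 2) / (n - 1))
    # excess variance attributable to the prior
    evar = var_e - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return float("inf"), float(np.exp(mean_e))
    # solve trigamma(d0/2) = evar for d0 by Newton iteration on x = d0/2
    x = 0.5 + 1.0 / evar  # rough inverse of trigamma
    for _ in range(100):
        f = float(special.polygamma(1, x)) - evar
        delta = -f / float(special.polygamma(2, x))
        x = max(x + delta, 1e-8)
        if abs(delta) < 1e-10 * x:
            break
    df_prior = 2 * x
    s2_prior = float(np.exp(mean_e + special.digamma(x) - np.log(x)))
    return df_prior, s2_prior


def moderated_t_test(
    group1: np.ndarray, group2: np.ndarray
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-sample t-test across many features.

    ``group1``/``group2`` are features x replicates matrices of (log) signal.
    Per-feature pooled variances are shrunk toward a prior fitted across
    features by method of moments; the t statistic uses the posterior
    variance with ``df_residual + df_prior`` degrees of freedom. Two-sided.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("feature dimension mismatch")
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 replicates per group")
    df = n1 + n2 - 2
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    ss = np.sum((g1 - m1[:, None]) ** 2, axis=1) + np.sum(
        (g2 - m2[:, None]) ** 2, axis=1
    )
    s2 = ss / df
    df_prior, s2_prior = _fit_f_dist(s2[s2 > 0], df)
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        df_total = float("inf")
    else:
        s2_post = (df * s2 + df_prior * s2_prior) / (df + df_prior)
        df_total = df + df_prior
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df=df_total)
    return ModeratedTestResult(t=t, p=p, log_fc=diff, df_prior=df_prior,
                               s2_prior=s2_prior, df_total=df_total)


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (for Spearman correlation by matrix algebra)."""
    return np.apply_along_axis(sps.rankdata, 1, np.asarray(x, dtype=float))


def pairwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt(np.sum(ac**2, axis=1))
    bn = np.sqrt(np.sum(bc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(an, bn)
    return r
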