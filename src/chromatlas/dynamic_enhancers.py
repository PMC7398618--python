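"""Temporally dynamic enhancer bins: moderated differential calling,
trajectory clustering with an elbow rule, motif enrichment against a
signal-matched background, and super-enhancer calling by the stitched
rank-signal tangent cutoff."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .core.intervals import GenomicInterval, IntervalSet
from .core.matrix import SignalGrid
from .core.stats import bh_adjust, moderated_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "call_dynamic_bins",
    "cluster_dynamic_bins",
    "ClusteringResult",
    "motif_enrichment",
    "call_super_enhancers",
]


def call_dynamic_bins(
    signal: SignalGrid,
    tissue: str,
    alpha: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dynamic flags for enhancer bins from adjacent-stage comparisons.

    Per adjacent-stage pair a moderated two-sample t-test (empirical-Bayes
    variance shrinkage) is applied to the log2 signal with two replicates
    per stage; p-values are BH-adjusted across bins within each comparison;
    a bin is dynamic when any comparison's adjusted p falls below
    ``alpha``. Bins with zero variance across all samples are excluded
    (flagged False, logged).

    Returns (flags, per-comparison table).
    """
    stages = signal.stages(tissue)
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    cols = {s: [j for j, k in enumerate(signal.samples)
                if k.tissue == tissue and k.stage == s] for s in stages}
    for s, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"stage {s}: need two replicates")
    tissue_cols = [j for s in stages for j in cols[s]]
    usable = np.ptp(signal.values[:, tissue_cols], axis=1) > 0
    if not usable.all():
        logger.warning("excluding %d zero-variance bins", int((~usable).sum()))
    flags = np.zeros(signal.n_regions, dtype=bool)
    rows = []
    idx = np.flatnonzero(usable)
    for t in range(len(stages) - 1):
        g1 = signal.values[np.ix_(idx, cols[stages[t]])]
        g2 = signal.values[np.ix_(idx, cols[stages[t + 1]])]
        res = moderated_t_test(g1, g2)
        adj = bh_adjust(res.p)
        sig = adj < alpha
        flags[idx[sig]] = True
        for local, i in enumerate(idx):
            rows.append({"bin": int(i), "transition": t,
                         "stage_from": stages[t], "stage_to": stages[t + 1],
                         "log2_fc": float(res.log_fc[local]),
                         "p": float(res.p[local]),
                         "adjusted_p": float(adj[local])})
    return flags, pd.DataFrame(rows)


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    wss_by_k: dict[int, float]
    normalized: np.ndarray
    order: np.ndarray  # row order: by cluster, then by mean signal


def cluster_dynamic_bins(
    profiles: np.ndarray,
    k_min: int = 1,
    k_max: int = 10,
    n_init: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """k-means over unit-normalized temporal profiles, k by the elbow rule.

    The elbow is quantified as the k maximizing the second difference of
    log within-cluster sum of squares over the scanned range (the raw
    second difference is dominated by the first drop on convexly decaying
    curves); a flat curve (all rows identical) degenerates to k = 1.
    """
    x = np.asarray(profiles, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two dynamic bins")
    norms = np.sqrt((x**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("zero rows cannot be unit-normalized")
    xn = x / norms[:, None]
    n_distinct = np.unique(xn.round(12), axis=0).shape[0]
    k_hi = min(k_max, x.shape[0], max(n_distinct, 1))
    if k_hi < k_max:
        logger.warning("k range truncated at %d", k_hi)
    wss: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in range(k_min, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(xn)
        wss[k] = float(km.inertia_)
        models[k] = km
    ks = sorted(wss)
    if wss[ks[0]] <= 1e-12 or len(ks) < 3:
        k_star = ks[0]
    else:
        logw = {k: np.log(max(w, 1e-12)) for k, w in wss.items()}
        second_diff = {
            ks[i]: logw[ks[i - 1]] - 2 * logw[ks[i]] + logw[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        k_star = max(second_diff, key=second_diff.get)  # type: ignore[arg-type]
    labels = models[k_star].labels_ if k_star in models else np.zeros(len(xn), int)
    mean_signal = x.mean(axis=1)
    order = np.lexsort((-mean_signal, labels))
    return ClusteringResult(k=k_star, labels=np.asarray(labels),
                            wss_by_k=wss, normalized=xn, order=order)


def _matched_background(
    cluster_signal: np.ndarray,
    pool_signal: np.ndarray,
    rng: np.random.Generator,
    n_strata: int = 20,
) -> np.ndarray:
    """Indices into the pool, sampled with replacement so the pool's mean
    signal distribution matches the cluster's (equal-width strata)."""
    lo = min(cluster_signal.min(), pool_signal.min())
    hi = max(cluster_signal.max(), pool_signal.max())
    if hi == lo:
        return rng.integers(0, len(pool_signal), size=len(cluster_signal))
    edges = np.linspace(lo, hi, n_strata + 1)
    c_strat = np.clip(np.digitize(cluster_signal, edges) - 1, 0, n_strata - 1)
    p_strat = np.clip(np.digitize(pool_signal, edges) - 1, 0, n_strata - 1)
    picks = []
    for s in range(n_strata):
        need = int((c_strat == s).sum())
        if need == 0:
            continue
        avail = np.flatnonzero(p_strat == s)
        if len(avail) == 0:
            logger.warning("stratum %d empty in pool; sampling whole pool", s)
            avail = np.arange(len(pool_signal))
        picks.append(rng.choice(avail, size=need, replace=True))
    return np.concatenate(picks)


def motif_enrichment(
    occurrences: pd.DataFrame,
    cluster_bins: dict[str, list[str]],
    nondynamic_bins: list[str],
    mean_signal: pd.Series,
    n_strata: int = 20,
    alternative: str = "two-sided",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster per-motif Fisher's exact enrichment against a
    signal-matched non-dynamic background.

    ``occurrences`` is a bin x motif 0/1 frame; ``mean_signal`` maps bins to
    average signal; the non-dynamic pool is resampled with replacement per
    signal stratum to match each cluster's distribution. p-values are
    BH-adjusted across motifs within each cluster; motifs absent everywhere
    are skipped.
    """
    rng = np.random.default_rng(seed)
    pool = [b for b in nondynamic_bins if b in occurrences.index]
    pool_occ = occurrences.loc[pool].to_numpy()
    pool_sig = mean_signal.reindex(pool).to_numpy(float)
    rows = []
    for cname, bins in cluster_bins.items():
        bins = [b for b in bins if b in occurrences.index]
        if len(pool) < len(bins):
            raise ValueError(f"pool smaller than cluster {cname!r}")
        c_occ = occurrences.loc[bins].to_numpy()
        c_sig = mean_signal.reindex(bins).to_numpy(float)
        bg_idx = _matched_background(c_sig, pool_sig, rng, n_strata)
        bg_occ = pool_occ[bg_idx]
        motif_rows = []
        for m, motif in enumerate(occurrences.columns):
            a = int(c_occ[:, m].sum())
            c = int(bg_occ[:, m].sum())
            if a == 0 and c == 0:
                continue
            b = len(bins) - a
            d = len(bg_idx) - c
            table = [[a, b], [c, d]]
            odds, p = sps.fisher_exact(table, alternative=alternative)
            motif_rows.append({"cluster": cname, "motif": motif,
                               "cluster_pos": a, "background_pos": c,
                               "odds_ratio": float(odds), "p": float(p)})
        if motif_rows:
            sub = pd.DataFrame(motif_rows)
            sub["adjusted_p"] = bh_adjust(sub["p"].to_numpy())
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["cluster", "motif", "cluster_pos",
                                     "background_pos", "odds_ratio", "p",
                                     "adjusted_p"])
    return pd.concat(rows, ignore_index=True)


def call_super_enhancers(
    peaks: IntervalSet,
    stitch: int = 12_500,
    tss: list[tuple[str, int]] | None = None,
    tss_flank: int = 2_500,
    slope_factor: float = 1.0,
) -> pd.DataFrame:
    """Stitch peaks and call super-enhancers by the rank-signal tangent rule.

    Peaks within ``stitch`` bp of each other are stitched; stitched regions
    are ranked by total signal; with both axes scaled, the cutoff is the
    point where the tangent to the signal-vs-rank curve has slope
    ``slope_factor`` (1 by default); regions with signal strictly above the
    cutoff are super-enhancers. Optional TSS exclusion removes peaks within
    ``tss_flank`` of a TSS before stitching.
    """
    if peaks.scores is None:
        raise ValueError("peaks require H3K27ac signal scores")
    keep = list(range(len(peaks)))
    if tss is not None:
        from .core.intervals import window_overlap
        near = window_overlap(peaks, tss, tss_flank)
        keep = [i for i in keep if not near[i]]
    items = sorted(
        ((peaks.intervals[i], peaks.scores[i]) for i in keep),
        key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    stitched: list[dict] = []
    for iv, score in items:
        if (stitched and stitched[-1]["chrom"] == iv.chrom
                and iv.start - stitched[-1]["end"] <= stitch):
            cur = stitched[-1]
            cur["end"] = max(cur["end"], iv.end)
            cur["signal"] += score
            cur["n_constituents"] += 1
        else:
            stitched.append({"chrom": iv.chrom, "start": iv.start,
                             "end": iv.end, "signal": float(score),
                             "n_constituents": 1})
    if len(stitched) < 3:
        raise ValueError("need at least three stitched regions")
    df = pd.DataFrame(stitched)
    # tangent cutoff on the ascending scaled curve
    values = np.sort(df["signal"].to_numpy())
    n = len(values)
    slope = slope_factor * (values.max() - values.min()) / n
    if slope == 0:
        cutoff = float(values[0])  # degenerate: nothing is above
    else:
        xs = np.arange(1, n + 1)
        below = [
            int(np.sum(values <= (xs * slope + (values[x - 1] - slope * x))))
            for x in xs
        ]
        x_pt = int(xs[int(np.argmin(below))])
        cutoff = float(values[x_pt - 1])
    df["rank"] = df["signal"].rank(ascending=False, method="first").astype(int)
    df["is_super"] = df["signal"] > cutoff
    df.attrs["cutoff"] = cutoff
    return df.sort_values("rank").reset_index(drop=True)


def enhancer_bins(
    state5_intervals: list[IntervalSet],
    genome: dict[str, int],
    bin_bp: int = 1_000,
) -> IntervalSet:
    """1-kb genomic bins overlapping a strong-enhancer call in >=1 stage."""
    flags: dict[str, np.ndarray] = {
        chrom: np.zeros(int(np.ceil(length / bin_bp)), dtype=bool)
        for chrom, length in genome.items()
    }
    for calls in state5_intervals:
        for iv in calls.intervals:
            if iv.chrom not in flags:
                continue
            b0 = iv.start // bin_bp
            b1 = (iv.end - 1) // bin_bp + 1
            flags[iv.chrom][b0:b1] = True
    ivs = []
    for chrom, f in flags.items():
        length = genome[chrom]
        for b in np.flatnonzero(f):
            ivs.append(GenomicInterval(chrom, int(b * bin_bp),
                                       int(min((b + 1) * bin_bp, length))))
    return IntervalSet(ivs)
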