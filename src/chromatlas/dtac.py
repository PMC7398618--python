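"""The accessible-chromatin (d-TAC) catalogue and its dynamics and
correlation structure.

Replicated peak sets from all tissue-stages are concatenated, merged and
labelled to form a non-overlapping catalogue of regions accessible in at
least one tissue-stage; regions are proximal or distal according to a
+/- 1-kb TSS window. Temporal dynamics are called between sequential
stages (fold change >= 2, p <= 0.05); correlation structure is mapped
within TADs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core.intervals import GenomicInterval, IntervalSet, merge_intervals, window_overlap
from .core.matrix import SignalGrid
from .core.stats import bh_adjust, pairwise_pearson, rate_ratio_test
from .states import Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "DTacCatalogue",
    "build_catalogue",
    "state_enrichment",
    "sensitivity_specificity",
    "call_dynamic",
    "gain_loss_state_transition_enrichment",
    "match_by_max_overlap",
    "offset_profile",
    "correlation_map",
    "distance_profile",
]


@dataclass
class DTacCatalogue:
    regions: IntervalSet                       # merged, non-overlapping
    membership: pd.DataFrame                   # region x "tissue:stage" bool
    proximity: list[str]                       # "proximal" / "distal"

    def __post_init__(self) -> None:
        if not self.regions.is_merged():
            raise ValueError("catalogue regions must be non-overlapping")
        if not self.membership.to_numpy().any(axis=1).all():
            raise ValueError("every region must be accessible in >=1 tissue-stage")


def build_catalogue(
    peaks: dict[tuple[str, str], IntervalSet],
    tss: list[tuple[str, int]],
    flank: int = 1_000,
) -> DTacCatalogue:
    """Concatenate, merge, sort and label replicated peak sets.

    Membership marks the tissue-stages whose constituent peaks fed each
    merged region; proximity classifies regions against TSS +/- ``flank``.
    """
    if not peaks:
        raise ValueError("no peak sets supplied")
    ivs: list[GenomicInterval] = []
    labels: list[str] = []
    sample_names = [f"{t}:{s}" for t, s in peaks]
    for (t, s), pk in peaks.items():
        ivs.extend(pk.intervals)
        labels.extend([f"{t}:{s}"] * len(pk))
    merged = merge_intervals(IntervalSet(ivs, labels))
    member = np.zeros((len(merged), len(sample_names)), dtype=bool)
    col = {name: j for j, name in enumerate(sample_names)}
    for i, lab in enumerate(merged.labels or []):
        for src in lab.split(","):
            member[i, col[src]] = True
    membership = pd.DataFrame(member, columns=sample_names)
    prox_flags = window_overlap(merged, tss, flank)
    proximity = ["proximal" if f else "distal" for f in prox_flags]
    return DTacCatalogue(IntervalSet(list(merged.intervals)), membership, proximity)


def _overlap_bp_by_label(regions: IntervalSet, seg: Segmentation) -> dict[str, int]:
    """bp of ``regions`` overlapping each state of a segmentation."""
    tracks = seg.tracks()
    out: dict[str, int] = {}
    for iv in regions.intervals:
        tr = tracks.get(iv.chrom)
        if tr is None:
            continue
        bounds, labels = tr
        i0 = max(int(np.searchsorted(bounds, iv.start, side="right")) - 1, 0)
        i1 = int(np.searchsorted(bounds, iv.end, side="left"))
        for k in range(i0, i1):
            lo = max(iv.start, int(bounds[k]))
            hi = min(iv.end, int(bounds[k + 1]))
            if hi > lo:
                out[labels[k]] = out.get(labels[k], 0) + (hi - lo)
    return out


def state_enrichment(
    catalogue: DTacCatalogue, consensus: Segmentation
) -> pd.DataFrame:
    """Observed/expected bp enrichment of the catalogue per chromatin state.

    expected bp for state s = total catalogue bp x genome fraction of s.
    States with zero genome coverage report NA.
    """
    genome = consensus.genome_length()
    state_bp: dict[str, int] = {}
    for iv, lab in zip(consensus.intervals.intervals, consensus.intervals.labels):
        state_bp[lab] = state_bp.get(lab, 0) + len(iv)
    observed = _overlap_bp_by_label(catalogue.regions, consensus)
    total_dtac = catalogue.regions.total_bases()
    rows = []
    for state in sorted(state_bp):
        frac = state_bp[state] / genome
        obs = observed.get(state, 0)
        enr = obs / (total_dtac * frac) if frac > 0 else float("nan")
        rows.append({"state": state, "observed_bp": obs,
                     "genome_fraction": frac, "enrichment": enr})
    return pd.DataFrame(rows).set_index("state")


def _overlaps_any(queries: IntervalSet, subject: IntervalSet) -> np.ndarray:
    subj = merge_intervals(subject).by_chrom() if len(subject) else {}
    flags = np.zeros(len(queries), dtype=bool)
    for i, iv in enumerate(queries.intervals):
        arr = subj.get(iv.chrom)
        if arr is None:
            continue
        j = int(np.searchsorted(arr[:, 0], iv.end, side="left"))
        flags[i] = bool(np.any(arr[:j, 1] > iv.start))
    return flags


def sensitivity_specificity(
    accessible: IntervalSet,
    reference_positives: IntervalSet,
    reference_negatives: IntervalSet,
) -> dict[str, float]:
    """Sensitivity = fraction of reference positives overlapped by the
    accessible regions; specificity = fraction of reference negatives NOT
    overlapped."""
    if len(reference_positives) == 0 or len(reference_negatives) == 0:
        raise ValueError("reference sets must be non-empty")
    sens = float(_overlaps_any(reference_positives, accessible).mean())
    spec = float((~_overlaps_any(reference_negatives, accessible)).mean())
    return {"sensitivity": sens, "specificity": spec}


def call_dynamic(
    counts: SignalGrid,
    tissue: str,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Temporally dynamic regions between sequential stages of one tissue.

    Replicate counts are summed per stage, library-size-normalized, and a
    two-sided exact rate-ratio (binomial) test is applied per region per
    adjacent-stage pair. Calls with |fold change| >= ``min_fold`` and
    p <= ``alpha`` are retained (raw p by default; ``adjust`` switches to
    BH-adjusted p).
    """
    if counts.units != "raw_count":
        raise ValueError("call_dynamic expects raw counts")
    stages = counts.stages(tissue)
    cols_by_stage = {
        s: [j for j, k in enumerate(counts.samples)
            if k.tissue == tissue and k.stage == s]
        for s in stages
    }
    rows = []
    min_lfc = np.log2(min_fold)
    for t in range(len(stages) - 1):
        s1, s2 = stages[t], stages[t + 1]
        x1 = counts.values[:, cols_by_stage[s1]].sum(axis=1)
        x2 = counts.values[:, cols_by_stage[s2]].sum(axis=1)
        size1, size2 = float(x1.sum()), float(x2.sum())
        if size1 == 0 or size2 == 0:
            logger.warning("stage with zero total counts; transition %s->%s skipped",
                           s1, s2)
            continue
        pvals = np.ones(len(x1))
        lfcs = np.zeros(len(x1))
        cache: dict[tuple[int, int], tuple[float, float]] = {}
        for i, (a, b) in enumerate(zip(x1.astype(int), x2.astype(int))):
            key = (a, b)
            if key not in cache:
                cache[key] = rate_ratio_test(a, b, size1, size2)
            lfcs[i], pvals[i] = cache[key]
        crit = bh_adjust(pvals) if adjust else pvals
        hit = (np.abs(lfcs) >= min_lfc) & (crit <= alpha)
        for i in np.flatnonzero(hit):
            rows.append({
                "region": int(i), "tissue": tissue, "transition": t,
                "stage_from": s1, "stage_to": s2,
                "log2_fold_change": float(lfcs[i]), "p": float(pvals[i]),
                "adjusted_p": float(crit[i]) if adjust else float("nan"),
                "direction": "gain" if lfcs[i] > 0 else "loss",
            })
    return pd.DataFrame(
        rows, columns=["region", "tissue", "transition", "stage_from",
                       "stage_to", "log2_fold_change", "p", "adjusted_p",
                       "direction"])


def _state_pair_bp(
    regions: IntervalSet, seg_n: Segmentation, seg_n1: Segmentation
) -> dict[tuple[str, str], int]:
    """bp of ``regions`` in each (state at n, state at n+1) combination."""
    tn, tn1 = seg_n.tracks(), seg_n1.tracks()
    out: dict[tuple[str, str], int] = {}
    for iv in regions.intervals:
        if iv.chrom not in tn or iv.chrom not in tn1:
            continue
        ba, la = tn[iv.chrom]
        bb, lb = tn1[iv.chrom]
        cuts = np.union1d(ba[(ba > iv.start) & (ba < iv.end)],
                          bb[(bb > iv.start) & (bb < iv.end)])
        bounds = np.concatenate([[iv.start], cuts, [iv.end]])
        mids = (bounds[:-1] + bounds[1:]) // 2
        ia = np.clip(np.searchsorted(ba, mids, side="right") - 1, 0, len(la) - 1)
        ib = np.clip(np.searchsorted(bb, mids, side="right") - 1, 0, len(lb) - 1)
        for k in range(len(mids)):
            key = (str(la[ia[k]]), str(lb[ib[k]]))
            out[key] = out.get(key, 0) + int(bounds[k + 1] - bounds[k])
    return out


def gain_loss_state_transition_enrichment(
    dynamic_calls: pd.DataFrame,
    catalogue: DTacCatalogue,
    seg_n: Segmentation,
    seg_n1: Segmentation,
    transition: int,
) -> dict[str, pd.DataFrame]:
    """Per-direction enrichment of dynamic bp over (state_n, state_n+1)
    combinations, relative to the expectation from all catalogue regions."""
    expected = _state_pair_bp(catalogue.regions, seg_n, seg_n1)
    total_exp = sum(expected.values())
    out: dict[str, pd.DataFrame] = {}
    calls = dynamic_calls[dynamic_calls["transition"] == transition]
    for direction in ("gain", "loss"):
        idx = calls.loc[calls["direction"] == direction, "region"].astype(int)
        states_n = sorted({k[0] for k in expected})
        states_n1 = sorted({k[1] for k in expected})
        mat = pd.DataFrame(np.nan, index=states_n, columns=states_n1)
        if len(idx) == 0:
            logger.warning("no %s calls at transition %d", direction, transition)
            out[direction] = mat
            continue
        sub = IntervalSet([catalogue.regions.intervals[i] for i in idx])
        observed = _state_pair_bp(sub, seg_n, seg_n1)
        total_obs = sum(observed.values())
        for (a, b), ebp in expected.items():
            obs_frac = observed.get((a, b), 0) / total_obs if total_obs else 0.0
            exp_frac = ebp / total_exp
            mat.loc[a, b] = obs_frac / exp_frac if exp_frac > 0 else np.nan
        out[direction] = mat
    return out


def match_by_max_overlap(
    queries: IntervalSet, targets: IntervalSet
) -> list[int | None]:
    """Index of the target with the largest bp overlap per query (ties to the
    leftmost target); None where nothing overlaps."""
    tgt = targets.by_chrom()
    # map sorted array rows back to original indices
    idx_map: dict[str, list[int]] = {}
    for i, iv in enumerate(targets.intervals):
        idx_map.setdefault(iv.chrom, []).append(i)
    for chrom in idx_map:
        idx_map[chrom].sort(key=lambda i: (targets.intervals[i].start,
                                           targets.intervals[i].end))
    out: list[int | None] = []
    for iv in queries.intervals:
        arr = tgt.get(iv.chrom)
        if arr is None:
            out.append(None)
            continue
        best, best_bp = None, 0
        for row, orig in zip(arr, idx_map[iv.chrom]):
            bp = min(iv.end, int(row[1])) - max(iv.start, int(row[0]))
            if bp > best_bp:
                best, best_bp = orig, bp
        out.append(best)
    return out


def _stage_log_means(signal: SignalGrid, tissue: str) -> tuple[np.ndarray, list[str]]:
    """Region x stage mean log2 signal for one tissue; raw counts are
    library-size-normalized first."""
    stages = signal.stages(tissue)
    mats = []
    for s in stages:
        cols = [j for j, k in enumerate(signal.samples)
                if k.tissue == tissue and k.stage == s]
        block = signal.values[:, cols]
        if signal.units == "raw_count":
            libs = block.sum(axis=0)
            libs[libs == 0] = 1.0
            block = block / libs * libs.mean()
            mats.append(np.log2(block.mean(axis=1) + 0.5))
        else:
            mats.append(block.mean(axis=1))
    return np.column_stack(mats), stages


def offset_profile(
    dynamic_elements: IntervalSet,
    element_transitions: list[int],
    signal: SignalGrid,
    tissue: str,
) -> pd.DataFrame:
    """Mean log2 fold change of ``signal`` at dynamic elements, re-indexed by
    offset relative to each element's own transition.

    Elements are matched to the signal's regions by largest bp overlap;
    unmatched elements are skipped and counted. Offset 0 is the element's
    transition, -1 the one before, and so on.
    """
    matches = match_by_max_overlap(dynamic_elements, signal.regions)
    log_means, stages = _stage_log_means(signal, tissue)
    n_tr = len(stages) - 1
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    skipped = 0
    for m, t0 in zip(matches, element_transitions):
        if m is None:
            skipped += 1
            continue
        for t in range(n_tr):
            off = t - t0
            lfc = log_means[m, t + 1] - log_means[m, t]
            sums[off] = sums.get(off, 0.0) + lfc
            counts[off] = counts.get(off, 0) + 1
    if skipped:
        logger.warning("offset_profile: %d elements had no overlapping region",
                       skipped)
    rows = [{"offset": off, "mean_log2_fc": sums[off] / counts[off],
             "n": counts[off]} for off in sorted(sums)]
    df = pd.DataFrame(rows, columns=["offset", "mean_log2_fc", "n"])
    df.attrs["skipped"] = skipped
    return df


def _prepare_log2(signal: SignalGrid, pseudocount: float = 0.5) -> np.ndarray:
    if signal.units == "RPKM":
        return np.log2(signal.values + pseudocount)
    return signal.values


def _tad_assignment(regions: IntervalSet, tads: IntervalSet) -> np.ndarray:
    """TAD index containing each region midpoint; -1 when outside all TADs."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for ti, iv in enumerate(tads.intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, ti))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out = np.full(len(regions), -1, dtype=int)
    for i, iv in enumerate(regions.intervals):
        for s, e, ti in by_chrom.get(iv.chrom, []):
            if s <= iv.midpoint < e:
                out[i] = ti
                break
    return out


def correlation_map(
    signal: SignalGrid,
    tads: IntervalSet,
    threshold: float = 0.7,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Same-TAD region pairs with Pearson correlation >= ``threshold``.

    ``signal`` should be RPKM (log2-transformed here with a pseudocount) or
    already log2. Constant rows are skipped with a warning.
    """
    x = _prepare_log2(signal, pseudocount)
    tad_of = _tad_assignment(signal.regions, tads)
    variable = np.ptp(x, axis=1) > 0
    if not variable.all():
        logger.warning("correlation_map: skipping %d constant regions",
                       int((~variable).sum()))
    rows = []
    for ti in np.unique(tad_of):
        if ti < 0:
            continue
        members = np.flatnonzero((tad_of == ti) & variable)
        if len(members) < 2:
            continue
        r = pairwise_pearson(x[members], x[members])
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if r[a, b] >= threshold:
                    rows.append({"region_a": int(members[a]),
                                 "region_b": int(members[b]),
                                 "pcc": float(r[a, b]), "tad": int(ti)})
    return pd.DataFrame(rows, columns=["region_a", "region_b", "pcc", "tad"])


def distance_profile(
    signal: SignalGrid,
    tads: IntervalSet,
    bin_bp: int = 10_000,
    max_dist: int = 2_000_000,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mean pairwise correlation vs midpoint distance, intra- vs inter-TAD.

    Regions are assigned to ``bin_bp`` bins by midpoint; all region pairs
    within ``max_dist`` contribute to the (distance, intra/inter) means,
    averaged per chromosome and then across chromosomes. At each distance a
    two-sided Wilcoxon signed-rank test compares intra vs inter means
    paired by chromosome (chromosomes carrying both kinds of pair).
    """
    x = _prepare_log2(signal, pseudocount)
    tad_of = _tad_assignment(signal.regions, tads)
    mids = np.array([iv.midpoint for iv in signal.regions.intervals])
    chroms = np.array([iv.chrom for iv in signal.regions.intervals])
    bins = mids // bin_bp
    variable = np.ptp(x, axis=1) > 0
    max_sep = max_dist // bin_bp
    # per (distance, chromosome) correlation lists, split by TAD sharing
    acc: dict[tuple[int, str, bool], list[float]] = {}
    for chrom in np.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & variable)
        if len(idx) < 2:
            continue
        r = pairwise_pearson(x[idx], x[idx])
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                sep = abs(int(bins[i]) - int(bins[j]))
                if sep == 0 or sep > max_sep:
                    continue
                same = tad_of[i] >= 0 and tad_of[i] == tad_of[j]
                acc.setdefault((sep, str(chrom), same), []).append(
                    float(r[a, b]))
    rows = []
    for sep in sorted({k[0] for k in acc}):
        intra_by_chrom = {c: float(np.mean(v))
                          for (s, c, same), v in acc.items()
                          if s == sep and same}
        inter_by_chrom = {c: float(np.mean(v))
                          for (s, c, same), v in acc.items()
                          if s == sep and not same}
        n_intra = sum(len(v) for (s, c, same), v in acc.items()
                      if s == sep and same)
        n_inter = sum(len(v) for (s, c, same), v in acc.items()
                      if s == sep and not same)
        shared = sorted(set(intra_by_chrom) & set(inter_by_chrom))
        p = float("nan")
        if len(shared) >= 5:
            diffs = np.array([intra_by_chrom[c] - inter_by_chrom[c]
                              for c in shared])
            if np.any(diffs != 0):
                p = float(sps.wilcoxon(diffs, alternative="two-sided").pvalue)
        rows.append({
            "distance": sep * bin_bp,
            "mean_pcc_intra": (float(np.mean(list(intra_by_chrom.values())))
                               if intra_by_chrom else np.nan),
            "mean_pcc_inter": (float(np.mean(list(inter_by_chrom.values())))
                               if inter_by_chrom else np.nan),
            "n_intra": n_intra, "n_inter": n_inter,
            "n_paired": len(shared), "wilcoxon_p": p,
        })
    return pd.DataFrame(rows)
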