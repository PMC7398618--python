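"""Polycomb-target classification of TSSs and genes, and contingency
enrichment among gene subsets.

A TSS is *active* in a tissue-stage when its promoter window overlaps the
active-promoter state (1) and none of the repressive states (3, 13, 14);
it is *repressed* when the window overlaps the Polycomb state (13) and
none of the active states (1, 2, 4, 5, 6, 7, 10, 12); otherwise it is
unclassified. A gene is a putative PcG target when it has at least one
repressed TSS in at least one tissue-stage.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core.genes import GeneAnnotation
from .core.stats import chi2_independence_2x2
from .states import Segmentation

logger = logging.getLogger(__name__)

ACTIVE_STATE = "1"
REPRESSIVE_STATES = frozenset({"3", "13", "14"})
POLYCOMB_STATE = "13"
ACTIVE_STATES = frozenset({"1", "2", "4", "5", "6", "7", "10", "12"})

__all__ = [
    "classify_tss",
    "classify_atlas",
    "classify_genes",
    "cumulative_fraction_curve",
    "two_by_two_enrichment",
]


def _states_in_window(tracks, chrom: str, lo: int, hi: int) -> set[str] | None:
    tr = tracks.get(chrom)
    if tr is None:
        return None
    bounds, labels = tr
    if hi <= bounds[0] or lo >= bounds[-1]:
        return None
    i0 = max(int(np.searchsorted(bounds, lo, side="right")) - 1, 0)
    i1 = int(np.searchsorted(bounds, hi, side="left"))
    return set(labels[i0:i1])


def classify_tss(
    tss: tuple[str, int],
    consensus: Segmentation,
    window: int = 2_000,
    _tracks=None,
) -> str:
    """Label one TSS in one tissue-stage: active / repressed / unclassified.

    ``window`` is the total window width centred on the TSS (2 kb total,
    i.e. TSS +/- 1 kb by default; configurable).
    """
    chrom, pos = str(tss[0]), int(tss[1])
    tracks = _tracks if _tracks is not None else consensus.tracks()
    half = window // 2
    states = _states_in_window(tracks, chrom, max(pos - half, 0), pos + half)
    if states is None:
        logger.warning("TSS %s:%d off the segmented genome", chrom, pos)
        return "unclassified"
    if ACTIVE_STATE in states and not (states & REPRESSIVE_STATES):
        return "active"
    if POLYCOMB_STATE in states and not (states & ACTIVE_STATES):
        return "repressed"
    return "unclassified"


def classify_atlas(
    annotation: Sequence[GeneAnnotation],
    consensus_by_sample: Mapping[tuple[str, str], Segmentation],
    window: int = 2_000,
) -> pd.DataFrame:
    """Classify every TSS of every gene in every tissue-stage.

    Returns a frame with columns gene_id, tissue, stage, tss, label.
    """
    rows = []
    for (tissue, stage), consensus in consensus_by_sample.items():
        tracks = consensus.tracks()
        for g in annotation:
            for t in g.tss_positions:
                label = classify_tss((g.chrom, t), consensus, window,
                                     _tracks=tracks)
                rows.append((g.gene_id, tissue, stage, t, label))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "stage", "tss", "label"])


def classify_genes(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per-gene PcG-target flags from the per-TSS classification table.

    ``n_tissue_stages_repressed`` counts tissue-stages with at least one
    repressed TSS; a gene is a PcG target iff that count is >= 1.
    """
    df = classifications
    rep = df[df["label"] == "repressed"]
    counts = (rep.groupby("gene_id")[["tissue", "stage"]]
              .apply(lambda x: x.drop_duplicates().shape[0]))
    out = pd.DataFrame({"gene_id": sorted(df["gene_id"].unique())})
    out["n_tissue_stages_repressed"] = (
        out["gene_id"].map(counts).fillna(0).astype(int))
    out["is_pcg_target"] = out["n_tissue_stages_repressed"] >= 1
    return out.set_index("gene_id")


def cumulative_fraction_curve(
    gene_labels: pd.DataFrame,
    gene_subsets: Mapping[str, Iterable[str]],
    max_count: int | None = None,
) -> pd.DataFrame:
    """Fraction of each subset repressed in at least x tissue-stages,
    for x = 1..max_count.

    The value at x=1 is the subset's PcG-target fraction; the curve is
    non-increasing by construction.
    """
    n_rep = gene_labels["n_tissue_stages_repressed"]
    if max_count is None:
        max_count = max(int(n_rep.max()), 1)
    xs = np.arange(1, max_count + 1)
    data = {"min_tissue_stages": xs}
    for name, subset in gene_subsets.items():
        subset = [g for g in subset]
        if not subset:
            raise ValueError(f"subset {name!r} is empty")
        counts = n_rep.reindex(subset).fillna(0).to_numpy()
        data[name] = [(counts >= x).mean() for x in xs]
    return pd.DataFrame(data)


def two_by_two_enrichment(
    a_pos: int, a_tot: int, b_pos: int, b_tot: int
) -> dict:
    """Fold enrichment and chi-square independence test on a 2x2 table.

    fold = (a_pos/a_tot) / (b_pos/b_tot); the chi-square statistic is the
    Pearson statistic without continuity correction, 1 df.
    """
    if min(a_pos, b_pos) < 0 or a_tot < a_pos or b_tot < b_pos:
        raise ValueError("counts must be non-negative with totals >= positives")
    chi2, p = chi2_independence_2x2(a_pos, a_tot, b_pos, b_tot)
    if b_pos == 0:
        logger.warning("reference positives are zero; fold undefined")
        return {"fold": float("inf"), "chi2": chi2, "p": p, "fold_defined": False}
    fold = (a_pos / a_tot) / (b_pos / b_tot)
    return {"fold": fold, "chi2": chi2, "p": p, "fold_defined": True}
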