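"""Replicate-consensus chromatin-state segmentations and their summaries:
coverage, between-sample variability, temporal transition graphs, and
state-based sample clustering.

A segmentation partitions each chromosome into labelled intervals; the
replicate consensus keeps a state where both replicates agree and assigns
the sentinel ``NRS`` ("no reproducible signal") elsewhere. The sentinel is
distinct from the no-signal state (state 15), which means no signal in
both replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core.intervals import GenomicInterval, IntervalSet, merge_intervals
from .core.matrix import SampleKey

logger = logging.getLogger(__name__)

SENTINEL = "NRS"

__all__ = [
    "SENTINEL",
    "Segmentation",
    "consensus_segmentation",
    "state_coverage",
    "functional_class_coverage",
    "variability_fraction",
    "transition_graph",
    "transition_graph_series",
    "cluster_samples_by_state",
    "StateClustering",
]


@dataclass
class Segmentation:
    """A labelled partition of the genome for one sample (or consensus)."""

    sample: SampleKey
    intervals: IntervalSet

    def __post_init__(self) -> None:
        if self.intervals.labels is None:
            raise ValueError("segmentation intervals require state labels")

    def tracks(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (bounds, labels): bounds has n+1 entries framing n
        contiguous segments. Raises if intervals overlap or leave gaps."""
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, lab in zip(self.intervals.intervals, self.intervals.labels):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, lab))
        out = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: segmentation has gaps or overlaps")
            bounds = np.concatenate([starts, ends[-1:]])
            labels = np.array([r[2] for r in rows], dtype=object)
            out[chrom] = (bounds, labels)
        return out

    def genome_length(self) -> int:
        return sum(len(iv) for iv in self.intervals.intervals)

    def state_intervals(self, states) -> IntervalSet:
        """Intervals whose label is in ``states`` (a set of labels)."""
        states = set(states)
        keep = [i for i, lab in enumerate(self.intervals.labels)
                if lab in states]
        return IntervalSet([self.intervals.intervals[i] for i in keep],
                           [self.intervals.labels[i] for i in keep])


def _align(a: Segmentation, b: Segmentation):
    """Yield (chrom, seg_lengths, labels_a, labels_b) over the common
    breakpoint lattice. The two segmentations must cover identical spans."""
    ta, tb = a.tracks(), b.tracks()
    if set(ta) != set(tb):
        raise ValueError("segmentations cover different chromosomes")
    for chrom in sorted(ta):
        ba, la = ta[chrom]
        bb, lb = tb[chrom]
        if ba[0] != bb[0] or ba[-1] != bb[-1]:
            raise ValueError(f"{chrom}: replicate genomes disagree in length")
        bounds = np.union1d(ba, bb)
        mids = (bounds[:-1] + bounds[1:]) // 2
        ia = np.searchsorted(ba, mids, side="right") - 1
        ib = np.searchsorted(bb, mids, side="right") - 1
        yield chrom, np.diff(bounds), bounds, la[ia], lb[ib]


def _runs_to_intervals(chrom: str, bounds: np.ndarray, labels: np.ndarray):
    """Collapse consecutive equal labels into maximal intervals."""
    ivs, labs = [], []
    start = bounds[0]
    cur = labels[0]
    for i in range(1, len(labels)):
        if labels[i] != cur:
            ivs.append(GenomicInterval(chrom, int(start), int(bounds[i])))
            labs.append(cur)
            start = bounds[i]
            cur = labels[i]
    ivs.append(GenomicInterval(chrom, int(start), int(bounds[-1])))
    labs.append(cur)
    return ivs, labs


def consensus_segmentation(rep1: Segmentation, rep2: Segmentation) -> Segmentation:
    """Per-base consensus: the shared state where replicates agree, the
    sentinel ``NRS`` where they disagree. Output intervals are maximal runs."""
    if (rep1.sample.tissue, rep1.sample.stage) != (rep2.sample.tissue, rep2.sample.stage):
        raise ValueError("replicates must share tissue and stage")
    ivs: list[GenomicInterval] = []
    labs: list[str] = []
    for chrom, _, bounds, la, lb in _align(rep1, rep2):
        merged = np.where(la == lb, la, SENTINEL)
        civ, clab = _runs_to_intervals(chrom, bounds, merged)
        ivs.extend(civ)
        labs.extend(clab)
    key = SampleKey(rep1.sample.tissue, rep1.sample.stage, "consensus")
    return Segmentation(key, IntervalSet(ivs, labs))


def state_coverage(consensus: Segmentation, denominator: int | None = None) -> dict:
    """Per-state covered bp and genome fraction.

    ``denominator`` defaults to the segmentation's covered length; for real
    mm10 runs the annotated-sequence total (2,725,535,600 bp) is the
    documented choice.
    """
    denom = denominator if denominator is not None else consensus.genome_length()
    bp: dict[str, int] = {}
    for iv, lab in zip(consensus.intervals.intervals, consensus.intervals.labels):
        bp[lab] = bp.get(lab, 0) + len(iv)
    return {
        state: {"bp": n, "fraction": n / denom}
        for state, n in sorted(bp.items())
    }


def functional_class_coverage(
    consensus_set: list[Segmentation],
    classes: dict[str, str],
    exclusions: frozenset[str] | set[str] = frozenset({"11", "15"}),
    denominator: int | None = None,
) -> float:
    """Fraction of the genome assigned to a reproducible functional class in
    at least one sample.

    ``classes`` maps each state label to one of promoter / enhancer /
    transcription / heterochromatin / none. States in ``exclusions`` and
    the sentinel never count. Unmapped labels raise.
    """
    if not consensus_set:
        raise ValueError("need at least one consensus segmentation")
    contributing: list[GenomicInterval] = []
    for seg in consensus_set:
        for iv, lab in zip(seg.intervals.intervals, seg.intervals.labels):
            if lab == SENTINEL:
                continue
            if lab not in classes:
                raise ValueError(f"state {lab!r} missing from class map")
            if lab in exclusions or classes[lab] == "none":
                continue
            contributing.append(iv)
    denom = denominator if denominator is not None else consensus_set[0].genome_length()
    if not contributing:
        return 0.0
    union = merge_intervals(IntervalSet(contributing))
    return union.total_bases() / denom


def variability_fraction(
    a: Segmentation, b: Segmentation, denominator: int | None = None
) -> float:
    """Fraction of bases whose state differs between two consensus calls.

    Sentinel-vs-state counts as differing; sentinel-vs-sentinel as equal.
    """
    differing = 0
    total = 0
    for _, lengths, _, la, lb in _align(a, b):
        differing += int(lengths[la != lb].sum())
        total += int(lengths.sum())
    denom = denominator if denominator is not None else total
    return differing / denom


def transition_graph_series(
    series: list[Segmentation], focus_state: str
) -> list[dict]:
    """Chromatin-state trajectories along a temporal series of consensus
    segmentations (one tissue).

    Bases ever labelled ``focus_state`` at any time point are tracked; for
    each adjacent pair of stages the bp moving state_i -> state_j is
    tallied, then all weights are normalized by the largest transition in
    the series (that edge gets weight exactly 1.0).

    Returns edge records ``{transition, state_from, state_to, bp, weight}``.
    """
    if len(series) < 2:
        raise ValueError("need at least two stages")
    # mask: bases ever in focus_state across the whole series
    label_stack: list[dict] = []
    edges: list[dict] = []
    for t in range(len(series) - 1):
        a, b = series[t], series[t + 1]
        tally: dict[tuple[str, str], int] = {}
        for chrom, lengths, bounds, la, lb in _align(a, b):
            ever = np.zeros(len(lengths), dtype=bool)
            mids = (bounds[:-1] + bounds[1:]) // 2
            for seg in series:
                tr = seg.tracks().get(chrom)
                if tr is None:
                    continue
                sb, sl = tr
                idx = np.searchsorted(sb, mids, side="right") - 1
                idx = np.clip(idx, 0, len(sl) - 1)
                ever |= np.asarray(sl[idx] == focus_state)
            for ln, x, y, keep in zip(lengths, la, lb, ever):
                if keep:
                    key = (str(x), str(y))
                    tally[key] = tally.get(key, 0) + int(ln)
        for (x, y), bp in tally.items():
            edges.append({"transition": t, "state_from": x, "state_to": y, "bp": bp})
    if not edges:
        logger.warning("focus state %s never observed", focus_state)
        return []
    max_bp = max(e["bp"] for e in edges)
    for e in edges:
        e["weight"] = e["bp"] / max_bp
    return edges


def transition_graph(
    stage_n: Segmentation, stage_n1: Segmentation, focus_state: str
) -> list[dict]:
    """Transition edges between two adjacent stages (see series variant)."""
    return transition_graph_series([stage_n, stage_n1], focus_state)


@dataclass
class StateClustering:
    labels: list[str]
    distances: np.ndarray  # condensed
    linkage: np.ndarray = field(repr=False)

    def to_newick(self) -> str:
        n = len(self.labels)
        Z = self.linkage

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            li, ri, h = int(Z[i - n, 0]), int(Z[i - n, 1]), Z[i - n, 2]

            def bl(child: int) -> float:
                ch = Z[child - n, 2] if child >= n else 0.0
                return max(h - ch, 0.0)

            return f"({node(li)}:{bl(li):g},{node(ri)}:{bl(ri):g})"

        return node(2 * n - 2) + ";"


def _intersection_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Overlap bp between two merged interval sets."""
    bb = b.by_chrom()
    total = 0
    for chrom, arr in a.by_chrom().items():
        other = bb.get(chrom)
        if other is None:
            continue
        i = j = 0
        while i < len(arr) and j < len(other):
            lo = max(arr[i, 0], other[j, 0])
            hi = min(arr[i, 1], other[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if arr[i, 1] <= other[j, 1]:
                i += 1
            else:
                j += 1
    return total


def cluster_samples_by_state(
    consensus_set: list[Segmentation], state: str = "5"
) -> StateClustering:
    """Hierarchical clustering of samples on per-base membership of one
    state: binary (Jaccard-complement) distances, Ward linkage."""
    if len(consensus_set) < 3:
        raise ValueError("need at least three samples")
    masks = [merge_intervals(seg.state_intervals({state}))
             if len(seg.state_intervals({state})) else IntervalSet()
             for seg in consensus_set]
    sizes = [m.total_bases() for m in masks]
    n = len(masks)
    condensed = []
    for i in range(n):
        if sizes[i] == 0:
            logger.warning("sample %s has zero state-%s bases",
                           consensus_set[i].sample, state)
        for j in range(i + 1, n):
            inter = _intersection_bases(masks[i], masks[j])
            union = sizes[i] + sizes[j] - inter
            condensed.append(1.0 - inter / union if union > 0 else 1.0)
    dist = np.asarray(condensed)
    Z = linkage(dist, method="ward")
    labels = [str(seg.sample) for seg in consensus_set]
    return StateClustering(labels=labels, distances=dist, linkage=Z)
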