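"""Region x sample signal matrices and the shared transforms.

A :class:`SignalGrid` couples an :class:`~chromatlas.core.intervals.IntervalSet`
of regions with a matrix of per-sample values and the tissue/stage/replicate
identity of every column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "SampleKey",
    "SignalGrid",
    "stage_sort_key",
    "quantile_normalize",
    "unit_vector_rows",
    "log2_with_zero_floor",
    "frot",
    "correlation_by_separation",
]

VALID_UNITS = {"RPKM", "log2RPKM", "FPKM", "log2FPKM", "raw_count"}


class SampleKey(NamedTuple):
    """Identity of a sample column: ``tissue:stage:replicate``."""

    tissue: str
    stage: str
    replicate: str

    def __str__(self) -> str:
        return f"{self.tissue}:{self.stage}:{self.replicate}"

    @classmethod
    def parse(cls, text: str) -> "SampleKey":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"sample key must be tissue:stage:rep, got {text!r}")
        return cls(*parts)


_STAGE_RE = re.compile(r"^([A-Za-z]+)([\d.]+)$")


def stage_sort_key(stage: str) -> tuple:
    """Sort key ordering embryonic stages before postnatal ones.

    ``E11.5 < E12.5 < ... < E16.5 < P0``; unparsable stages sort
    lexicographically after parsable ones.
    """
    m = _STAGE_RE.match(stage)
    if m:
        prefix, num = m.groups()
        rank = {"E": 0, "P": 1}.get(prefix.upper(), 2)
        return (0, rank, float(num), stage)
    return (1, 0, 0.0, stage)


@dataclass
class SignalGrid:
    regions: IntervalSet
    samples: list[SampleKey]
    values: np.ndarray
    units: str = "RPKM"
    stage_order: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.samples = [
            s if isinstance(s, SampleKey) else SampleKey.parse(str(s))
            for s in self.samples
        ]
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("signal matrix contains missing values")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    def stages(self, tissue: str | None = None) -> list[str]:
        """Stages present (optionally within one tissue), in temporal order."""
        vals = {s.stage for s in self.samples
                if tissue is None or s.tissue == tissue}
        if self.stage_order is not None:
            return [s for s in self.stage_order if s in vals]
        return sorted(vals, key=stage_sort_key)

    def column(self, key: SampleKey) -> np.ndarray:
        return self.values[:, self.samples.index(key)]

    def subset_samples(self, keep: Sequence[int]) -> "SignalGrid":
        return SignalGrid(
            self.regions,
            [self.samples[i] for i in keep],
            self.values[:, list(keep)],
            self.units,
            self.stage_order,
        )

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "SignalGrid":
        return SignalGrid(self.regions, list(self.samples), values,
                          units or self.units, self.stage_order)


def quantile_normalize(grid: SignalGrid) -> SignalGrid:
    """Quantile-normalize columns to a common distribution.

    Every column's sorted values become the across-column mean of sorted
    values; ties within a column receive the mean of their reference
    quantiles (average-rank tie handling).
    """
    x = grid.values
    if x.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return grid.copy_with(x.copy())
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for j in range(x.shape[1]):
        ranks = sps.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        # interpolate reference at (possibly fractional) average ranks
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return grid.copy_with(out)


def unit_vector_rows(grid: SignalGrid) -> SignalGrid:
    """Scale each row to unit Euclidean norm; all-zero rows are dropped."""
    norms = np.sqrt(np.sum(grid.values**2, axis=1))
    keep = norms > 0
    if not keep.all():
        logger.warning("unit_vector_rows: dropping %d all-zero rows",
                       int((~keep).sum()))
    regions = IntervalSet(
        [iv for iv, k in zip(grid.regions.intervals, keep) if k],
        ([l for l, k in zip(grid.regions.labels, keep) if k]
         if grid.regions.labels is not None else None),
        ([s for s, k in zip(grid.regions.scores, keep) if k]
         if grid.regions.scores is not None else None),
    )
    vals = grid.values[keep] / norms[keep, None]
    return SignalGrid(regions, list(grid.samples), vals, grid.units,
                      grid.stage_order)


def log2_with_zero_floor(grid: SignalGrid) -> SignalGrid:
    """log2-transform after replacing zeros by the smallest positive value."""
    x = grid.values
    if np.any(x < 0):
        raise ValueError("values must be non-negative")
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("all-zero matrix has no detectable floor")
    floor = positive.min()
    out = np.log2(np.where(x == 0, floor, x))
    units = {"RPKM": "log2RPKM", "FPKM": "log2FPKM"}.get(grid.units, grid.units)
    return grid.copy_with(out, units)


def frot(
    read_positions: Iterable[tuple[str, int]],
    tss: Iterable[tuple[str, int]],
    flank: int = 1000,
) -> float:
    """Fraction of reads overlapping a TSS: reads within ``flank`` bp of any
    TSS divided by total reads."""
    reads = [(str(c), int(p)) for c, p in read_positions]
    if not reads:
        raise ValueError("no reads supplied")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for c, p in tss:
        tss_by_chrom.setdefault(str(c), []).append(int(p))  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    hits = 0
    for c, p in reads:
        arr = tss_by_chrom.get(c)
        if arr is None:
            continue
        i = int(np.searchsorted(arr, p))
        near = []
        if i < len(arr):
            near.append(arr[i] - p)
        if i > 0:
            near.append(p - arr[i - 1])
        if near and min(near) <= flank:
            hits += 1
    return hits / len(reads)


def correlation_by_separation(
    grid: SignalGrid, method: str = "spearman"
) -> list[dict]:
    """Correlate every within-tissue sample pair, grouped by stage separation.

    Separation 0 covers replicate pairs from the same stage; separation k
    covers pairs of samples k developmental stages apart. Constant columns
    are skipped with a warning.

    Returns a list of records ``{tissue, sample_a, sample_b, separation,
    correlation}``.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = sps.spearmanr if method == "spearman" else sps.pearsonr
    records: list[dict] = []
    for tissue in grid.tissues():
        stage_list = grid.stages(tissue)
        stage_idx = {s: i for i, s in enumerate(stage_list)}
        cols = [(i, s) for i, s in enumerate(grid.samples) if s.tissue == tissue]
        if len(cols) < 2:
            continue
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                ia, ka = cols[a]
                ib, kb = cols[b]
                xa, xb = grid.values[:, ia], grid.values[:, ib]
                if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                    logger.warning("constant column, skipping pair %s/%s", ka, kb)
                    continue
                r = float(corr(xa, xb)[0])
                records.append({
                    "tissue": tissue,
                    "sample_a": str(ka),
                    "sample_b": str(kb),
                    "separation": abs(stage_idx[ka.stage] - stage_idx[kb.stage]),
                    "correlation": r,
                })
    return records
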