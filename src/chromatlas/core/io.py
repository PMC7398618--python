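"""Readers and writers for the plain-text formats used throughout.

All interval formats follow the BED convention (0-based half-open);
matrices are TSV with a header row. Sample columns are identified by
``tissue:stage:replicate`` keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneAnnotation
from .intervals import GenomicInterval, IntervalSet
from .matrix import SampleKey, SignalGrid

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_segmentation_bed",
    "write_segmentation_bed",
    "read_signal_grid",
    "write_signal_grid",
    "read_expression_grid",
    "write_expression_grid",
    "read_annotation",
    "write_annotation",
    "read_gene_labels",
    "read_motif_occurrences",
    "write_motif_occurrences",
]


def _validated_interval(chrom, start, end) -> GenomicInterval:
    return GenomicInterval(str(chrom), int(start), int(end))


def read_bed(path) -> IntervalSet:
    """Read BED3/BED4/BED6; column 4 becomes the label, column 5 the score."""
    ivs: list[GenomicInterval] = []
    labels: list[str] = []
    scores: list[float] = []
    ncols = 3
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            ncols = max(ncols, len(parts))
            ivs.append(_validated_interval(parts[0], parts[1], parts[2]))
            labels.append(parts[3] if len(parts) > 3 else ".")
            scores.append(float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0)
    return IntervalSet(
        ivs,
        labels if ncols > 3 else None,
        scores if ncols > 4 else None,
    )


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals.intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if intervals.labels is not None:
                fields.append(intervals.labels[i])
                if intervals.scores is not None:
                    fields.append(f"{intervals.scores[i]:g}")
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(path) -> IntervalSet:
    """Read ENCODE narrowPeak; label = name, score = signalValue (col 7)."""
    ivs, labels, scores = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"narrowPeak needs 10 columns, got {len(parts)}")
            ivs.append(_validated_interval(parts[0], parts[1], parts[2]))
            labels.append(parts[3])
            scores.append(float(parts[6]))
    return IntervalSet(ivs, labels, scores)


def read_segmentation_bed(path) -> IntervalSet:
    """Dense segmentation BED4 (column 4 = state label)."""
    out = read_bed(path)
    if out.labels is None:
        raise ValueError(f"{path}: segmentation BED requires a state column")
    return out


def write_segmentation_bed(intervals: IntervalSet, path) -> None:
    if intervals.labels is None:
        raise ValueError("segmentation intervals require state labels")
    write_bed(IntervalSet(intervals.intervals, intervals.labels), path)


def read_signal_grid(path, units: str = "RPKM") -> SignalGrid:
    """Region matrix TSV: header ``chrom start end <tissue:stage:rep>...``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    sample_cols = list(df.columns[3:])
    regions = IntervalSet(
        [_validated_interval(c, s, e)
         for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    )
    samples = [SampleKey.parse(c) for c in sample_cols]
    return SignalGrid(regions, samples, df[sample_cols].to_numpy(float), units)


def write_signal_grid(grid: SignalGrid, path) -> None:
    data = {
        "chrom": [iv.chrom for iv in grid.regions],
        "start": [iv.start for iv in grid.regions],
        "end": [iv.end for iv in grid.regions],
    }
    for j, key in enumerate(grid.samples):
        data[str(key)] = grid.values[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_expression_grid(
    path, annotation: Sequence[GeneAnnotation], units: str = "FPKM"
) -> SignalGrid:
    """Gene matrix TSV: header ``gene_id <tissue:stage:rep>...``.

    Genes are represented as intervals spanning their TSSs (on the
    annotated chromosome) and carried as region labels.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be gene_id")
    by_id = {g.gene_id: g for g in annotation}
    ivs, labels = [], []
    for gid in df["gene_id"]:
        g = by_id.get(str(gid))
        if g is None:
            raise KeyError(f"gene {gid} absent from annotation")
        lo, hi = min(g.tss_positions), max(g.tss_positions)
        ivs.append(GenomicInterval(g.chrom, lo, hi + 1))
        labels.append(g.gene_id)
    sample_cols = list(df.columns[1:])
    samples = [SampleKey.parse(c) for c in sample_cols]
    regions = IntervalSet(ivs, labels)
    return SignalGrid(regions, samples, df[sample_cols].to_numpy(float), units)


def write_expression_grid(grid: SignalGrid, path) -> None:
    if grid.regions.labels is None:
        raise ValueError("expression grid requires gene-id region labels")
    data = {"gene_id": list(grid.regions.labels)}
    for j, key in enumerate(grid.samples):
        data[str(key)] = grid.values[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> list[GeneAnnotation]:
    """Annotation TSV: gene_id, chrom, strand, tss_positions (comma-sep), biotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        genes.append(GeneAnnotation(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            tss_positions=[int(t) for t in str(row.tss_positions).split(",")],
            biotype=row.biotype,
        ))
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    rows = [{
        "gene_id": g.gene_id,
        "chrom": g.chrom,
        "strand": g.strand,
        "tss_positions": ",".join(str(t) for t in g.tss_positions),
        "biotype": g.biotype,
    } for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_labels(path) -> pd.DataFrame:
    """Gene label table TSV: gene_id plus 0/1 flag columns (is_TF, is_MDG, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: gene label table requires a gene_id column")
    for col in df.columns:
        if col != "gene_id":
            df[col] = df[col].astype(int).astype(bool)
    return df.set_index("gene_id")


def read_motif_occurrences(path) -> pd.DataFrame:
    """Long-format occurrence TSV (bin, motif, present) -> bin x motif 0/1 frame."""
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot_table(index="bin", columns="motif", values="present",
                          fill_value=0, aggfunc="max")
    return (wide > 0).astype(int)


def write_motif_occurrences(occurrences: pd.DataFrame, path) -> None:
    long = occurrences.stack().rename("present").reset_index()
    long.columns = ["bin", "motif", "present"]
    long.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
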