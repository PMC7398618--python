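"""Gene annotation records (TSS positions, strand, biotype)."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneAnnotation", "all_tss", "protein_coding"]


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss_positions: list[int]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.tss_positions = [int(t) for t in self.tss_positions]
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id} has no TSS")

    def nearest_tss(self, position: int) -> int:
        return min(self.tss_positions, key=lambda t: abs(t - position))


def all_tss(genes) -> list[tuple[str, int]]:
    """Flatten an annotation into ``(chrom, tss)`` anchor pairs."""
    return [(g.chrom, t) for g in genes for t in g.tss_positions]


def protein_coding(genes) -> list[GeneAnnotation]:
    return [g for g in genes if g.biotype == "protein_coding"]
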