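import numpy as np
import pytest

from chromatlas.core.intervals import GenomicInterval, IntervalSet


def per_base_mask(intervals, chrom: str, length: int) -> np.ndarray:
    """Brute-force per-base coverage of one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start:min(iv.end, length)] = True
    return mask


def random_interval_set(rng, n, chroms=("chr1", "chr2"), length=100_000,
                        max_len=500) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, length - max_len))
        ivs.append(GenomicInterval(chrom, start,
                                   start + int(rng.integers(1, max_len))))
    return IntervalSet(ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_atlas():
    """A small annotated genome shared across tests: 2 x 1 Mb chromosomes."""
    from chromatlas.synthetic import gen_annotation_and_tads

    genes, tads = gen_annotation_and_tads(
        n_chrom=2, chrom_len=1_000_000, n_genes=60, n_tads_per_chrom=4, seed=11)
    genome = {"chr1": 1_000_000, "chr2": 1_000_000}
    return genes, tads, genome
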