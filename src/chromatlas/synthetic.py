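"""Synthetic atlas generator with recorded ground truth.

Emits every input the pipeline consumes — gene annotation, TADs, replicated
chromatin-state segmentations, H3K27ac / ATAC / expression signal grids,
replicated peak sets, emission-model families, validation tables and motif
occurrence matrices — together with a :class:`SyntheticTruth` record of all
planted structure, so that every downstream stage can be tested as a
recovery problem without external data.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core.genes import GeneAnnotation
from .core.intervals import GenomicInterval, IntervalSet
from .core.matrix import SampleKey, SignalGrid
from .state_selection import EmissionModel, ModelFamily
from .states import Segmentation

__all__ = [
    "DEFAULT_TISSUES",
    "DEFAULT_STAGES",
    "SyntheticTruth",
    "gen_annotation_and_tads",
    "gen_segmentation_replicates",
    "gen_signal_grid",
    "gen_peak_sets",
    "gen_model_family",
    "gen_validation_and_motif_fixtures",
    "gen_interaction_fixture",
    "gen_eqtl_fixture",
]

DEFAULT_TISSUES = ["forebrain", "midbrain", "hindbrain", "heart", "limb", "liver"]
DEFAULT_STAGES = ["E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "P0"]


@dataclass
class SyntheticTruth:
    """Everything planted by the generators, for recovery tests."""

    seed: int
    true_links: list = field(default_factory=list)       # (enh chrom,start,end, gene_id, target_scc)
    dynamic_regions: list = field(default_factory=list)  # (chrom,start,end, tissue, transition_idx, direction)
    pcg_genes: list = field(default_factory=list)
    active_genes: list = field(default_factory=list)
    pcg_plan: dict = field(default_factory=dict)         # gene_id -> ["tissue:stage", ...]
    state_signatures: list = field(default_factory=list)
    validation_curve: dict = field(default_factory=dict)
    atac_lead: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_links"] = [tuple(x) for x in d.get("true_links", [])]
        d["dynamic_regions"] = [tuple(x) for x in d.get("dynamic_regions", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# annotation and TADs


def gen_annotation_and_tads(
    n_chrom: int = 2,
    chrom_len: int = 10_000_000,
    n_genes: int = 200,
    n_tads_per_chrom: int = 15,
    seed: int = 0,
    min_gene_spacing: int = 8_000,
    protein_coding_fraction: float = 0.85,
) -> tuple[list[GeneAnnotation], IntervalSet]:
    """Non-overlapping TADs tiling most of each chromosome, plus genes whose
    TSSs (1-3 each) fall inside a single TAD."""
    if n_tads_per_chrom < 1:
        raise ValueError("need at least one TAD per chromosome")
    rng = np.random.default_rng(seed)
    tad_ivs: list[GenomicInterval] = []
    tad_labels: list[str] = []
    block = chrom_len // n_tads_per_chrom
    gap = max(block // 100, 1)
    if 2 * gap >= block:
        raise ValueError("TAD parameters imply overlapping or empty TADs")
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        for t in range(n_tads_per_chrom):
            start = t * block + gap
            end = (t + 1) * block - gap
            tad_ivs.append(GenomicInterval(chrom, start, end))
            tad_labels.append(f"{chrom}_tad{t}")
    tads = IntervalSet(tad_ivs, tad_labels)

    usable = sum(len(iv) for iv in tad_ivs)
    if n_genes * min_gene_spacing > usable:
        raise ValueError("too many genes for the requested genome")

    # spread genes over TADs proportionally to TAD size, keep TSS clusters
    # separated so promoter windows never collide
    genes: list[GeneAnnotation] = []
    tad_order = rng.permutation(len(tad_ivs))
    per_tad = [[] for _ in tad_ivs]
    for g in range(n_genes):
        per_tad[tad_order[g % len(tad_ivs)]].append(g)
    gid = 0
    margin = 3_000
    for ti, members in enumerate(per_tad):
        if not members:
            continue
        tad = tad_ivs[ti]
        lo, hi = tad.start + margin, tad.end - margin
        span = hi - lo
        slots = len(members)
        if span < slots * min_gene_spacing:
            raise ValueError("TAD too small for its genes")
        offsets = np.sort(rng.choice(span // min_gene_spacing, size=slots,
                                     replace=False)) * min_gene_spacing
        jitter = rng.integers(0, min_gene_spacing // 4, size=slots)
        for pos0, j in zip(offsets, jitter):
            base = int(lo + pos0 + j)
            n_tss = int(rng.integers(1, 4))
            tss = sorted(int(base + k * 400) for k in range(n_tss))
            biotype = ("protein_coding"
                       if rng.random() < protein_coding_fraction else "lincRNA")
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(
                gene_id=f"gene{gid:05d}", chrom=tad.chrom, strand=strand,
                tss_positions=tss, biotype=biotype))
            gid += 1
    return genes, tads


# ---------------------------------------------------------------------------
# segmentations


def gen_segmentation_replicates(
    annotation: list[GeneAnnotation],
    genome: dict[str, int],
    tissues: list[str] | None = None,
    stages: list[str] | None = None,
    n_states: int = 15,
    bin_bp: int = 200,
    concordance: float = 0.97,
    pcg_genes: list[str] | None = None,
    active_genes: list[str] | None = None,
    pcg_stage_fraction: float = 0.5,
    window: int = 1_000,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], tuple[Segmentation, Segmentation]], SyntheticTruth]:
    """Replicate segmentation pairs over a fixed bin lattice.

    Replicate 2 copies replicate 1 bin-wise with probability ``concordance``
    and is resampled uniformly over the state alphabet otherwise. Every
    gene's TSS window is set to the permissive state (11) as a neutral
    baseline; planted active genes receive state 1 in all tissue-stages and
    planted PcG genes receive state 13 in a seeded subset of tissue-stages
    (at least one). Planted windows are kept concordant across replicates.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must lie in [0, 1]")
    tissues = tissues or DEFAULT_TISSUES
    stages = stages or DEFAULT_STAGES
    rng = np.random.default_rng(seed)
    pcg_genes = list(pcg_genes or [])
    active_genes = list(active_genes or [])
    alphabet = np.array([str(s) for s in range(1, n_states + 1)], dtype=object)

    samples = [(t, s) for t in tissues for s in stages]
    pcg_plan: dict[str, list[str]] = {}
    for g in pcg_genes:
        k = max(1, int(round(pcg_stage_fraction * len(samples))))
        chosen = rng.choice(len(samples), size=min(k, len(samples)), replace=False)
        pcg_plan[g] = sorted(f"{samples[i][0]}:{samples[i][1]}" for i in chosen)

    # per-chromosome bin lattices
    lattices: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        n_bins = math.ceil(length / bin_bp)
        bounds = np.minimum(np.arange(n_bins + 1) * bin_bp, length)
        lattices[chrom] = bounds

    def window_bins(chrom: str, tss: int) -> tuple[int, int]:
        bounds = lattices[chrom]
        lo = max(tss - window, 0)
        hi = min(tss + window, bounds[-1])
        i0 = int(np.searchsorted(bounds, lo, side="right") - 1)
        i1 = int(np.searchsorted(bounds, hi, side="left"))
        return i0, i1  # bins [i0, i1) intersect the window

    gene_bins: dict[str, list[tuple[str, int, int]]] = {}
    for g in annotation:
        if g.chrom not in lattices:
            continue
        gene_bins[g.gene_id] = [
            (g.chrom, *window_bins(g.chrom, t)) for t in g.tss_positions
        ]

    out: dict[tuple[str, str], tuple[Segmentation, Segmentation]] = {}
    for tissue, stage in samples:
        sample_tag = f"{tissue}:{stage}"
        rep_tracks = []
        protected: dict[str, np.ndarray] = {}
        labels1: dict[str, np.ndarray] = {}
        for chrom, bounds in lattices.items():
            n_bins = len(bounds) - 1
            lab = alphabet[rng.integers(0, n_states, n_bins)].copy()
            protected[chrom] = np.zeros(n_bins, dtype=bool)
            labels1[chrom] = lab
        # neutral baseline in every promoter window, then plantings
        for gid, spans in gene_bins.items():
            for chrom, i0, i1 in spans:
                labels1[chrom][i0:i1] = "11"
                protected[chrom][i0:i1] = True
        for gid in active_genes:
            for chrom, i0, i1 in gene_bins.get(gid, []):
                labels1[chrom][i0:i1] = "1"
        for gid, planted in pcg_plan.items():
            if sample_tag in planted:
                for chrom, i0, i1 in gene_bins.get(gid, []):
                    labels1[chrom][i0:i1] = "13"
        labels2 = {}
        for chrom, lab in labels1.items():
            n_bins = lab.size
            resample = (rng.random(n_bins) >= concordance) & ~protected[chrom]
            lab2 = lab.copy()
            lab2[resample] = alphabet[rng.integers(0, n_states, int(resample.sum()))]
            labels2[chrom] = lab2
        for rep, labels in (("1", labels1), ("2", labels2)):
            ivs, labs = [], []
            for chrom, lab in labels.items():
                bounds = lattices[chrom]
                change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [lab.size]])
                for s, e in zip(starts, ends):
                    ivs.append(GenomicInterval(chrom, int(bounds[s]), int(bounds[e])))
                    labs.append(str(lab[s]))
            rep_tracks.append(Segmentation(
                SampleKey(tissue, stage, rep), IntervalSet(ivs, labs)))
        out[(tissue, stage)] = (rep_tracks[0], rep_tracks[1])

    truth = SyntheticTruth(
        seed=seed, pcg_genes=sorted(pcg_genes), active_genes=sorted(active_genes),
        pcg_plan=pcg_plan)
    return out, truth


# ---------------------------------------------------------------------------
# signal grids


def _logistic_profiles(rng, n: int, n_tissues: int, n_stages: int,
                       base_sd: float = 1.0, amp_sd: float = 1.8,
                       wiggle_sd: float = 1.5) -> np.ndarray:
    """Latent log2 temporal profiles: per-tissue logistic ramps with random
    midpoints (enduring developmental shifts) plus independent
    tissue-stage-level variation, so distinct profiles decorrelate."""
    base = rng.normal(5.0, base_sd, size=n)[:, None, None]
    amp = rng.normal(0.0, amp_sd, size=(n, n_tissues, 1))
    mid = rng.uniform(0.5, n_stages - 1.5, size=(n, n_tissues, 1))
    s = np.arange(n_stages)[None, None, :]
    ramp = 1.0 / (1.0 + np.exp(-(s - mid) / 0.6))
    wiggle = rng.normal(0.0, wiggle_sd, size=(n, n_tissues, n_stages))
    return base + amp * ramp + wiggle  # (n, n_tissues, n_stages)


def _calibrate_link_noise(
    latents: list[np.ndarray], target_scc: float, rng: np.random.Generator
) -> float:
    """Noise scale (in units of each latent's sd) such that two independently
    noised copies of a latent profile reach the target mean Spearman
    correlation. Solved by bisection against fixed noise draws, since the
    logistic-ramp latents are far from Gaussian and closed-form
    Spearman/Pearson conversions undershoot."""
    from scipy.stats import spearmanr

    if target_scc >= 1.0 or not latents:
        return 0.0
    sample = latents[:: max(1, len(latents) // 50)]
    z = [(rng.standard_normal(l.size), rng.standard_normal(l.size))
         for l in sample]

    def mean_scc(scale: float) -> float:
        vals = []
        for lat, (z1, z2) in zip(sample, z):
            s = scale * lat.std()
            vals.append(spearmanr(lat + s * z1, lat + s * z2)[0])
        return float(np.nanmean(vals))

    lo, hi = 0.0, 4.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if mean_scc(mid) > target_scc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def gen_signal_grid(
    annotation: list[GeneAnnotation],
    tads: IntervalSet,
    n_enhancers: int = 400,
    n_links: int = 100,
    link_strength: float = 0.9,
    dynamics: dict | None = None,
    noise_sd: float = 0.35,
    tissues: list[str] | None = None,
    stages: list[str] | None = None,
    n_reps: int = 2,
    nb_dispersion: float = 0.1,
    atac_depth: float = 60.0,
    profile_amplitude_sd: float = 1.8,
    profile_wiggle_sd: float = 1.5,
    seed: int = 0,
) -> tuple[SignalGrid, SignalGrid, SignalGrid, SyntheticTruth]:
    """H3K27ac (log2RPKM), ATAC (raw counts) and expression (FPKM) grids with
    planted enhancer-gene links, temporal dynamics and an optional
    accessibility lead over H3K27ac.

    Linked enhancer/gene pairs share a latent temporal profile; Gaussian
    noise is calibrated so the expected Spearman correlation of a linked
    pair is approximately ``link_strength``. Non-linked rows are
    independent. ATAC counts are negative-binomial around means
    proportional to the (lead-shifted) H3K27ac latent; ``dynamics`` plants
    fold jumps of at least two at chosen transitions:
    ``{"n_dynamic": int, "fold": float, "lead": int}``.
    """
    if not 0 < link_strength <= 1:
        raise ValueError("link_strength must lie in (0, 1]")
    tissues = tissues or DEFAULT_TISSUES
    stages = stages or DEFAULT_STAGES
    dynamics = dynamics or {}
    n_dynamic = int(dynamics.get("n_dynamic", 0))
    dyn_fold = float(dynamics.get("fold", 4.0))
    lead = int(dynamics.get("lead", 0))
    if n_dynamic and dyn_fold < 2:
        raise ValueError("planted dynamic folds must be >= 2")
    rng = np.random.default_rng(seed)
    nT, nS = len(tissues), len(stages)

    # --- enhancer regions: inside TADs, away from TSSs -------------------
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in annotation:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss_positions)  # type: ignore
    tss_by_chrom = {c: np.sort(np.concatenate(v)) for c, v in tss_by_chrom.items()}

    width = 2_000
    enh_ivs: list[GenomicInterval] = []
    enh_tad: list[int] = []
    occupied: dict[str, list[int]] = {}
    tad_list = list(tads.intervals)
    attempts = 0
    while len(enh_ivs) < n_enhancers:
        attempts += 1
        if attempts > 200 * n_enhancers:
            raise ValueError("could not place the requested enhancers")
        ti = int(rng.integers(0, len(tad_list)))
        tad = tad_list[ti]
        mid = int(rng.integers(tad.start + width, tad.end - width))
        tss = tss_by_chrom.get(tad.chrom)
        if tss is not None:
            i = int(np.searchsorted(tss, mid))
            near = min([abs(int(tss[j]) - mid) for j in (i - 1, i)
                        if 0 <= j < len(tss)] or [np.inf])
            if near < 3_500:
                continue
        prev = occupied.setdefault(tad.chrom, [])
        if any(abs(mid - m) < width + 500 for m in prev):
            continue
        prev.append(mid)
        enh_ivs.append(GenomicInterval(tad.chrom, mid - width // 2, mid + width // 2))
        enh_tad.append(ti)
    enh_regions = IntervalSet(enh_ivs)

    # --- choose true links ----------------------------------------------
    coding = [g for g in annotation if g.biotype == "protein_coding"]
    genes_by_tad: dict[int, list[GeneAnnotation]] = {}
    for g in coding:
        for ti, tad in enumerate(tad_list):
            if tad.chrom == g.chrom and tad.start <= g.tss_positions[0] < tad.end:
                genes_by_tad.setdefault(ti, []).append(g)
                break
    linked_gene: dict[int, str] = {}
    used_genes: set[str] = set()
    order = rng.permutation(len(enh_ivs))
    for ei in order:
        if len(linked_gene) >= n_links:
            break
        pool = [g for g in genes_by_tad.get(enh_tad[ei], []) if g.gene_id not in used_genes]
        if not pool:
            continue
        g = pool[int(rng.integers(0, len(pool)))]
        linked_gene[int(ei)] = g.gene_id
        used_genes.add(g.gene_id)
    if len(linked_gene) < n_links:
        raise ValueError("not enough enhancer-gene pairs available inside TADs")

    # --- latent profiles --------------------------------------------------
    gene_ids = [g.gene_id for g in coding]
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    gene_latent = _logistic_profiles(rng, len(gene_ids), nT, nS,
                                     amp_sd=profile_amplitude_sd,
                                     wiggle_sd=profile_wiggle_sd)
    enh_latent = _logistic_profiles(rng, n_enhancers, nT, nS,
                                    amp_sd=profile_amplitude_sd,
                                    wiggle_sd=profile_wiggle_sd)
    for ei, gid in linked_gene.items():
        enh_latent[ei] = gene_latent[gene_idx[gid]]  # shared profile

    # --- planted ATAC dynamics -------------------------------------------
    atac_latent = enh_latent.copy()
    if lead:
        # accessibility anticipates the H3K27ac profile by `lead` stages
        atac_latent = np.concatenate(
            [enh_latent[:, :, lead:], np.repeat(enh_latent[:, :, -1:], lead, axis=2)],
            axis=2,
        )
    dynamic_records = []
    if n_dynamic:
        dyn_idx = rng.choice(n_enhancers, size=min(n_dynamic, n_enhancers),
                             replace=False)
        for ei in dyn_idx:
            t = int(rng.integers(0, nT))
            tr = int(rng.integers(max(0, lead), nS - 1 - max(0, lead)))
            direction = "gain" if rng.random() < 0.5 else "loss"
            step = np.log2(dyn_fold) * (1 if direction == "gain" else -1)
            atac_latent[ei, t, tr + 1:] += step
            # matching H3K27ac shift `lead` stages later (if it fits)
            htr = tr + lead
            if htr < nS - 1:
                enh_latent[ei, t, htr + 1:] += step
            dynamic_records.append((
                enh_ivs[ei].chrom, enh_ivs[ei].start, enh_ivs[ei].end,
                tissues[t], tr, direction))

    # --- noise calibration ------------------------------------------------
    samples = [SampleKey(t, s, str(r + 1))
               for t in tissues for s in stages for r in range(n_reps)]
    cols = [(ti, si) for ti in range(nT) for si in range(nS) for _ in range(n_reps)]
    col_t = np.array([c[0] for c in cols])
    col_s = np.array([c[1] for c in cols])

    def expand(latent: np.ndarray) -> np.ndarray:
        return latent[:, col_t, col_s]

    gene_vals = expand(gene_latent)
    enh_vals = expand(enh_latent)
    atac_vals = expand(atac_latent)

    gene_noise_sd = np.full(len(gene_ids), noise_sd)
    enh_noise_sd = np.full(n_enhancers, noise_sd)
    linked_lat = [gene_latent[gene_idx[gid]].reshape(-1)
                  for gid in linked_gene.values()]
    scale = _calibrate_link_noise(linked_lat, link_strength,
                                  np.random.default_rng(rng.integers(2**63)))
    for ei, gid in linked_gene.items():
        s = scale * float(gene_latent[gene_idx[gid]].std())
        gene_noise_sd[gene_idx[gid]] = s
        enh_noise_sd[ei] = s

    gene_log2 = gene_vals + rng.normal(size=gene_vals.shape) * gene_noise_sd[:, None]
    enh_log2 = enh_vals + rng.normal(size=enh_vals.shape) * enh_noise_sd[:, None]
    atac_mu = atac_depth * 2 ** (atac_vals - atac_vals.mean()
                                 + rng.normal(0, 0.05, size=atac_vals.shape))
    nb_n = 1.0 / nb_dispersion
    atac_counts = rng.negative_binomial(nb_n, nb_n / (nb_n + atac_mu)).astype(float)

    gene_regions = IntervalSet(
        [GenomicInterval(g.chrom, min(g.tss_positions), max(g.tss_positions) + 1)
         for g in coding],
        gene_ids,
    )
    h3k27ac = SignalGrid(enh_regions, samples, enh_log2, "log2RPKM",
                         stage_order=list(stages))
    atac = SignalGrid(enh_regions, samples, atac_counts, "raw_count",
                      stage_order=list(stages))
    expr = SignalGrid(gene_regions, samples, 2.0 ** gene_log2, "FPKM",
                      stage_order=list(stages))

    truth = SyntheticTruth(
        seed=seed,
        true_links=[(enh_ivs[ei].chrom, enh_ivs[ei].start, enh_ivs[ei].end,
                     gid, link_strength)
                    for ei, gid in sorted(linked_gene.items())],
        dynamic_regions=dynamic_records,
        atac_lead=lead,
    )
    return h3k27ac, atac, expr, truth


def gen_peak_sets(
    regions: IntervalSet,
    tissues: list[str] | None = None,
    stages: list[str] | None = None,
    membership_prob: float = 0.6,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], IntervalSet], pd.DataFrame]:
    """Replicated peak sets per tissue-stage drawn from a master region set.

    Every region is accessible in a random subset of tissue-stages (at
    least one). Returns the per-sample peak sets and the planted
    region x tissue-stage membership table.
    """
    tissues = tissues or DEFAULT_TISSUES
    stages = stages or DEFAULT_STAGES
    rng = np.random.default_rng(seed)
    samples = [(t, s) for t in tissues for s in stages]
    n = len(regions)
    member = rng.random((n, len(samples))) < membership_prob
    for i in range(n):
        if not member[i].any():
            member[i, int(rng.integers(0, len(samples)))] = True
    peaks = {}
    for j, (t, s) in enumerate(samples):
        keep = np.flatnonzero(member[:, j])
        peaks[(t, s)] = IntervalSet(
            [regions.intervals[i] for i in keep],
            [f"{t}:{s}:peak{i}" for i in keep],
        )
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions.intervals]
    table = pd.DataFrame(member, index=index,
                         columns=[f"{t}:{s}" for t, s in samples])
    return peaks, table


# ---------------------------------------------------------------------------
# emission-model families


def _separated_signatures(rng, n_signatures: int, n_marks: int) -> np.ndarray:
    """Binary-ish emission signatures with large guaranteed pairwise
    separation, taken from (seeded permutations of) a Hadamard design.

    Rows of an m x m Hadamard matrix differ pairwise in exactly m/2
    positions, so mapping -1/+1 to 0.1/0.9 yields signatures whose squared
    distance (0.64 * m/2) comfortably exceeds their spread around the grand
    mean — the regime in which cluster-separation model selection is
    well-posed.
    """
    from scipy.linalg import hadamard

    m = 1
    while m < max(n_marks, n_signatures + 1):
        m *= 2
    H = hadamard(m)
    rows = rng.choice(np.arange(1, m), size=n_signatures, replace=False)
    cols = rng.permutation(m)[:n_marks]
    sigs = np.where(H[np.ix_(rows, cols)] > 0, 0.9, 0.1)
    if n_marks < m:
        # column subsetting weakens the distance guarantee: verify
        d2 = ((sigs[:, None, :] - sigs[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 0.64 * n_marks / 4:
            raise RuntimeError(
                "signatures insufficiently separated; use n_marks equal to a "
                "power of two (>= n_signatures + 1)")
    return sigs


def gen_model_family(
    n_signatures: int = 15,
    n_marks: int = 16,
    k_min: int = 2,
    k_max: int = 24,
    noise_sd: float = 0.02,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[ModelFamily, np.ndarray]:
    """A family of emission models derived from planted state signatures.

    The model at k <= n_signatures carries the first k signatures; richer
    models repeat randomly chosen signatures. Independent Gaussian noise
    (clipped to [0, 1]) distinguishes replicates and models.
    """
    rng = np.random.default_rng(seed)
    sigs = _separated_signatures(rng, n_signatures, n_marks)
    marks = [f"mark{m}" for m in range(n_marks)]
    models: dict[str, dict[int, EmissionModel]] = {}
    for rep in range(1, n_replicates + 1):
        rep_models = {}
        for k in range(k_min, k_max + 1):
            if k <= n_signatures:
                rows = sigs[:k]
            else:
                extra = rng.integers(0, n_signatures, size=k - n_signatures)
                rows = np.vstack([sigs, sigs[extra]])
            noisy = np.clip(rows + rng.normal(0, noise_sd, rows.shape), 0, 1)
            rep_models[k] = EmissionModel(marks, noisy)
        models[f"rep{rep}"] = rep_models
    return ModelFamily(models), sigs


# ---------------------------------------------------------------------------
# validation and motif fixtures


def _curve_function(curve_params: dict):
    kind = curve_params.get("kind", "logistic")
    if kind == "logistic":
        top = float(curve_params.get("top", 0.6))
        base = float(curve_params.get("base", 0.05))
        mid = float(curve_params.get("mid", 200.0))
        scale = float(curve_params.get("scale", 60.0))
        if top < base:
            raise ValueError("curve must be monotone non-increasing")
        return lambda r: base + (top - base) / (1.0 + np.exp((np.asarray(r, float) - mid) / scale))
    if kind == "step":
        levels = sorted(curve_params["levels"])  # [(max_rank, p), ...]
        probs = [p for _, p in levels]
        if any(b > a for a, b in zip(probs, probs[1:])):
            # sorted by rank; probabilities must not increase
            raise ValueError("curve must be monotone non-increasing")

        def step(r):
            r = np.asarray(r, dtype=float)
            out = np.full(r.shape, levels[-1][1])
            for max_rank, p in reversed(levels):
                out = np.where(r <= max_rank, p, out)
            return out

        return step
    raise ValueError(f"unknown curve kind {kind!r}")


def gen_validation_and_motif_fixtures(
    n_elements: int = 400,
    curve_params: dict | None = None,
    n_motifs: int = 20,
    enrichment_spec: dict | None = None,
    rank_noise: float = 20.0,
    tissue: str = "forebrain",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Validation records with rank-dependent positive labels, plus a
    bin x motif occurrence matrix with planted per-cluster enrichments.

    ``curve_params`` describes a monotone non-increasing rank -> probability
    function; element i (true rank i) is positive with probability
    curve(i). Two replicate rank lists perturb the true order with
    Gaussian noise. ``enrichment_spec``:
    ``{"clusters": {name: n_bins}, "background_bins": int,
    "planted": {(cluster, motif_index): freq}, "background_freq": float}``.
    """
    rng = np.random.default_rng(seed)
    curve_params = curve_params or {"kind": "logistic"}
    curve = _curve_function(curve_params)
    ranks = np.arange(1, n_elements + 1)
    probs = curve(ranks)
    if np.any(np.diff(probs) > 1e-12):
        raise ValueError("curve must be monotone non-increasing")
    labels = rng.random(n_elements) < probs

    def observed_ranks() -> np.ndarray:
        score = -ranks + rng.normal(0, rank_noise, n_elements)
        order = np.argsort(-score, kind="stable")
        out = np.empty(n_elements, dtype=int)
        out[order] = np.arange(1, n_elements + 1)
        return out

    validation = pd.DataFrame({
        "element": [f"elem{i:04d}" for i in range(n_elements)],
        "chrom": "chr1",
        "start": 10_000 * np.arange(n_elements) + 1_000,
        "end": 10_000 * np.arange(n_elements) + 2_500,
        "rank_rep1": observed_ranks(),
        "rank_rep2": observed_ranks(),
        "tissue": tissue,
        "positive": labels.astype(int),
    })

    spec = enrichment_spec or {
        "clusters": {"c1": 100, "c2": 100},
        "background_bins": 400,
        "planted": {("c1", 0): 0.8},
        "background_freq": 0.1,
    }
    bg_freq = float(spec.get("background_freq", 0.1))
    rows = []
    bin_cluster = {}
    b = 0
    for cname, count in spec["clusters"].items():
        for _ in range(count):
            bin_cluster[f"bin{b:05d}"] = cname
            b += 1
    for _ in range(int(spec.get("background_bins", 0))):
        bin_cluster[f"bin{b:05d}"] = "background"
        b += 1
    planted = {(c, int(m)): float(f) for (c, m), f in spec.get("planted", {}).items()}
    motif_names = [f"motif{m:03d}" for m in range(n_motifs)]
    for bin_name, cname in bin_cluster.items():
        freqs = np.full(n_motifs, bg_freq)
        for (c, m), f in planted.items():
            if c == cname:
                freqs[m] = f
        rows.append(rng.random(n_motifs) < freqs)
    occurrences = pd.DataFrame(
        np.array(rows, dtype=int), index=list(bin_cluster), columns=motif_names)
    occurrences.index.name = "bin"

    truth = SyntheticTruth(
        seed=seed,
        validation_curve={"params": {k: (v if not isinstance(v, dict) else v)
                                     for k, v in curve_params.items()},
                          "clusters": {b: c for b, c in bin_cluster.items()}},
    )
    return validation, occurrences, truth


# ---------------------------------------------------------------------------
# evaluation fixtures derived from truth


def gen_interaction_fixture(
    truth: SyntheticTruth,
    annotation: list[GeneAnnotation],
    n_decoys: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Region-gene interaction pairs: anchors at true-link enhancers paired
    with their planted genes, plus optional random decoy pairs."""
    rng = np.random.default_rng(seed)
    rows = [{"chrom": c, "start": s, "end": e, "gene_id": g}
            for c, s, e, g, _ in truth.true_links]
    gene_ids = [g.gene_id for g in annotation]
    for _ in range(n_decoys):
        c, s, e, g, _ = truth.true_links[int(rng.integers(0, len(truth.true_links)))]
        rows.append({"chrom": c, "start": s, "end": e,
                     "gene_id": gene_ids[int(rng.integers(0, len(gene_ids)))]})
    return pd.DataFrame(rows)


def gen_eqtl_fixture(
    truth: SyntheticTruth,
    annotation: list[GeneAnnotation],
    inside_fraction: float = 1.0,
    n_pairs: int | None = None,
    genome: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """eQTL-style (variant position, gene) associations: a fraction planted
    inside true-link enhancers (associated with the linked gene), the rest
    uniform over the genome with random genes."""
    rng = np.random.default_rng(seed)
    n_pairs = n_pairs or len(truth.true_links)
    gene_ids = [g.gene_id for g in annotation]
    rows = []
    for _ in range(n_pairs):
        if rng.random() < inside_fraction and truth.true_links:
            c, s, e, g, _ = truth.true_links[int(rng.integers(0, len(truth.true_links)))]
            rows.append({"chrom": c, "pos": int(rng.integers(s, e)), "gene_id": g})
        else:
            if genome is None:
                raise ValueError("genome required for background eQTLs")
            chrom = list(genome)[int(rng.integers(0, len(genome)))]
            rows.append({"chrom": chrom,
                         "pos": int(rng.integers(0, genome[chrom])),
                         "gene_id": gene_ids[int(rng.integers(0, len(gene_ids)))]})
    return pd.DataFrame(rows)
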