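"""Planted-truth synthetic data: repeat genomes, plaid Hi-C, nuclear images.

These generators produce inputs with the statistical structure the analysis
assumes, so every estimator in the package can be checked against the
parameter that generated its input:

* :func:`simulate_repeat_genome` — chromosomes tiled by alternating blocks of
  L1-dominated and B1-dominated sequence (log-normal block lengths, median
  1.5 Mb), with individual elements (L1 ~6-7 kb, B1 ~150-300 bp) placed
  uniformly without same-family overlap to target coverages.
* :func:`simulate_contact_matrix` — Poisson counts around a power-law
  distance decay modulated by a homotypic/heterotypic affinity checkerboard;
  a mitotic mode suppresses the checkerboard and boosts near-diagonal counts.
* :func:`simulate_nucleus_images` — segregated nuclei (L1 at the nuclear rim
  and a nucleolar shell, B1 as interior puncta filling the L1-free interior)
  versus mixed nuclei (both channels sampling one smooth field), with
  Poisson-Gaussian noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .genome import GenomeTable
from .hic import ContactMatrix
from .imaging import NucleusImage
from .compartments import COMPARTMENT_COLUMNS, compartments_to_bins
from .repeats import ANNOTATION_COLUMNS

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticHiCSpec",
    "SyntheticImageSpec",
    "simulate_repeat_genome",
    "simulate_contact_matrix",
    "simulate_contact_matrices",
    "simulate_nucleus_images",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Alternating L1-block / B1-block genome with stated element coverages."""

    n_chroms: int = 5
    chrom_length: int = 40_000_000
    block_length_median: float = 1_500_000.0
    block_length_sigma: float = 0.5
    l1_cov_in_l1_blocks: float = 0.30
    l1_cov_in_b1_blocks: float = 0.05
    b1_cov_in_b1_blocks: float = 0.08
    b1_cov_in_l1_blocks: float = 0.01
    l1_length_range: tuple[int, int] = (6_000, 7_000)
    b1_length_range: tuple[int, int] = (150, 300)

    def __post_init__(self) -> None:
        covs = (
            self.l1_cov_in_l1_blocks,
            self.l1_cov_in_b1_blocks,
            self.b1_cov_in_b1_blocks,
            self.b1_cov_in_l1_blocks,
        )
        if not all(0 <= c < 1 for c in covs):
            raise InputError("coverages must lie in [0, 1)")
        if self.l1_cov_in_l1_blocks <= self.l1_cov_in_b1_blocks:
            raise InputError("L1 coverage must be higher in L1 blocks")
        if self.b1_cov_in_b1_blocks <= self.b1_cov_in_l1_blocks:
            raise InputError("B1 coverage must be higher in B1 blocks")


def _draw_elements(rng, target_bases: float, length_range: tuple[int, int]) -> np.ndarray:
    """Element lengths accumulating to the coverage target (last one may overshoot)."""
    if target_bases <= 0:
        return np.empty(0, dtype=np.int64)
    lo, hi = length_range
    mean_len = (lo + hi) / 2
    lengths = np.empty(0, dtype=np.int64)
    while lengths.sum() < target_bases:
        n_more = int((target_bases - lengths.sum()) / mean_len) + 4
        lengths = np.concatenate([lengths, rng.integers(lo, hi + 1, n_more)])
    cum = np.cumsum(lengths)
    n = int(np.searchsorted(cum, target_bases)) + 1
    return lengths[:n]


def _place_nonoverlapping(rng, block_start: int, block_len: int, lengths: np.ndarray) -> np.ndarray:
    """Uniform non-overlapping starts via the gap-allocation construction."""
    total = int(lengths.sum())
    if total > block_len:
        raise InputError("packing failure: requested coverage does not fit the block")
    if len(lengths) == 0:
        return np.empty(0, dtype=np.int64)
    lengths = rng.permutation(lengths)
    offsets = np.sort(rng.integers(0, block_len - total + 1, size=len(lengths)))
    starts = block_start + offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return np.stack([starts, starts + lengths], axis=1)


def simulate_repeat_genome(
    spec: SyntheticGenomeSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GenomeTable]:
    """Generate (annotation, truth compartments, genome table).

    Each chromosome is tiled by alternating-label blocks with log-normal
    lengths; within each block both element families are placed uniformly at
    random without same-family overlap until their coverage targets are met.
    """
    rng = np.random.default_rng(seed)
    names = tuple(f"chr{i + 1}" for i in range(spec.n_chroms))
    genome = GenomeTable(names, (spec.chrom_length,) * spec.n_chroms)
    ann_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    mu = np.log(spec.block_length_median)
    for chrom in names:
        L = spec.chrom_length
        pos = 0
        label = "B1-rich" if rng.random() < 0.5 else "L1-rich"
        while pos < L:
            block_len = int(rng.lognormal(mu, spec.block_length_sigma))
            block_len = max(block_len, 50_000)
            end = min(pos + block_len, L)
            block_len = end - pos
            if label == "L1-rich":
                l1_cov, b1_cov = spec.l1_cov_in_l1_blocks, spec.b1_cov_in_l1_blocks
            else:
                l1_cov, b1_cov = spec.l1_cov_in_b1_blocks, spec.b1_cov_in_b1_blocks
            for family, cov, lrange in (
                ("L1", l1_cov, spec.l1_length_range),
                ("B1", b1_cov, spec.b1_length_range),
            ):
                lengths = _draw_elements(rng, cov * block_len, lrange)
                placed = _place_nonoverlapping(rng, pos, block_len, lengths)
                for s, e in placed:
                    ann_rows.append((chrom, int(s), int(e), family, "+" if rng.random() < 0.5 else "-"))
            truth_rows.append((chrom, pos, end, label, np.nan))
            pos = end
            label = "L1-rich" if label == "B1-rich" else "B1-rich"
    annotation = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    annotation = annotation.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=COMPARTMENT_COLUMNS)
    return annotation, truth, genome


@dataclass(frozen=True)
class SyntheticHiCSpec:
    """Plaid contact-matrix model: power-law decay times label affinity."""

    bin_size: int = 100_000
    alpha: float = 1.0
    a_hom: float = 1.5
    a_het: float = 0.67
    depth: float = 1e7
    mitotic_mode: bool = False
    mitotic_boost: float = 5.0
    mitotic_range: int = 1_000_000

    def __post_init__(self) -> None:
        if not (self.a_hom > self.a_het > 0):
            raise InputError("need a_hom > a_het > 0")
        if self.depth <= 0:
            raise InputError("depth must be positive")


def expected_contact_matrix(
    truth: pd.DataFrame, genome: GenomeTable, chrom: str, spec: SyntheticHiCSpec
) -> np.ndarray:
    """Noise-free expectation: depth * (bp separation)^-alpha * affinity."""
    n = genome.n_bins(chrom, spec.bin_size)
    labels = compartments_to_bins(truth, chrom, n, spec.bin_size)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    dist_bp = np.maximum(sep, 1) * spec.bin_size
    base = spec.depth * dist_bp.astype(float) ** (-spec.alpha)
    if spec.mitotic_mode:
        aff = np.ones((n, n))
        aff[dist_bp < spec.mitotic_range] *= spec.mitotic_boost
    else:
        labeled = labels != ""
        same = (labels[:, None] == labels[None, :]) & labeled[:, None] & labeled[None, :]
        diff = (labels[:, None] != labels[None, :]) & labeled[:, None] & labeled[None, :]
        aff = np.ones((n, n))
        aff[same] = spec.a_hom
        aff[diff] = spec.a_het
    return base * aff


def simulate_contact_matrix(
    truth: pd.DataFrame,
    genome: GenomeTable,
    chrom: str,
    spec: SyntheticHiCSpec,
    seed: int,
    *,
    poisson: bool = True,
) -> ContactMatrix:
    """Poisson-sample the plaid expectation into a symmetric raw matrix."""
    if chrom not in genome:
        raise InputError(f"unknown chromosome {chrom!r}")
    mean = expected_contact_matrix(truth, genome, chrom, spec)
    if not poisson:
        return ContactMatrix(chrom, spec.bin_size, mean, "raw")
    rng = np.random.default_rng(seed)
    n = mean.shape[0]
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(mean[iu])
    counts = counts + np.triu(counts, k=1).T
    return ContactMatrix(chrom, spec.bin_size, counts, "raw")


def simulate_contact_matrices(
    truth: pd.DataFrame, genome: GenomeTable, spec: SyntheticHiCSpec, seed: int, **kw
) -> dict[str, ContactMatrix]:
    """One matrix per chromosome, seeds spawned deterministically per chromosome."""
    seeds = np.random.SeedSequence(seed).spawn(len(genome.names))
    return {
        chrom: simulate_contact_matrix(
            truth, genome, chrom, spec, seeds[i].generate_state(1)[0] % (2**31), **kw
        )
        for i, chrom in enumerate(genome.names)
    }


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Two-channel nucleus image: segregated or mixed localization."""

    size: int = 256
    nucleus_radius: float = 100.0
    mode: str = "segregated"  # segregated | mixed
    snr: float = 10.0
    n_puncta: int = 150
    puncta_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("segregated", "mixed"):
            raise InputError("mode must be 'segregated' or 'mixed'")
        if self.nucleus_radius * 2 >= self.size:
            raise InputError("nucleus does not fit the image")
        if self.snr <= 0:
            raise InputError("SNR must be positive")


def _noisy(rng, base: np.ndarray, snr: float) -> np.ndarray:
    """Poisson-Gaussian detection noise; SNR sets the peak photon count."""
    photons = base * snr**2
    img = rng.poisson(photons).astype(float) + rng.normal(0.0, 1.0, base.shape)
    return np.clip(img, 0, None)


def simulate_nucleus_images(spec: SyntheticImageSpec, seed: int) -> NucleusImage:
    rng = np.random.default_rng(seed)
    c = spec.size / 2
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size]
    r = np.hypot(yy - c, xx - c)
    R = spec.nucleus_radius
    disk = r <= R
    dna = ndimage.gaussian_filter(disk.astype(float), 2.0)

    if spec.mode == "mixed":
        field = ndimage.gaussian_filter(rng.normal(size=(spec.size, spec.size)), 4.0)
        field = (field - field.min()) / np.ptp(field)
        field = (0.2 + 0.8 * field) * disk
        l1_base = field
        b1_base = field
    else:
        rim = np.exp(-(((r - 0.93 * R) / (0.05 * R)) ** 2))
        nucleolar_shell = 0.8 * np.exp(-(((r - 0.35 * R) / (0.05 * R)) ** 2))
        l1_base = (rim + nucleolar_shell) * disk
        l1_norm = l1_base / l1_base.max()
        # B1 fills the L1-free interior, plus brighter puncta avoiding the L1 field
        interior = (r < 0.88 * R).astype(float)
        diffuse = 0.45 * interior * (1.0 - l1_norm)
        puncta = np.zeros_like(l1_base)
        placed = 0
        while placed < spec.n_puncta:
            py, px = rng.integers(0, spec.size, 2)
            if r[py, px] < 0.85 * R and l1_norm[py, px] < 0.2:
                puncta[py, px] += 1.0
                placed += 1
        puncta = ndimage.gaussian_filter(puncta, spec.puncta_sigma)
        if puncta.max() > 0:
            puncta = puncta / puncta.max()
        b1_base = (diffuse + 0.8 * puncta) * disk
        b1_base = b1_base / b1_base.max()
        l1_base = l1_norm

    return NucleusImage(
        channel_l1=_noisy(rng, l1_base, spec.snr),
        channel_b1=_noisy(rng, b1_base, spec.snr),
        channel_dna=_noisy(rng, dna, spec.snr),
        mask=disk,
    )
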