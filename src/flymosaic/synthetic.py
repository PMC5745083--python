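"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (config, seed) and return ground truth
alongside the data: hexagonal Gaussian-spot retina mosaics with a
multiplicative illumination field, inbred-line genotype cohorts with a
planted causal indel, Boltzmann-resampled SELEX read cycles, copying-model
haplotype panels with a tunable partial sweep, and binomial two-choice
T-maze trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import TrialCounts
from .gwas import (DeficiencyInterval, GenotypeMatrix, HET, HOM_ALT, HOM_REF,
                   MISSING, Variant)
from .kmers import PWM, reverse_complement
from .popgen import HaplotypeMatrix
from .segmentation import RetinaImage

__all__ = [
    "CrossTruth",
    "MosaicGroundTruth",
    "SimulationConfig",
    "generate_cross_cohort",
    "generate_haplotypes",
    "generate_retina_image",
    "generate_selex_reads",
    "generate_tmaze_trials",
]


@dataclass
class MosaicGroundTruth:
    """True spot centers, ON/OFF identities, and border flags for one mosaic."""

    centers: np.ndarray      # (n, 2) pixel (row, col)
    identities: np.ndarray   # (n,) bool, True = ON (rh4)
    is_border: np.ndarray    # (n,) bool, outermost lattice ring

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.identities = np.asarray(self.identities, dtype=bool)
        self.is_border = np.asarray(self.is_border, dtype=bool)
        n = len(self.centers)
        if len(self.identities) != n or len(self.is_border) != n:
            raise ValueError("ground-truth arrays must have equal length")

    @property
    def n_spots(self) -> int:
        return len(self.centers)

    @property
    def on_fraction_true(self) -> float:
        return float(self.identities.mean())

    @property
    def pct_on_true(self) -> float:
        return 100.0 * self.on_fraction_true


@dataclass
class SimulationConfig:
    """Retina-mosaic generator parameters."""

    seed: int = 0
    n_rows: int = 14
    n_cols: int = 15
    on_fraction: float = 0.65
    spot_sigma: float = 2.2
    spot_amplitude: float = 1.0
    spacing: float = 12.0
    background: float = 0.02
    noise_sd: float = 0.02
    illum_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError("on_fraction must lie in [0, 1]")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _hex_lattice(config: SimulationConfig) -> Tuple[np.ndarray, np.ndarray,
                                                    Tuple[int, int]]:
    """Hexagonally packed centers, border flags, and the image shape."""
    s = config.spacing
    margin = 3.0 * config.spot_sigma + s / 2.0
    row_step = s * math.sqrt(3.0) / 2.0
    centers, border = [], []
    for i in range(config.n_rows):
        for j in range(config.n_cols):
            r = margin + i * row_step
            c = margin + j * s + (i % 2) * s / 2.0
            centers.append((r, c))
            border.append(i in (0, config.n_rows - 1)
                          or j in (0, config.n_cols - 1))
    height = int(math.ceil(2 * margin + (config.n_rows - 1) * row_step))
    width = int(math.ceil(2 * margin + (config.n_cols - 1) * s + s / 2.0))
    return np.array(centers), np.array(border), (height, width)


def _render_spots(shape: Tuple[int, int], centers: np.ndarray,
                  amplitude: float, sigma: float) -> np.ndarray:
    canvas = np.zeros(shape)
    half = int(math.ceil(4 * sigma))
    for cr, cc in centers:
        r0, r1 = max(int(cr) - half, 0), min(int(cr) + half + 1, shape[0])
        c0, c1 = max(int(cc) - half, 0), min(int(cc) + half + 1, shape[1])
        rr, cc_grid = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - cr) ** 2 + (cc_grid - cc) ** 2) / (2 * sigma ** 2))
    return canvas


def _illumination_field(shape: Tuple[int, int], amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + amplitude * quadratic in (u, v)."""
    if amplitude == 0:
        return np.ones(shape)
    u = np.linspace(-1.0, 1.0, shape[0])[:, None]
    v = np.linspace(-1.0, 1.0, shape[1])[None, :]
    coef = rng.uniform(-1.0, 1.0, size=5)
    f = (coef[0] * u + coef[1] * v + coef[2] * u * v
         + coef[3] * u ** 2 + coef[4] * v ** 2)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * 0.5 * (f + 1.0)  # field in [1, 1 + amplitude]


def generate_retina_image(config: SimulationConfig
                          ) -> Tuple[RetinaImage, MosaicGroundTruth]:
    """Two-channel mosaic image with known spot identities.

    Spots sit on a hexagonal lattice; each is rendered as an isotropic
    Gaussian into exactly one channel per its Bernoulli(on_fraction)
    identity. Both channels are multiplied by a smooth illumination field
    and perturbed by additive Gaussian noise (clipped at zero).
    """
    rng = np.random.default_rng(config.seed)
    centers, border, shape = _hex_lattice(config)
    identities = rng.random(len(centers)) < config.on_fraction
    rh4 = _render_spots(shape, centers[identities], config.spot_amplitude,
                        config.spot_sigma) + config.background
    rh3 = _render_spots(shape, centers[~identities], config.spot_amplitude,
                        config.spot_sigma) + config.background
    illum = _illumination_field(shape, config.illum_amplitude, rng)
    rh3 *= illum
    rh4 *= illum
    if config.noise_sd > 0:
        rh3 = rh3 + rng.normal(0.0, config.noise_sd, shape)
        rh4 = rh4 + rng.normal(0.0, config.noise_sd, shape)
    rh3 = np.clip(rh3, 0.0, None)
    rh4 = np.clip(rh4, 0.0, None)
    truth = MosaicGroundTruth(centers, identities, border)
    return RetinaImage(rh3, rh4), truth


@dataclass(frozen=True)
class CrossTruth:
    """Generative parameters of a synthetic cross cohort."""

    causal_index: int
    effect_size: float
    baseline: float
    noise_sd: float


def generate_cross_cohort(n_lines: int, n_variants: int, causal_index: int,
                          effect_size: float,
                          deficiency: DeficiencyInterval, seed: int,
                          het_rate: float = 0.02,
                          missing_rate: float = 0.01,
                          baseline: float = 0.49,
                          noise_sd: float = 0.25
                          ) -> Tuple[GenotypeMatrix, pd.Series, CrossTruth]:
    """Inbred-line genotypes plus a %ON phenotype driven by one causal indel.

    Lines are homozygous apart from *het_rate* residual heterozygous and
    *missing_rate* missing calls. The causal variant (a 1-bp insertion) sits
    inside the deficiency interval at index *causal_index*; the phenotype is
    100 * logistic(baseline + effect_size * x + noise) where x is half the
    causal alt dosage of the inbred line (0, 0.5 or 1).
    """
    if not 0 <= causal_index < n_variants:
        raise ValueError("causal_index out of variant range")
    rng = np.random.default_rng(seed)

    # evenly spaced positions with the causal index at the interval center
    center = (deficiency.start + deficiency.end) // 2
    span = deficiency.end - deficiency.start + 1
    step = max(span // max(n_variants, 10), 50)
    first = center - causal_index * step
    if first < 1:
        step = max((center - 1) // max(causal_index, 1), 1)
        first = center - causal_index * step
    positions = first + step * np.arange(n_variants)
    if not deficiency.contains(deficiency.chrom, int(positions[causal_index])):
        raise ValueError("cannot place the causal variant inside the "
                         "deficiency interval with this geometry")
    variants = []
    for i, pos in enumerate(positions):
        if i == causal_index:
            variants.append(Variant(deficiency.chrom, int(pos), "A", "AC",
                                    vid="causal"))
        else:
            variants.append(Variant(deficiency.chrom, int(pos), "A", "G",
                                    vid=f"v{i}"))

    freqs = rng.uniform(0.15, 0.85, n_variants)
    calls = np.where(rng.random((n_lines, n_variants)) < freqs[None, :],
                     HOM_ALT, HOM_REF).astype(np.int8)
    noise_mask = rng.random((n_lines, n_variants))
    calls[noise_mask < het_rate] = HET
    calls[(noise_mask >= het_rate)
          & (noise_mask < het_rate + missing_rate)] = MISSING

    lines = [f"line_{i:04d}" for i in range(n_lines)]
    genotypes = GenotypeMatrix(variants, lines, calls)

    causal_calls = calls[:, causal_index].astype(float)
    x = np.where(causal_calls == MISSING, freqs[causal_index],
                 causal_calls / 2.0)
    logit = baseline + effect_size * x + rng.normal(0.0, noise_sd, n_lines)
    pct_on = 100.0 / (1.0 + np.exp(-logit))
    phenotype = pd.Series(pct_on, index=lines, name="pct_on")
    truth = CrossTruth(causal_index, effect_size, baseline, noise_sd)
    return genotypes, phenotype, truth


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_INT[_b] = _i


def _random_reads(rng: np.random.Generator, n_reads: int,
                  read_length: int) -> List[str]:
    codes = rng.integers(0, 4, size=(n_reads, read_length))
    return [bytes(_BASES[row]).decode() for row in codes]


def _best_scores(reads: Sequence[str], pwm: PWM,
                 pseudocount: float = 1e-3) -> np.ndarray:
    """Vectorized best log-odds PWM score per read over both strands."""
    w = pwm.width
    logodds = np.log2((pwm.freqs + pseudocount) / (1.0 + 4 * pseudocount)
                      / 0.25)
    enc = np.array([_BASE_TO_INT[np.frombuffer(r.encode(), dtype=np.uint8)]
                    for r in reads])
    best = np.full(len(reads), -np.inf)
    for strand_enc in (enc, 3 - enc[:, ::-1]):  # reverse complement = 3 - code
        windows = np.lib.stride_tricks.sliding_window_view(strand_enc, w,
                                                           axis=1)
        scores = logodds[np.arange(w)[None, None, :], windows].sum(axis=2)
        np.maximum(best, scores.max(axis=1), out=best)
    return best


def generate_selex_reads(pwm: PWM, n_reads: int, read_length: int,
                         n_cycles: int, temperature: float, seed: int,
                         site: Optional[str] = None,
                         site_freq: float = 0.0) -> List[List[str]]:
    """Simulated SELEX cycles: uniform cycle 0, then Boltzmann resampling.

    Each later cycle resamples the previous cycle's reads with probability
    proportional to exp(best PWM log-odds score / temperature), so
    high-affinity k-mers enrich monotonically in expectation. Returns
    n_cycles + 1 read lists (index 0 is the unselected pool). When *site*
    is given, each cycle-0 read independently carries an embedded copy at
    a random offset with probability *site_freq*.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if read_length < pwm.width:
        raise ValueError("read_length must be >= PWM width")
    if site is not None and len(site) > read_length:
        raise ValueError("embedded site longer than read")
    rng = np.random.default_rng(seed)
    reads = _random_reads(rng, n_reads, read_length)
    if site is not None and site_freq > 0:
        embed = rng.random(n_reads) < site_freq
        offsets = rng.integers(0, read_length - len(site) + 1, n_reads)
        for i in np.nonzero(embed)[0]:
            o = offsets[i]
            reads[i] = reads[i][:o] + site + reads[i][o + len(site):]
    cycles = [reads]
    for _ in range(n_cycles):
        scores = _best_scores(cycles[-1], pwm)
        weights = np.exp((scores - scores.max()) / temperature)
        probs = weights / weights.sum()
        idx = rng.choice(n_reads, size=n_reads, replace=True, p=probs)
        cycles.append([cycles[-1][i] for i in idx])
    return cycles


def generate_haplotypes(n_haps: int, n_sites: int, focal_index: int,
                        derived_freq: float, sweep_strength: float,
                        seed: int) -> HaplotypeMatrix:
    """Copying-model haplotype panel around a partially swept focal allele.

    Background alleles are independent Bernoulli draws at per-site
    frequencies. Each derived carrier copies a single founder haplotype
    over a segment around the focal site whose per-side extent (in sites)
    is exponential with mean *sweep_strength*; strength 0 reduces to the
    exchangeable neutral model.
    """
    if not 0.0 < derived_freq < 1.0:
        raise ValueError("derived_freq must lie strictly in (0, 1)")
    if not 0 <= focal_index < n_sites:
        raise ValueError("focal_index out of bounds")
    if sweep_strength < 0:
        raise ValueError("sweep_strength must be non-negative")
    rng = np.random.default_rng(seed)
    positions = np.cumsum(rng.integers(50, 151, size=n_sites))
    site_freqs = rng.uniform(0.1, 0.9, n_sites)
    haps = (rng.random((n_haps, n_sites)) < site_freqs[None, :]).astype(np.int8)

    n_derived = int(round(n_haps * derived_freq))
    n_derived = min(max(n_derived, 1), n_haps - 1)
    carriers = rng.permutation(n_haps)[:n_derived]
    haps[:, focal_index] = 0
    haps[carriers, focal_index] = 1

    if sweep_strength > 0:
        founder = (rng.random(n_sites) < site_freqs).astype(np.int8)
        for h in carriers:
            left = int(rng.exponential(sweep_strength))
            right = int(rng.exponential(sweep_strength))
            lo = max(focal_index - left, 0)
            hi = min(focal_index + right + 1, n_sites)
            haps[h, lo:hi] = founder[lo:hi]
        haps[carriers, focal_index] = 1  # focal allele stays derived
    return HaplotypeMatrix(haps, positions, focal_index)


def generate_tmaze_trials(n_trials: int, n_flies: int, green_prob: float,
                          seed: int, line_id: str = "",
                          has_insertion: Optional[bool] = None
                          ) -> List[TrialCounts]:
    """Binomial two-choice trials: N_G ~ Binomial(n_flies, green_prob)."""
    if not 0.0 <= green_prob <= 1.0:
        raise ValueError("green_prob must lie in [0, 1]")
    if n_flies <= 0:
        raise ValueError("n_flies must be positive")
    rng = np.random.default_rng(seed)
    n_green = rng.binomial(n_flies, green_prob, size=n_trials)
    return [TrialCounts(int(g), int(n_flies - g), line_id=line_id,
                        has_insertion=has_insertion) for g in n_green]
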