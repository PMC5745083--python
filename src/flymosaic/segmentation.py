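"""Automated R7 photoreceptor identification and ON/OFF mosaic counting.

The chain: homomorphic denoising of each channel, Canny edge detection,
convex-hull rough segmentation of edge components, morphological
active-contour refinement, marker-based watershed partitioning, size- and
center-distance exclusion, then per-region two-channel classification into
RH3 (OFF) / RH4 (ON) / AMBIGUOUS calls and the per-retina %ON summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure, morphology, segmentation

__all__ = [
    "CandidateRegion",
    "MosaicCount",
    "R7Region",
    "RetinaImage",
    "SegmentationParams",
    "classify_regions",
    "count_mosaic",
    "detect_boundaries",
    "filter_regions",
    "homomorphic_denoise",
    "refine_contours",
    "roi_mean_intensity",
    "rough_segment",
    "watershed_partition",
]

logger = logging.getLogger(__name__)

RH3, RH4, AMBIGUOUS = "RH3", "RH4", "AMBIGUOUS"


@dataclass
class RetinaImage:
    """Two-channel retina raster: rh3 (OFF reporter) and rh4 (ON reporter)."""

    rh3: np.ndarray
    rh4: np.ndarray

    def __post_init__(self) -> None:
        self.rh3 = np.asarray(self.rh3, dtype=float)
        self.rh4 = np.asarray(self.rh4, dtype=float)
        if self.rh3.shape != self.rh4.shape or self.rh3.ndim != 2:
            raise ValueError("channels must be 2-D arrays of equal shape")
        for name, ch in (("rh3", self.rh3), ("rh4", self.rh4)):
            if not np.isfinite(ch).all():
                raise ValueError(f"{name} channel contains non-finite values")
            if (ch < 0).any():
                raise ValueError(f"{name} channel contains negative values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.rh3.shape


@dataclass
class SegmentationParams:
    """Tunable parameters of the counting chain.

    The source procedure names the operators but no numeric values; the
    defaults here are tuned on the synthetic mosaic generator.
    """

    homomorphic_cutoff: float = 0.01   # normalized spatial frequency
    gaussian_sigma: float = 1.0        # post-filter blur, px
    canny_sigma: float = 1.5
    canny_low: float = 0.08
    canny_high: float = 0.2
    contour_iterations: int = 10
    min_area: int = 15                 # px^2
    max_area: int = 500                # px^2
    max_center_distance: float = 0.95  # fraction of image half-diagonal
    intensity_percentile: float = 99.0
    ambiguity_margin: float = 0.05
    norm_floor_fraction: float = 0.2   # floor vs the brighter channel
    min_seed_distance: int = 5         # px, watershed marker separation

    def __post_init__(self) -> None:
        if not 0 < self.canny_low < self.canny_high:
            raise ValueError("require 0 < canny_low < canny_high")
        if self.min_area >= self.max_area:
            raise ValueError("require min_area < max_area")
        if not 0 < self.max_center_distance <= 1:
            raise ValueError("max_center_distance must be in (0, 1]")


@dataclass
class CandidateRegion:
    """A candidate cell region as a boolean mask over the full image."""

    mask: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> Tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())


@dataclass
class R7Region:
    label: int
    pixel_count: int
    centroid: Tuple[float, float]
    mean_rh3: float
    mean_rh4: float
    norm_rh3: float
    norm_rh4: float
    call: str


@dataclass
class MosaicCount:
    """Per-retina region tallies; pct_on = 100 * n_rh4 / (n_rh3 + n_rh4)."""

    n_rh3: int
    n_rh4: int
    n_ambiguous: int = 0

    @property
    def n_called(self) -> int:
        return self.n_rh3 + self.n_rh4

    @property
    def pct_on(self) -> float:
        if self.n_called == 0:
            raise ValueError("pct_on undefined: no called regions")
        return 100.0 * self.n_rh4 / self.n_called

    def meets_floor(self, min_scored: int = 100) -> bool:
        """Scoring floor: at least *min_scored* R7s called per retina."""
        return self.n_called >= min_scored


def homomorphic_denoise(channel: np.ndarray, cutoff: float = 0.01,
                        gaussian_sigma: float = 1.0) -> np.ndarray:
    """Remove a multiplicative illumination field, then Gaussian-blur.

    The channel is offset to be strictly positive, log-transformed, and
    high-pass filtered (subtracting a Gaussian low-pass of normalized
    cutoff frequency *cutoff*, re-adding the global log-mean so intensity
    scale is preserved). cutoff = 0 skips the filter, leaving only the blur.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite values")
    eps = max(channel.max(), 1.0) * 1e-3
    log_img = np.log(channel - min(channel.min(), 0.0) + eps)
    if cutoff > 0:
        sigma_lp = 1.0 / (2.0 * math.pi * cutoff)
        low = ndi.gaussian_filter(log_img, sigma_lp)
        log_img = log_img - low + low.mean()
    out = np.exp(log_img) - eps
    np.clip(out, 0.0, None, out=out)
    if gaussian_sigma > 0:
        out = ndi.gaussian_filter(out, gaussian_sigma)
    return out


def _rescale01(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        return np.zeros_like(channel, dtype=float)
    return (channel - lo) / (hi - lo)


def detect_boundaries(channel: np.ndarray, canny_low: float,
                      canny_high: float, sigma: float = 1.5) -> np.ndarray:
    """Canny edge map (hysteresis thresholds on the [0,1]-rescaled raster)."""
    if not 0 < canny_low < canny_high:
        raise ValueError("require 0 < canny_low < canny_high")
    return feature.canny(_rescale01(np.asarray(channel, dtype=float)),
                         sigma=sigma, low_threshold=canny_low,
                         high_threshold=canny_high)


def rough_segment(edges: np.ndarray) -> List[CandidateRegion]:
    """Convex hull of each connected edge component -> candidate regions."""
    labels = measure.label(edges, connectivity=2)
    regions = []
    for prop in measure.regionprops(labels):
        mask = np.zeros(edges.shape, dtype=bool)
        if prop.area >= 3:
            hull = prop.image_convex
        else:
            hull = prop.image
        mask[prop.slice] = hull
        regions.append(CandidateRegion(mask))
    return regions


def refine_contours(regions: Sequence[CandidateRegion], channel: np.ndarray,
                    contour_iterations: int = 10,
                    max_dilation: int = 3) -> List[CandidateRegion]:
    """Evolve each region boundary toward intensity structure.

    Morphological Chan–Vese active contours run for at most
    *contour_iterations* steps on a padded crop around each region; the
    refined mask is constrained to a *max_dilation*-pixel dilation of its
    input hull. Zero iterations is the identity.
    """
    if contour_iterations <= 0:
        return [CandidateRegion(r.mask.copy()) for r in regions]
    channel = np.asarray(channel, dtype=float)
    out = []
    pad = max_dilation + 2
    selem = morphology.disk(max_dilation)
    for region in regions:
        rows, cols = np.nonzero(region.mask)
        r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1,
                                               channel.shape[0])
        c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1,
                                               channel.shape[1])
        patch = channel[r0:r1, c0:c1]
        init = region.mask[r0:r1, c0:c1]
        evolved = segmentation.morphological_chan_vese(
            _rescale01(patch), num_iter=contour_iterations,
            init_level_set=init.astype(np.int8))
        bound = ndi.binary_dilation(init, structure=selem)
        refined = evolved.astype(bool) & bound
        mask = np.zeros(channel.shape, dtype=bool)
        if refined.any():
            mask[r0:r1, c0:c1] = refined
        else:
            mask |= region.mask  # degenerate evolution: keep the hull
        out.append(CandidateRegion(mask))
    return out


def watershed_partition(image: RetinaImage,
                        regions: Sequence[CandidateRegion],
                        min_seed_distance: int = 5,
                        smoothing_sigma: float = 1.0) -> np.ndarray:
    """Split the candidate foreground into single-cell labels.

    Seeds are local intensity maxima of the smoothed summed channel inside
    the union of refined regions (a region without a peak seeds at its
    centroid); the watershed floods the inverted intensity from those
    seeds. Returns a labeled raster (0 = background).
    """
    shape = image.shape
    if not regions:
        logger.warning("watershed: no candidate regions, empty labeling")
        return np.zeros(shape, dtype=np.int32)
    foreground = np.zeros(shape, dtype=bool)
    for r in regions:
        foreground |= r.mask
    combined = ndi.gaussian_filter(image.rh3 + image.rh4, smoothing_sigma)
    peaks = feature.peak_local_max(combined, min_distance=min_seed_distance,
                                   labels=foreground.astype(np.int32),
                                   exclude_border=False)
    seed_mask = np.zeros(shape, dtype=bool)
    if peaks.size:
        seed_mask[peaks[:, 0], peaks[:, 1]] = True
    for r in regions:  # guarantee every candidate contributes a seed
        if not (seed_mask & r.mask).any():
            cr, cc = r.centroid
            seed_mask[int(round(cr)), int(round(cc))] = True
    markers, n_seeds = ndi.label(seed_mask)
    if n_seeds == 0:
        logger.warning("watershed: no seeds found, empty labeling")
        return np.zeros(shape, dtype=np.int32)
    return segmentation.watershed(-combined, markers=markers,
                                  mask=foreground).astype(np.int32)


def filter_regions(labels: np.ndarray, min_area: int, max_area: int,
                   max_center_distance: float = 1.0) -> np.ndarray:
    """Exclude labeled regions by size or centroid distance from center.

    Distance is measured as a fraction of the image half-diagonal; regions
    strictly outside [min_area, max_area] or beyond *max_center_distance*
    are zeroed out, others are untouched.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    center = (np.array(labels.shape) - 1) / 2.0
    half_diag = float(np.linalg.norm(center)) or 1.0
    for prop in measure.regionprops(labels):
        dist = float(np.linalg.norm(np.asarray(prop.centroid) - center))
        if (prop.area < min_area or prop.area > max_area
                or dist / half_diag > max_center_distance):
            out[labels == prop.label] = 0
    return out


def classify_regions(labels: np.ndarray, image: RetinaImage,
                     intensity_percentile: float = 99.0,
                     ambiguity_margin: float = 0.05,
                     norm_floor_fraction: float = 0.2) -> List[R7Region]:
    """Assign each labeled region an RH3 / RH4 / AMBIGUOUS call.

    Each channel is normalized by its *intensity_percentile* value over the
    pooled pixels of all labeled regions; a region is called for the channel
    whose normalized mean exceeds the other by more than *ambiguity_margin*,
    else AMBIGUOUS. A channel with no signal anywhere would otherwise
    normalize its background to ~1, so each denominator is floored at
    *norm_floor_fraction* of the brighter channel's percentile value.
    """
    labels = np.asarray(labels)
    pool = labels > 0
    if not pool.any():
        return []
    p99 = {name: float(np.percentile(ch[pool], intensity_percentile))
           for name, ch in (("rh3", image.rh3), ("rh4", image.rh4))}
    ceiling = max(p99.values())
    norms = {}
    for name, value in p99.items():
        norm = max(value, norm_floor_fraction * ceiling)
        if norm <= 0:
            raise ValueError(f"zero normalization denominator for channel "
                             f"{name}")
        norms[name] = norm
    out = []
    for prop in measure.regionprops(labels):
        mask = labels == prop.label
        mean3 = float(image.rh3[mask].mean())
        mean4 = float(image.rh4[mask].mean())
        n3, n4 = mean3 / norms["rh3"], mean4 / norms["rh4"]
        if n4 - n3 > ambiguity_margin:
            call = RH4
        elif n3 - n4 > ambiguity_margin:
            call = RH3
        else:
            call = AMBIGUOUS
        out.append(R7Region(prop.label, int(prop.area),
                            tuple(prop.centroid), mean3, mean4, n3, n4,
                            call))
    return out


def count_mosaic(image: RetinaImage,
                 params: SegmentationParams | None = None) -> MosaicCount:
    """Run the full chain on one retina and tally the calls."""
    p = params or SegmentationParams()
    d3 = homomorphic_denoise(image.rh3, p.homomorphic_cutoff, p.gaussian_sigma)
    d4 = homomorphic_denoise(image.rh4, p.homomorphic_cutoff, p.gaussian_sigma)
    denoised = RetinaImage(d3, d4)
    combined = d3 + d4
    edges = detect_boundaries(combined, p.canny_low, p.canny_high,
                              sigma=p.canny_sigma)
    candidates = rough_segment(edges)
    refined = refine_contours(candidates, combined, p.contour_iterations)
    labels = watershed_partition(denoised, refined,
                                 min_seed_distance=p.min_seed_distance)
    labels = filter_regions(labels, p.min_area, p.max_area,
                            p.max_center_distance)
    calls = classify_regions(labels, denoised, p.intensity_percentile,
                             p.ambiguity_margin, p.norm_floor_fraction)
    n3 = sum(1 for r in calls if r.call == RH3)
    n4 = sum(1 for r in calls if r.call == RH4)
    na = sum(1 for r in calls if r.call == AMBIGUOUS)
    logger.info("count_mosaic: %d candidates -> %d regions "
                "(%d RH3, %d RH4, %d ambiguous)",
                len(candidates), len(calls), n3, n4, na)
    return MosaicCount(n3, n4, na)


def roi_mean_intensity(channel: np.ndarray,
                       centers: Sequence[Tuple[float, float]],
                       radius: float) -> List[float]:
    """Mean pixel intensity within a circular ROI around each center.

    Order is preserved; an ROI with no pixels inside the image raises.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    channel = np.asarray(channel, dtype=float)
    h, w = channel.shape
    rows, cols = np.mgrid[0:h, 0:w]
    out = []
    for i, (cr, cc) in enumerate(centers):
        mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius ** 2
        if not mask.any():
            raise ValueError(f"ROI {i} at ({cr}, {cc}) lies entirely outside "
                             "the image")
        out.append(float(channel[mask].mean()))
    return out
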