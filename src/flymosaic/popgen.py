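"""Selection-scan statistics around a focal variant.

Pairwise FST (Hudson estimator, Weir–Cockerham optional), inverse-normal
rank Z-scores, extended haplotype homozygosity (EHH) decay profiles, their
physical-distance integral (iEHH), the log2 derived/ancestral iEHH ratio
(IHS), matched indel control-set selection, and empirical percentile
placement against the control distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EHHProfile",
    "HaplotypeMatrix",
    "ehh",
    "empirical_percentile",
    "fst_pairwise",
    "iehh",
    "ihs",
    "rank_normal_z",
    "select_control_set",
]

ANCESTRAL, DERIVED = 0, 1


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (rows) over sites (columns) with bp positions."""

    haplotypes: np.ndarray       # (n_haps, n_sites) in {0, 1}
    positions: np.ndarray        # (n_sites,) 1-based bp, strictly increasing
    focal_index: int

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.positions.shape != (self.haplotypes.shape[1],):
            raise ValueError("positions length must equal the number of sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not 0 <= self.focal_index < self.haplotypes.shape[1]:
            raise ValueError("focal index out of bounds")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be 0 (ancestral) or 1 (derived)")

    @property
    def n_haps(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def focal_alleles(self) -> np.ndarray:
        return self.haplotypes[:, self.focal_index]


@dataclass
class EHHProfile:
    """EHH decay away from the focal site, one arm per direction.

    Distances are positive bp offsets from the focal position; values start
    implicitly at EHH = 1 at distance 0 (the focal site itself).
    """

    allele_class: int
    n_carriers: int
    left_distances: np.ndarray
    left_ehh: np.ndarray
    right_distances: np.ndarray
    right_ehh: np.ndarray


def _ehh_arm(carriers: np.ndarray, site_order: Sequence[int]) -> np.ndarray:
    """EHH at each successive site, grouping haplotypes by growing prefix.

    carriers: (n_c, n_sites) alleles of the core carriers; site_order gives
    the column visit order walking away from the focal site.
    """
    n_c = carriers.shape[0]
    denom = n_c * (n_c - 1)
    # group id per haplotype; refined as each site is appended
    groups = np.zeros(n_c, dtype=np.int64)
    out = np.empty(len(site_order))
    for j, col in enumerate(site_order):
        key = groups * 2 + carriers[:, col]
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        out[j] = (counts * (counts - 1)).sum() / denom
    return out


def ehh(haps: HaplotypeMatrix, allele_class: int) -> EHHProfile:
    """EHH profile for the carriers of one focal allele class.

    EHH(x) = sum_h n_h (n_h - 1) / (n_c (n_c - 1)) over the distinct
    extended haplotypes h spanning the focal site out to x, computed
    separately leftward and rightward. Requires >= 2 carriers.
    """
    if allele_class not in (ANCESTRAL, DERIVED):
        raise ValueError("allele_class must be 0 or 1")
    mask = haps.focal_alleles == allele_class
    n_c = int(mask.sum())
    if n_c < 2:
        raise ValueError(f"need >= 2 carriers of allele {allele_class}, "
                         f"have {n_c}")
    carriers = haps.haplotypes[mask]
    f = haps.focal_index
    pos = haps.positions
    left_order = list(range(f - 1, -1, -1))
    right_order = list(range(f + 1, haps.n_sites))
    return EHHProfile(
        allele_class=allele_class,
        n_carriers=n_c,
        left_distances=pos[f] - pos[left_order],
        left_ehh=_ehh_arm(carriers, left_order),
        right_distances=pos[right_order] - pos[f],
        right_ehh=_ehh_arm(carriers, right_order),
    )


def _integrate_arm(distances: np.ndarray, values: np.ndarray,
                   threshold: float) -> Tuple[float, bool]:
    """Trapezoid over (0, EHH=1) .. points while EHH >= threshold.

    Stops before the first point below threshold; returns (area, unbounded)
    where unbounded means EHH never dropped below threshold.
    """
    d = np.concatenate([[0.0], np.asarray(distances, dtype=float)])
    v = np.concatenate([[1.0], np.asarray(values, dtype=float)])
    below = np.nonzero(v < threshold)[0]
    if below.size:
        stop = below[0]
        unbounded = False
    else:
        stop = len(v)
        unbounded = True
    if stop < 2:
        return 0.0, unbounded
    return float(np.trapezoid(v[:stop], d[:stop])), unbounded


def iehh(profile: EHHProfile, threshold: float = 0.05,
         return_flags: bool = False):
    """Integrated EHH over physical distance (bp), both arms summed.

    Each arm integrates from the focal site (EHH = 1 at distance 0) by the
    trapezoid rule and truncates before the first point where EHH drops
    below *threshold*; an arm that never drops is integrated to its last
    site and flagged unbounded.
    """
    left, left_unbounded = _integrate_arm(profile.left_distances,
                                          profile.left_ehh, threshold)
    right, right_unbounded = _integrate_arm(profile.right_distances,
                                            profile.right_ehh, threshold)
    total = left + right
    if return_flags:
        return total, left_unbounded, right_unbounded
    return total


def ihs(iehh_derived: float, iehh_ancestral: float) -> float:
    """log2(iEHH_derived / iEHH_ancestral); positive = extended derived
    haplotypes (partial sweep signal)."""
    if iehh_derived <= 0 or iehh_ancestral <= 0:
        raise ValueError("iEHH inputs must be positive")
    return math.log2(iehh_derived / iehh_ancestral)


def fst_pairwise(freq_table: pd.DataFrame, pop_a: str, pop_b: str,
                 estimator: str = "hudson") -> pd.Series:
    """Per-variant FST between two populations from a frequency table.

    *freq_table* columns: variant, pop, freq, n (chromosomes sampled).
    Hudson's estimator by default; "wc" selects Weir–Cockerham. Values are
    clipped to [0, 1]; variants monomorphic for the same allele in both
    populations are NaN.
    """
    pivot_f = freq_table.pivot_table(index="variant", columns="pop",
                                     values="freq")
    pivot_n = freq_table.pivot_table(index="variant", columns="pop",
                                     values="n")
    for pop in (pop_a, pop_b):
        if pop not in pivot_f.columns:
            raise ValueError(f"population {pop!r} not in frequency table")
    p1, p2 = pivot_f[pop_a].to_numpy(), pivot_f[pop_b].to_numpy()
    n1, n2 = pivot_n[pop_a].to_numpy(), pivot_n[pop_b].to_numpy()
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("sample sizes must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "hudson":
            num = ((p1 - p2) ** 2
                   - p1 * (1 - p1) / (n1 - 1)
                   - p2 * (1 - p2) / (n2 - 1))
            den = p1 * (1 - p2) + p2 * (1 - p1)
        elif estimator == "wc":
            n_bar = (n1 + n2) / 2
            n_c = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2))
            p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 / 2)
                                 / (2 * n_bar - 1))
            b = (2 * n_bar / (2 * n_bar - 1)) * (p_bar * (1 - p_bar) - s2 / 2)
            num, den = a, a + b
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        fst = np.where(den > 0, num / den, np.nan)
    fst = np.clip(fst, 0.0, 1.0)
    return pd.Series(fst, index=pivot_f.index, name="fst")


def rank_normal_z(values: Sequence[float]) -> np.ndarray:
    """Inverse-normal rank transform: Z = Phi^-1((rank - 0.5) / N).

    Ties take the average rank; a constant vector maps to all-zero Z. The
    output is invariant to any strictly monotone transform of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def select_control_set(variants: pd.DataFrame, target_freq: float = 0.25,
                       tolerance: float = 0.05, max_len: int = 2,
                       autosomes: Sequence[str] = ("2L", "2R", "3L", "3R"),
                       exclude: Tuple[str, int] | None = None) -> pd.DataFrame:
    """Frequency-matched indel control set.

    Keeps rows that are indels of length <= max_len, lie on one of the
    listed autosomes, and have freq within target_freq +/- tolerance. The
    focal variant (chrom, pos) is excluded if given.
    Required columns: chrom, pos, is_indel, length, freq.
    """
    required = {"chrom", "pos", "is_indel", "length", "freq"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    keep = (variants["is_indel"].astype(bool)
            & (variants["length"] <= max_len)
            & variants["chrom"].isin(list(autosomes))
            & (variants["freq"] >= target_freq - tolerance)
            & (variants["freq"] <= target_freq + tolerance))
    if exclude is not None:
        chrom, pos = exclude
        keep &= ~((variants["chrom"] == chrom) & (variants["pos"] == pos))
    out = variants.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("control set is empty under the given filters",
                      stacklevel=2)
    return out


def empirical_percentile(stat_value: float,
                         control_values: Sequence[float]) -> Tuple[float, float]:
    """Percentile of *stat_value* in the control distribution and a
    two-sided empirical p = 2 * min(tail proportions), floored at 1/(N+1)
    and capped at 1."""
    controls = np.asarray(control_values, dtype=float)
    if controls.size == 0:
        raise ValueError("control set is empty")
    n = controls.size
    lower = float((controls <= stat_value).sum()) / n
    upper = float((controls >= stat_value).sum()) / n
    percentile = 100.0 * lower
    p = 2.0 * min(lower, upper)
    p = min(1.0, max(p, 1.0 / (n + 1)))
    return percentile, p
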