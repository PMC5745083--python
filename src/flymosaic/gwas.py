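"""Hemizygosity-cross simulation and quantitative association scan.

The cross remap turns inbred-panel genotypes into the genotypes of progeny
from a cross to a deficiency chromosome: homozygous reference stays
homozygous reference; homozygous alternate stays homozygous alternate
inside the deficiency interval and becomes heterozygous outside it; every
other call becomes missing. The scan is per-variant OLS of the phenotype on
allele dosage with relationship-matrix PC covariates, family-wise error
controlled by max(T) permutation and a Bonferroni threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeficiencyInterval",
    "GenotypeMatrix",
    "HOM_REF", "HET", "HOM_ALT", "MISSING",
    "Variant",
    "association_scan",
    "bonferroni_threshold",
    "compute_relationship_pcs",
    "maxT_permutation",
    "simulate_cross",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vid: str = "."

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class GenotypeMatrix:
    """Lines x variants genotype codes in {HOM_REF, HET, HOM_ALT, MISSING}."""

    variants: List[Variant]
    lines: List[str]
    calls: np.ndarray  # (n_lines, n_variants), int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.variants)):
            raise ValueError("calls shape must be (n_lines, n_variants)")
        if not np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING)).all():
            raise ValueError("invalid genotype codes")
        by_chrom: dict = {}
        for v in self.variants:
            prev = by_chrom.get(v.chrom)
            if prev is not None and v.pos < prev:
                raise ValueError("positions must be sorted within chromosome")
            by_chrom[v.chrom] = v.pos

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self, impute: bool = False) -> np.ndarray:
        """Float dosage matrix: HOM_REF=0, HET=1, HOM_ALT=2.

        Missing calls become NaN, or the per-variant mean when impute=True
        (monomorphic-missing columns fall back to 0).
        """
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute:
            means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            means = np.nan_to_num(means, nan=0.0)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[1]]
        return d


@dataclass(frozen=True)
class DeficiencyInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def simulate_cross(genotypes: GenotypeMatrix,
                   deficiency: DeficiencyInterval) -> GenotypeMatrix:
    """Remap inbred-line genotypes to deficiency-cross progeny genotypes."""
    if not any(v.chrom == deficiency.chrom for v in genotypes.variants):
        raise ValueError(f"deficiency chromosome {deficiency.chrom!r} absent "
                         "from the genotype matrix")
    inside = np.array([deficiency.contains(v.chrom, v.pos)
                       for v in genotypes.variants])
    calls = genotypes.calls
    out = np.full_like(calls, MISSING)
    out[calls == HOM_REF] = HOM_REF
    hom_alt = calls == HOM_ALT
    out[hom_alt & inside[None, :]] = HOM_ALT
    out[hom_alt & ~inside[None, :]] = HET
    return GenotypeMatrix(list(genotypes.variants), list(genotypes.lines), out)


def compute_relationship_pcs(genotypes: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Top eigenvectors of the standardized genetic relationship matrix.

    Dosages are mean-imputed per variant, centered by 2p and scaled by
    sqrt(2p(1-p)); monomorphic variants are skipped. Returns a
    (n_lines, n_pcs) covariate matrix.
    """
    if genotypes.n_lines < n_pcs + 1:
        raise ValueError(f"{genotypes.n_lines} lines cannot support "
                         f"{n_pcs} principal components")
    d = genotypes.dosages(impute=True)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants for the relationship matrix")
    z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    grm = z @ z.T / poly.sum()
    eigvals, eigvecs = np.linalg.eigh(grm)
    order = np.argsort(eigvals)[::-1]
    return eigvecs[:, order[:n_pcs]]


def _design_basis(covariates: np.ndarray | None, idx: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of [intercept | covariates] on the rows in idx."""
    n = int(idx.sum())
    cols = [np.ones((n, 1))]
    if covariates is not None and covariates.shape[1] > 0:
        cols.append(covariates[idx])
    design = np.hstack(cols)
    q, _ = np.linalg.qr(design)
    return q


def _variant_context(genotypes: GenotypeMatrix,
                     covariates: np.ndarray | None,
                     mac_floor: int):
    """Per-variant (idx, residual dosage, its squared norm, df) or None.

    A variant is untestable when its minor-allele count is below mac_floor,
    its dosage is constant, the residual degrees of freedom are non-positive,
    or its residualized dosage is numerically null (collinear design).
    """
    dos = genotypes.dosages(impute=False)
    n_cov = 0 if covariates is None else covariates.shape[1]
    contexts = []
    for j in range(genotypes.n_variants):
        d = dos[:, j]
        idx = ~np.isnan(d)
        n = int(idx.sum())
        df = n - n_cov - 2
        if n == 0 or df < 1:
            contexts.append(None)
            continue
        x = d[idx]
        alt_count = x.sum()
        mac = min(alt_count, 2 * n - alt_count)
        if mac < mac_floor or np.ptp(x) == 0:
            contexts.append(None)
            continue
        q = _design_basis(covariates, idx)
        x_res = x - q @ (q.T @ x)
        xx = float(x_res @ x_res)
        if xx <= 1e-12:
            contexts.append(None)  # collinear with covariates
            continue
        contexts.append((idx, q, x_res, xx, df))
    return contexts


def _t_for_phenotype(ctx, y: np.ndarray) -> Tuple[float, float]:
    """(beta, t) for one variant context against a full-length phenotype."""
    idx, q, x_res, xx, df = ctx
    ys = y[idx]
    y_res = ys - q @ (q.T @ ys)
    beta = float(x_res @ y_res) / xx
    rss = float(y_res @ y_res) - beta ** 2 * xx
    sigma2 = max(rss, 0.0) / df
    if sigma2 <= 0:
        return beta, math.inf if beta != 0 else 0.0
    return beta, beta * math.sqrt(xx / sigma2)


def _phenotype_vector(genotypes: GenotypeMatrix,
                      phenotype: pd.Series | dict) -> np.ndarray:
    pheno = pd.Series(phenotype)
    missing = [l for l in genotypes.lines if l not in pheno.index]
    if missing:
        raise ValueError(f"phenotype missing for lines: {missing[:5]}")
    return pheno.loc[genotypes.lines].to_numpy(dtype=float)


def association_scan(genotypes: GenotypeMatrix,
                     phenotype: pd.Series | dict,
                     covariates: np.ndarray | None = None,
                     mac_floor: int = 5) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage + covariates + intercept.

    Lines missing a variant's call are dropped for that variant. Returns a
    DataFrame (chrom, pos, beta, t, p, tested); untested variants (below the
    minor-allele-count floor or with a singular design) carry NaN statistics
    and tested=False.
    """
    y = _phenotype_vector(genotypes, phenotype)
    contexts = _variant_context(genotypes, covariates, mac_floor)
    rows = []
    for v, ctx in zip(genotypes.variants, contexts):
        if ctx is None:
            rows.append((v.chrom, v.pos, np.nan, np.nan, np.nan, False))
            continue
        beta, t = _t_for_phenotype(ctx, y)
        df = ctx[4]
        p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
        rows.append((v.chrom, v.pos, beta, t, p, True))
    return pd.DataFrame(rows, columns=["chrom", "pos", "beta", "t", "p",
                                       "tested"])


def maxT_permutation(genotypes: GenotypeMatrix,
                     phenotype: pd.Series | dict,
                     covariates: np.ndarray | None = None,
                     n_perm: int = 1000,
                     seed: int | None = None,
                     mac_floor: int = 5) -> pd.DataFrame:
    """Empirical family-wise p-values from max(T) phenotype permutation.

    Raw phenotype vectors are permuted across lines n_perm times, the full
    covariate-adjusted scan refit each time, and the maximum |t| over tested
    variants recorded. The empirical p of variant v is
    (1 + #{perms: max|t| >= |t_v|}) / (n_perm + 1), hence monotone
    non-increasing in |t_v|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = _phenotype_vector(genotypes, phenotype)
    contexts = _variant_context(genotypes, covariates, mac_floor)

    obs = np.full(genotypes.n_variants, np.nan)
    betas = np.full(genotypes.n_variants, np.nan)
    for j, ctx in enumerate(contexts):
        if ctx is not None:
            betas[j], obs[j] = _t_for_phenotype(ctx, y)

    # (n_lines, n_perm) matrix of permuted phenotypes, residualized per variant
    perm_y = np.column_stack([y[rng.permutation(len(y))]
                              for _ in range(n_perm)])
    max_t = np.zeros(n_perm)
    for ctx in contexts:
        if ctx is None:
            continue
        idx, q, x_res, xx, df = ctx
        ys = perm_y[idx]
        y_res = ys - q @ (q.T @ ys)
        beta = (x_res @ y_res) / xx
        rss = np.einsum("ij,ij->j", y_res, y_res) - beta ** 2 * xx
        sigma2 = np.maximum(rss, 0.0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sigma2 > 0, beta * np.sqrt(xx / sigma2),
                         np.where(beta != 0, np.inf, 0.0))
        np.maximum(max_t, np.abs(t), out=max_t)

    emp_p = np.full(genotypes.n_variants, np.nan)
    tested = ~np.isnan(obs)
    for j in np.nonzero(tested)[0]:
        emp_p[j] = (1 + (max_t >= abs(obs[j])).sum()) / (n_perm + 1)

    return pd.DataFrame({
        "chrom": [v.chrom for v in genotypes.variants],
        "pos": [v.pos for v in genotypes.variants],
        "beta": betas,
        "t": obs,
        "emp_p": emp_p,
        "tested": tested,
    })


def bonferroni_threshold(p_values: Sequence[float],
                         alpha: float = 0.05) -> Tuple[float, np.ndarray]:
    """alpha / m threshold over tested (non-NaN) p-values and per-variant
    significance flags (NaN p-values are never significant)."""
    p = np.asarray(p_values, dtype=float)
    m = int(np.isfinite(p).sum())
    if m < 1:
        raise ValueError("no tested variants")
    threshold = alpha / m
    flags = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    flags[finite] = p[finite] <= threshold
    return threshold, flags
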