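"""Canonical k-mer counting and binding-site affinity statistics.

Implements reverse-complement-canonical k-mer tables, consensus-distance
orientation, read-level binding-site counts with McNemar's test,
frequency-rank statistics against the canonical k-mer universe,
positional-dependence grids, count-based PWM construction and log-odds
scoring, and single-base insertion arithmetic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "BindingSiteSet",
    "KmerTable",
    "PWM",
    "SiteReadCounts",
    "apply_insertion",
    "build_pwm",
    "canonical",
    "canonical_kmer_counts",
    "canonical_universe_size",
    "consensus_orient",
    "count_site_reads",
    "hamming",
    "mcnemar_test",
    "positional_dependence",
    "pwm_score",
    "rank_kmers_above",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Binding-site sequences used throughout: the repressor's endogenous core,
#: the same core carrying the single-base insertion, the predicted optimal
#: core, and the extended endogenous context.
@dataclass(frozen=True)
class BindingSiteSet:
    site_without_sin: str = "CGCCCACACA"
    site_with_sin: str = "CGCCCACACC"
    optimal_site: str = "CGCCCACGCA"
    extended_site: str = "ACGCCCACACAC"

    def __post_init__(self) -> None:
        for s in (self.site_without_sin, self.site_with_sin,
                  self.optimal_site, self.extended_site):
            if set(s) - set("ACGT"):
                raise ValueError(f"site {s!r} contains non-ACGT characters")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G; N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic-minimum canonical form of *kmer* vs its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def canonical_universe_size(k: int) -> int:
    """Number of distinct canonical k-mers, (4^k + 4^(k/2)) / 2 for even k.

    Only even k is supported: for odd k no k-mer is its own reverse
    complement and the formula differs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k % 2 != 0:
        raise ValueError("only even k supported for the canonical universe size")
    return (4 ** k + 4 ** (k // 2)) // 2


@dataclass
class KmerTable:
    """Canonical k-mer counts for one read set (or a merged collection)."""

    k: int
    counts: Dict[str, int]
    cycle: str = ""
    orientation: str = "lexmin"

    @property
    def total_distinct(self) -> int:
        return len(self.counts)

    def merge(self, other: "KmerTable") -> "KmerTable":
        """Combine counts by addition; k and orientation must match."""
        if self.k != other.k or self.orientation != other.orientation:
            raise ValueError("cannot merge tables with different k or orientation")
        merged = Counter(self.counts)
        merged.update(other.counts)
        return KmerTable(self.k, dict(merged),
                         cycle=f"{self.cycle}+{other.cycle}",
                         orientation=self.orientation)


def canonical_kmer_counts(reads: Iterable[str], k: int, cycle: str = "") -> KmerTable:
    """Count canonical k-mers across reads.

    Every window of length k is counted once under lexicographic-minimum
    canonicalization; windows containing N are skipped. Counting from reads
    shorter than k yields an empty table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for read in reads:
        read = read.upper()
        n = len(read)
        for i in range(n - k + 1):
            kmer = read[i:i + k]
            if "N" in kmer:
                continue
            counts[canonical(kmer)] += 1
    return KmerTable(k, dict(counts), cycle=cycle)


def consensus_orient(kmer: str, consensus: str) -> str:
    """Return *kmer* or its reverse complement, whichever is closer in
    Hamming distance to *consensus*; ties keep the forward orientation."""
    rc = reverse_complement(kmer)
    d_fwd = hamming(kmer, consensus)
    d_rev = hamming(rc, consensus)
    return rc if d_rev < d_fwd else kmer


@dataclass(frozen=True)
class SiteReadCounts:
    """Partition of a read set by containment of the two focal sites."""

    n_with_only: int
    n_without_only: int
    n_both: int
    n_neither: int

    @property
    def total(self) -> int:
        return self.n_with_only + self.n_without_only + self.n_both + self.n_neither


def _contains_either_strand(read: str, site: str) -> bool:
    return site in read or reverse_complement(site) in read


def count_site_reads(reads: Sequence[str], sites: BindingSiteSet) -> SiteReadCounts:
    """Partition reads by containment of the with-insertion vs the
    without-insertion site, scanning both strands of each read."""
    if not reads:
        raise ValueError("empty read set")
    n_with = n_without = n_both = n_neither = 0
    for read in reads:
        read = read.upper()
        has_with = _contains_either_strand(read, sites.site_with_sin)
        has_without = _contains_either_strand(read, sites.site_without_sin)
        if has_with and has_without:
            n_both += 1
        elif has_with:
            n_with += 1
        elif has_without:
            n_without += 1
        else:
            n_neither += 1
    return SiteReadCounts(n_with, n_without, n_both, n_neither)


def mcnemar_test(counts: SiteReadCounts) -> Tuple[float, float, float | None]:
    """McNemar's test on the discordant read counts.

    Returns (statistic, chi-square p, exact binomial p). The statistic is
    the uncorrected (b - c)^2 / (b + c) with 1 df. The exact two-sided
    binomial p is computed whenever the discordant total is below 25, else
    None.
    """
    b, c = counts.n_with_only, counts.n_without_only
    n_disc = b + c
    if n_disc == 0:
        raise ValueError("no discordant reads: McNemar statistic undefined")
    statistic = (b - c) ** 2 / n_disc
    p_chi2 = float(stats.chi2.sf(statistic, df=1))
    p_exact = None
    if n_disc < 25:
        p_exact = float(stats.binomtest(min(b, c), n_disc, 0.5).pvalue)
    return float(statistic), p_chi2, p_exact


def rank_kmers_above(table: KmerTable, site: str,
                     denominator: str = "universe") -> Tuple[int, float]:
    """Count canonical k-mers with frequency strictly greater than the site's.

    Returns (count, percentage). The percentage denominator is the full
    canonical universe (4^k + 4^(k/2)) / 2 by default, or the number of
    distinct observed k-mers with ``denominator="observed"``. A site absent
    from the table has frequency 0.
    """
    if len(site) != table.k:
        raise ValueError(f"site length {len(site)} != table k {table.k}")
    site_count = table.counts.get(canonical(site), 0)
    n_above = sum(1 for c in table.counts.values() if c > site_count)
    if denominator == "universe":
        denom = canonical_universe_size(table.k)
    elif denominator == "observed":
        denom = table.total_distinct
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return n_above, 100.0 * n_above / denom


def positional_dependence(table: KmerTable, core_template: str,
                          positions: Sequence[int],
                          alphabet: Sequence[str] = "ACGT") -> Dict[Tuple[str, ...], int]:
    """Canonical-table counts for every instantiation of wildcard positions.

    *core_template* carries arbitrary placeholder characters at the queried
    1-based *positions*; every combination of *alphabet* bases is substituted
    there and the canonical count of the resulting k-mer looked up. Returns
    a mapping from the base combination tuple to the count.
    """
    if len(core_template) != table.k:
        raise ValueError("template length must equal table k")
    for p in positions:
        if not 1 <= p <= len(core_template):
            raise ValueError(f"position {p} out of range 1..{len(core_template)}")
    grid: Dict[Tuple[str, ...], int] = {}
    chars = list(core_template)
    import itertools
    for combo in itertools.product(alphabet, repeat=len(positions)):
        inst = chars[:]
        for pos, base in zip(positions, combo):
            inst[pos - 1] = base
        kmer = "".join(inst)
        grid[combo] = table.counts.get(canonical(kmer), 0)
    return grid


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix: per-position base frequencies (columns sum to 1)."""

    freqs: np.ndarray  # shape (width, 4), columns ordered A C G T

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("PWM frequency matrix must have shape (width, 4)")
        if np.any(self.freqs < 0):
            raise ValueError("PWM frequencies must be non-negative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits: 2 - entropy."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(self.freqs > 0,
                            self.freqs * np.log2(self.freqs), 0.0).sum(axis=1)
        return 2.0 - ent

    @classmethod
    def uniform(cls, width: int) -> "PWM":
        return cls(np.full((width, 4), 0.25))

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.91) -> "PWM":
        """Near-one-hot PWM putting *match_prob* on each consensus base."""
        off = (1.0 - match_prob) / 3.0
        m = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            m[i, _BASE_INDEX[b]] = match_prob
        return cls(m)


def build_pwm(oriented_kmers: Mapping[str, int] | Sequence[str],
              pseudocount: float = 0.0) -> PWM:
    """Count-weighted PWM from consensus-oriented k-mers.

    Accepts either a mapping k-mer -> count or a plain sequence (each
    weighted 1). All k-mers must share one length.
    """
    if isinstance(oriented_kmers, Mapping):
        items = list(oriented_kmers.items())
    else:
        items = [(k, 1) for k in oriented_kmers]
    if not items:
        raise ValueError("cannot build a PWM from no k-mers")
    width = len(items[0][0])
    counts = np.full((width, 4), float(pseudocount))
    for kmer, count in items:
        if len(kmer) != width:
            raise ValueError("all k-mers must have the same length")
        for i, base in enumerate(kmer):
            counts[i, _BASE_INDEX[base]] += count
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a PWM column received zero total weight")
    return PWM(counts / totals)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def pwm_score(pwm: PWM, sequence: str,
              pseudocount: float = 1e-3) -> Tuple[float, int, str]:
    """Best log2-odds PWM score over all windows on both strands.

    Log-odds uses pseudocounted frequencies against a uniform 0.25
    background. Returns (score, 0-based window start on the forward strand,
    strand '+'/'-').
    """
    w = pwm.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than PWM width")
    logodds = np.log2((pwm.freqs + pseudocount) /
                      (1.0 + 4 * pseudocount) / 0.25)
    best = (-math.inf, -1, "+")
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        enc = _encode(seq.upper())
        n_win = len(seq) - w + 1
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (windows >= 0).all(axis=1)
        scores = np.full(n_win, -math.inf)
        if valid.any():
            idx = np.arange(w)
            scores[valid] = logodds[idx, windows[valid]].sum(axis=1)
        i = int(np.argmax(scores))
        if scores[i] > best[0]:
            # report start position in forward-strand coordinates
            start = i if strand == "+" else len(sequence) - w - i
            best = (float(scores[i]), start, strand)
    return best


def apply_insertion(sequence: str, pos_1based: int, base: str) -> str:
    """Insert *base* before 1-based position *pos_1based*.

    pos = len(sequence) + 1 appends. The output is exactly one base longer.
    """
    if not 1 <= pos_1based <= len(sequence) + 1:
        raise ValueError(f"insertion position {pos_1based} out of range "
                         f"1..{len(sequence) + 1}")
    if base not in _BASES:
        raise ValueError(f"invalid base {base!r}")
    i = pos_1based - 1
    return sequence[:i] + base + sequence[i:]
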