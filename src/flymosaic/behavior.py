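"""Two-choice phototaxis preference-index statistics.

PI = (N_G - N_B) / (N_G + N_B) per trial; lines are summarised by the mean
of per-trial PIs with its SEM, and groups of lines compared with Welch's
unequal-variance t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PreferenceIndex",
    "TrialCounts",
    "group_compare",
    "line_mean_pi",
    "preference_index",
]

#: Paper-protocol floor on trials per genotype; fewer only warns.
MIN_TRIALS = 5


@dataclass(frozen=True)
class TrialCounts:
    """Fly counts for one T-maze trial: green side vs blue side."""

    n_green: int
    n_blue: int
    line_id: str = ""
    has_insertion: bool | None = None

    def __post_init__(self) -> None:
        if self.n_green < 0 or self.n_blue < 0:
            raise ValueError("fly counts must be non-negative")


@dataclass(frozen=True)
class PreferenceIndex:
    value: float
    n_trials: int
    sem: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError("PI must lie in [-1, 1]")


def preference_index(trial: TrialCounts) -> float:
    """(N_G - N_B) / (N_G + N_B); positive = green preference."""
    total = trial.n_green + trial.n_blue
    if total == 0:
        raise ValueError("unscorable trial: no flies on either side")
    return (trial.n_green - trial.n_blue) / total


def line_mean_pi(trials: Sequence[TrialCounts]) -> PreferenceIndex:
    """Mean of per-trial PIs and SEM = sample SD / sqrt(n) for one line."""
    pis = [preference_index(t) for t in trials if t.n_green + t.n_blue > 0]
    if not pis:
        raise ValueError("no scorable trials")
    if len(pis) < MIN_TRIALS:
        warnings.warn(f"only {len(pis)} scorable trials (protocol floor is "
                      f"{MIN_TRIALS})", stacklevel=2)
    n = len(pis)
    mean = float(np.mean(pis))
    sem = float(np.std(pis, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return PreferenceIndex(mean, n, sem)


def group_compare(line_means_a: Sequence[float],
                  line_means_b: Sequence[float]) -> Tuple[float, float]:
    """Welch two-sample comparison of per-line mean PIs.

    Returns (mean(a) - mean(b), two-sided p). Two groups with identical
    means and zero pooled variance return p = 1.
    """
    if len(line_means_a) < 2 or len(line_means_b) < 2:
        raise ValueError("each group needs at least 2 lines")
    a = np.asarray(line_means_a, dtype=float)
    b = np.asarray(line_means_b, dtype=float)
    diff = float(a.mean() - b.mean())
    with warnings.catch_warnings():
        # zero-variance groups trip scipy's precision warning; the NaN
        # outcome is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):
        # zero variance in both groups: identical means are maximally null
        p = 1.0 if diff == 0 else 0.0
    return diff, p
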