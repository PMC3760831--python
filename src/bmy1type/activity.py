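"""One-way ANOVA and Duncan's multiple range test.

Duncan's test compares the k group means of a balanced one-way layout after
sorting them. Two means whose ranks are p apart are separated when their
difference exceeds the least significant range

    R_p = q(alpha_p; p, df) * sqrt(MSE / n),   alpha_p = 1 - (1-alpha)^(p-1),

where q is the upper quantile of the studentized range distribution, MSE and
df come from the one-way ANOVA, and alpha_p is Duncan's protection level.
The classical protection rule applies: a pair contained in a wider
non-significant range is itself declared non-significant. Rank letters are
assigned by the standard underline sweep — each maximal non-significant run
of consecutively ranked means shares a letter, letters ascending from the
smallest mean — so two-letter intermediates arise naturally.

Studentized-range quantiles come from scipy's implementation of the
distribution; results are cached per (span, df, alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import studentized_range

__all__ = [
    "anova_components",
    "studentized_range_q",
    "duncan_mrt",
    "rank_group_count",
    "DuncanResult",
]


def anova_components(groups: Mapping[str, Sequence[float]]) -> tuple[float, int]:
    """Pooled within-group mean square and its df for a balanced layout."""
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("groups must be balanced")
    (n,) = sizes
    if n < 2:
        raise ValueError("need at least two replicates per group")
    k = len(groups)
    mse = float(np.mean([np.var(np.asarray(v, float), ddof=1) for v in groups.values()]))
    return mse, k * (n - 1)


@lru_cache(maxsize=None)
def _q_cached(p: int, df: float, alpha: float) -> float:
    return float(studentized_range.ppf(1.0 - alpha, p, df))


def studentized_range_q(p: int, df: float, alpha: float) -> float:
    """Upper-alpha quantile of the studentized range of p means, error df."""
    if p < 2 or df < 1 or not 0 < alpha < 1:
        raise ValueError("require p >= 2, df >= 1, 0 < alpha < 1")
    return _q_cached(int(p), float(df), float(alpha))


@dataclass(frozen=True)
class DuncanResult:
    """Outcome of Duncan's multiple range test."""

    order: tuple[str, ...]            # group names, ascending mean
    means: Mapping[str, float]
    letters: Mapping[str, str]        # rank letters, 'a' = smallest mean
    mse: float
    error_df: int
    n: int
    alpha: float
    ranges: Mapping[int, float] = field(default_factory=dict)  # span -> R_p

    @property
    def means_descending(self) -> tuple[tuple[str, float], ...]:
        return tuple((g, self.means[g]) for g in reversed(self.order))


def _significance(
    means: np.ndarray, ranges: Mapping[int, float]
) -> np.ndarray:
    """Pairwise significance on ascending means, with range protection.

    A pair (i, j) is significant iff means[j]-means[i] > R_{j-i+1} and the
    pair is not contained in any wider range already found non-significant.
    Spans are processed widest-first, so containment is known when needed.
    """
    k = len(means)
    sig = np.zeros((k, k), dtype=bool)
    nonsig = np.zeros((k, k), dtype=bool)  # marks protected (blocked) spans
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            contained = any(
                nonsig[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j)
            )
            if not contained and means[j] - means[i] > ranges[span]:
                sig[i, j] = sig[j, i] = True
            else:
                nonsig[i, j] = True
    return sig


def _letters(order: Sequence[str], sig: np.ndarray) -> dict[str, str]:
    """Underline sweep: one letter per maximal non-significant run."""
    k = len(order)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        runs.append((i, j))
    maximal = sorted(
        {
            r
            for r in runs
            if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
        }
    )
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(maximal):
        c = chr(ord("a") + idx)
        for t in range(i, j + 1):
            letters[order[t]] += c
    return letters


def duncan_mrt(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test on a balanced one-way layout.

    With MSE = 0 (all replicates equal within groups) only exactly tied means
    share a letter.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mse, df = anova_components(groups)
    n = len(next(iter(groups.values())))
    means = {g: float(np.mean(np.asarray(v, float))) for g, v in groups.items()}
    order = tuple(sorted(means, key=lambda g: (means[g], g)))
    m = np.array([means[g] for g in order])
    k = len(order)
    sem = float(np.sqrt(mse / n))
    ranges = {}
    for span in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        ranges[span] = studentized_range_q(span, df, alpha_p) * sem if sem > 0 else 0.0
    sig = _significance(m, ranges)
    letters = _letters(order, sig)
    return DuncanResult(order, means, letters, mse, df, n, alpha, ranges)


def rank_group_count(result: DuncanResult) -> int:
    """Number of distinct single letters used in the result."""
    return len(set("".join(result.letters.values())))
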