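"""One-way ANOVA, Tukey HSD, and normality summaries.

Sums of squares, the F ratio, and the Tukey–Kramer studentized-range
statistic are computed directly from the group data; tail probabilities
come from scipy's F and studentized-range distributions (the latter is
evaluated numerically by quadrature, not from printed tables).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "PairwiseComparison",
    "normality_summary",
    "one_way_anova",
    "tukey_hsd",
]


@dataclass(frozen=True)
class StatsResult:
    F: float
    df_between: int
    df_within: int
    p: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.df_between < 1 or self.df_within < 1:
            raise ValueError("degrees of freedom must be positive integers")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b), same units as the data
    q_stat: float
    p_adj: float
    significant: bool

    def __post_init__(self):
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError("p_adj must lie in [0, 1]")


def normality_summary(values: Sequence[float]) -> tuple[float, float]:
    """Sample skewness and excess kurtosis (Fisher), bias-corrected.

    Companions to the visual histogram/QQ checks used to justify ANOVA;
    values near (0, 0) are consistent with normality.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input has zero variance; moments undefined")
    skew = float(sps.skew(x, bias=False))
    kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    return skew, kurt


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} needs at least 2 observations")
    return arrays


def _sums_of_squares(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    df_between = len(arrays) - 1
    df_within = all_x.size - len(arrays)
    return ssb, ssw, df_between, df_within


def one_way_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> StatsResult:
    """Independent-groups one-way ANOVA.

    F = MSB / MSW with MSB = SSB / (k - 1) and MSW = SSW / (N - k); the
    p-value is the upper tail of the F(k-1, N-k) distribution. If every
    observation is identical, F = 0 and p = 1 by convention.
    """
    arrays = _validate_groups(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return StatsResult(F=0.0, df_between=dfb, df_within=dfw, p=1.0, alpha=alpha)
        return StatsResult(F=math.inf, df_between=dfb, df_within=dfw, p=0.0, alpha=alpha)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return StatsResult(F=float(F), df_between=dfb, df_within=dfw, p=p, alpha=alpha)


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD with the Tukey–Kramer unequal-n correction.

    For groups a, b: q = |m_a - m_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)), and
    the adjusted p is the studentized-range upper tail with k groups and
    the ANOVA's within-group degrees of freedom.
    """
    arrays = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels must match the number of groups")
    _, ssw, _, dfw = _sums_of_squares(arrays)
    msw = ssw / dfw
    k = len(arrays)
    out: list[PairwiseComparison] = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = float(a.mean() - b.mean())
        if msw == 0.0:
            q = math.inf if diff != 0.0 else 0.0
            p_adj = 0.0 if diff != 0.0 else 1.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, dfw))
            p_adj = min(max(p_adj, 0.0), 1.0)
        out.append(
            PairwiseComparison(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                mean_diff=diff,
                q_stat=float(q),
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out
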