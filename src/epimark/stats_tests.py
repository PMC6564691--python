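"""Group-comparison statistics with exact small-sample behaviour.

The Mann-Whitney U test is the workhorse for comparing methylation
percentages between disease groups; small samples get the exact permutation
null (full enumeration of group labelings, mid-rank tie handling) and larger
ones the tie-corrected normal approximation with continuity correction.
Unpaired t-tests (Student or Welch) cover parameter comparisons between
strata.  ``progression_trend`` summarises an ordered series of groups
(e.g. gastritis → intestinal metaplasia → cancer) by medians, a monotonicity
flag and adjacent-pair Mann-Whitney tests.

Tests are two-sided by default and no multiplicity correction is applied;
the conventional significance threshold is α = 0.05 (reporting only).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, inf
from typing import Literal, Sequence

import numpy as np
from scipy import stats

ALPHA = 0.05
EXACT_MAX_N = 12  # full enumeration is C(12,6)=924 labelings at worst


@dataclass(frozen=True)
class GroupVector:
    label: str
    values: tuple[float, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.isfinite(vals).all():
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    mode_used: str
    significant: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    variant: str
    zero_variance: bool
    significant: bool


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + ½·#{x_i = y_j} over all pairs (mid-rank convention)."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of the permutation null.

    The null distribution of U under label exchange is symmetric about
    n_x·n_y/2 (relabelling maps U to n_x·n_y − U), so the two-sided p is the
    probability of a U at least as far from the centre as observed.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu)
    total = comb(nx + ny, nx)
    hits = 0
    idx = np.arange(nx + ny)
    for xs in combinations(idx, nx):
        mask = np.zeros(nx + ny, dtype=bool)
        mask[list(xs)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        # half-unit tolerance guards float equality of tied U values
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / total


def mann_whitney(
    x: GroupVector | Sequence[float],
    y: GroupVector | Sequence[float],
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates every labeling of the pooled sample (feasible for
    n_x + n_y ≤ 12); ``approx`` uses the normal approximation with
    tie-corrected variance and continuity correction; ``auto`` picks exact
    when feasible.  Ties contribute ½ to U in both modes.
    """
    xv = np.asarray(x.values if isinstance(x, GroupVector) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, GroupVector) else y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = "exact" if xv.size + yv.size <= EXACT_MAX_N else "approx"
    if mode == "exact":
        if xv.size + yv.size > EXACT_MAX_N:
            raise ValueError(
                f"exact enumeration infeasible for n={xv.size + yv.size} (> {EXACT_MAX_N})"
            )
        u, p = _exact_mw_p(xv, yv)
    elif mode == "approx":
        res = stats.mannwhitneyu(
            xv, yv, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = min(p, 1.0)
    return MannWhitneyResult(U=u, p=p, mode_used=mode, significant=p < ALPHA)


def ttest_unpaired(
    x: GroupVector | Sequence[float],
    y: GroupVector | Sequence[float],
    variant: Literal["student", "welch"] = "student",
) -> TTestResult:
    """Two-sided unpaired t-test, Student (pooled variance) or Welch."""
    xv = np.asarray(x.values if isinstance(x, GroupVector) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, GroupVector) else y, dtype=float)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("t-test needs at least 2 observations per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if xv.var(ddof=1) == 0 and yv.var(ddof=1) == 0:
        if xv.mean() == yv.mean():
            return TTestResult(0.0, 1.0, variant, zero_variance=True, significant=False)
        t = inf if xv.mean() > yv.mean() else -inf
        return TTestResult(t, 0.0, variant, zero_variance=True, significant=True)
    res = stats.ttest_ind(xv, yv, equal_var=(variant == "student"))
    t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t, p, variant, zero_variance=False, significant=p < ALPHA)


@dataclass(frozen=True)
class TrendResult:
    labels: tuple[str, ...]
    medians: tuple[float, ...]
    monotone: bool  # medians non-decreasing along the stated order
    strictly_increasing: bool
    pairwise: tuple[MannWhitneyResult, ...]  # adjacent pairs, in order


def progression_trend(
    groups: Sequence[GroupVector],
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> TrendResult:
    """Medians, monotonicity and adjacent-pair Mann-Whitney tests for ordered groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a trend")
    medians = tuple(g.median for g in groups)
    pairwise = tuple(
        mann_whitney(groups[i], groups[i + 1], mode=mode) for i in range(len(groups) - 1)
    )
    return TrendResult(
        labels=tuple(g.label for g in groups),
        medians=medians,
        monotone=all(a <= b for a, b in zip(medians, medians[1:])),
        strictly_increasing=all(a < b for a, b in zip(medians, medians[1:])),
        pairwise=pairwise,
    )


def groups_from_long(df, group_order: Sequence[str], value_col: str = "value",
                     group_col: str = "group") -> list[GroupVector]:
    """Build ordered GroupVectors from a long-format table (sample, group, value)."""
    out = []
    for label in group_order:
        vals = df.loc[df[group_col] == label, value_col].tolist()
        out.append(GroupVector(label, tuple(vals)))
    return out
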