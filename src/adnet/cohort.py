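"""Incidence and severity statistics for dissection cohorts.

Covers exact contingency-table tests (Fisher's 2x2 and its Freeman-Halton
r x 2 generalization, both by full enumeration in exact integer arithmetic),
lesion-length severity from per-segment aortic diameter profiles (a lesion is
any span whose diameter is at least 1.5x the segment's reference diameter),
and the group-comparison decision procedure used throughout the study:
parametric (one-way ANOVA + Bonferroni pairwise) when every group passes the
D'Agostino-Pearson normality test and Bartlett's variance test at alpha=0.05,
otherwise Kruskal-Wallis followed by Dunn's test with Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "SegmentProfile",
    "LesionRecord",
    "GroupCompareReport",
    "incidence",
    "fisher_2x2",
    "fisher_rx2",
    "lesion_length",
    "group_compare",
    "summarize",
]

LESION_DIAMETER_RATIO = 1.5  # dissection call: diameter >= 1.5x segment reference
RX2_ENUMERATION_GUARD = 200  # refuse exact r x 2 enumeration above this N


@dataclass(frozen=True)
class CohortTable:
    """AD+/AD- counts per ordered experimental group."""

    groups: tuple[str, ...]
    ad_pos: tuple[int, ...]
    ad_neg: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.ad_pos) == len(self.ad_neg)):
            raise ValueError("groups, ad_pos and ad_neg must have equal length")
        if any(x < 0 for x in self.ad_pos + self.ad_neg):
            raise ValueError("counts must be nonnegative integers")

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(p + n for p, n in zip(self.ad_pos, self.ad_neg))


@dataclass(frozen=True)
class SegmentProfile:
    """Diameter profile along one aortic segment, sampled at uniform spacing.

    ``diameters[i]`` is the diameter (mm) of the i-th interval of width
    ``spacing`` mm; ``reference_diameter`` is the healthy calibre of the
    segment.
    """

    name: str
    reference_diameter: float
    spacing: float
    diameters: np.ndarray

    def __post_init__(self) -> None:
        if self.reference_diameter <= 0:
            raise ValueError(f"segment {self.name}: reference diameter must be > 0")
        if self.spacing <= 0:
            raise ValueError(f"segment {self.name}: spacing must be > 0")
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size == 0 or np.any(d <= 0):
            raise ValueError(f"segment {self.name}: diameters must be positive")
        object.__setattr__(self, "diameters", d)


@dataclass(frozen=True)
class LesionRecord:
    """One animal's per-segment diameter profiles."""

    mouse_id: str
    group: str
    segments: list[SegmentProfile]


def incidence(table: CohortTable) -> dict[str, float]:
    """Percentage of AD+ animals per group, rounded to 1 decimal."""
    out = {}
    for g, pos, tot in zip(table.groups, table.ad_pos, table.totals):
        if tot == 0:
            raise ValueError(f"group {g!r} has zero animals")
        out[g] = round(100.0 * pos / tot, 1)
    return out


# ---------------------------------------------------------------------------
# Exact contingency tests
#
# Both tests use the probability-mass two-sided convention: p is the total
# (multivariate) hypergeometric probability of every table sharing the
# observed margins whose probability is <= that of the observed table.  All
# table probabilities share the denominator C(N, C1), so the "<= observed"
# comparison reduces to comparing integer numerators -- no floating-point tie
# tolerance is needed.


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    return fisher_rx2_counts([(a, b), (c, d)])


def fisher_rx2(table: CohortTable) -> float:
    """Two-sided Freeman-Halton exact p over all groups (r x 2 outcomes)."""
    return fisher_rx2_counts(list(zip(table.ad_pos, table.ad_neg)))


def fisher_rx2_counts(rows: list[tuple[int, int]]) -> float:
    """Exact two-sided p for an r x 2 table given as [(pos, neg), ...].

    Enumerates every table with the observed row and column margins; the
    probability mass of tables no more probable than the observed one is
    accumulated as an exact Fraction and converted to float at the end.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 groups")
    for r in rows:
        if len(r) != 2 or any(int(x) != x or x < 0 for x in r):
            raise ValueError("rows must be pairs of nonnegative integers")
    rows = [(int(p), int(n)) for p, n in rows]
    row_sums = [p + n for p, n in rows]
    c1 = sum(p for p, _ in rows)
    n_total = sum(row_sums)
    if n_total < 1:
        raise ValueError("table must contain at least one observation")
    if n_total > RX2_ENUMERATION_GUARD:
        raise ValueError(
            f"table too large for exact enumeration (N = {n_total} > "
            f"{RX2_ENUMERATION_GUARD})"
        )

    obs_num = math.prod(math.comb(n, p) for (p, _), n in zip(rows, row_sums))

    # Depth-first enumeration over the first-column entries a_i with margins
    # fixed; the running product of binomials is the table's numerator.
    tail_capacity = [0] * (len(rows) + 1)
    for i in range(len(rows) - 1, -1, -1):
        tail_capacity[i] = tail_capacity[i + 1] + row_sums[i]

    total = 0
    stack = [(0, c1, 1)]  # (row index, first-column mass left, partial numerator)
    while stack:
        i, rem, num = stack.pop()
        if i == len(rows):
            if rem == 0 and num <= obs_num:
                total += num
            continue
        lo = max(0, rem - tail_capacity[i + 1])
        hi = min(row_sums[i], rem)
        for a in range(lo, hi + 1):
            stack.append((i + 1, rem - a, num * math.comb(row_sums[i], a)))

    return float(Fraction(total, math.comb(n_total, c1)))


# ---------------------------------------------------------------------------
# Lesion severity


def lesion_length(record: LesionRecord) -> dict[str, float]:
    """Lesion length (mm) per segment and in total.

    A position counts as lesioned when its diameter is at least 1.5x the
    segment's reference diameter (inclusive); the lesion length of a segment
    is the summed width of lesioned intervals.
    """
    out: dict[str, float] = {}
    total = 0.0
    for seg in record.segments:
        hit = seg.diameters >= LESION_DIAMETER_RATIO * seg.reference_diameter
        length = float(hit.sum() * seg.spacing)
        out[seg.name] = length
        total += length
    out["total"] = total
    return out


# ---------------------------------------------------------------------------
# Group comparison decision procedure


@dataclass(frozen=True)
class GroupCompareReport:
    """Outcome of the normality-gated group comparison.

    ``path`` is "parametric" (ANOVA + pooled-variance pairwise t with
    Bonferroni) or "nonparametric" (Kruskal-Wallis + Dunn with Bonferroni).
    ``pairwise`` has one row per group pair with raw and adjusted p-values and
    a two-sided alpha=0.05 significance flag.
    """

    path: str
    normality_p: tuple[float, ...]
    bartlett_p: float
    omnibus_p: float
    pairwise: pd.DataFrame
    notes: tuple[str, ...] = ()


def _dunn_pairwise(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], z, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])


def _pooled_t_pairwise(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Pairwise t tests sharing the pooled within-group variance (ANOVA MSE)."""
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df = n_total - k
    mse = sum(((g.size - 1) * g.var(ddof=1) for g in groups)) / df
    rows = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se > 0:
            t = (groups[i].mean() - groups[j].mean()) / se
            p = 2.0 * stats.t.sf(abs(t), df)
        else:
            t, p = 0.0, 1.0
        rows.append((names[i], names[j], t, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])


def group_compare(
    groups: list[np.ndarray] | list[list[float]],
    names: list[str] | None = None,
    alpha: float = 0.05,
) -> GroupCompareReport:
    """Compare >= 2 groups with the normality-gated decision procedure.

    The parametric path (one-way ANOVA, then pairwise pooled-variance t tests
    with Bonferroni correction) is taken iff every group passes the
    D'Agostino-Pearson normality test and Bartlett's test for equal variances,
    both at alpha = 0.05.  Otherwise Kruskal-Wallis followed by Dunn's
    multiple-comparison test (Bonferroni-adjusted) is used.  Groups smaller
    than 8 observations cannot be normality-tested and route the whole
    comparison to the nonparametric path.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 3:
            raise ValueError(f"group {i} has fewer than 3 observations")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]

    notes: list[str] = []
    normality_p: list[float] = []
    all_normal = True
    for i, g in enumerate(arrays):
        if g.size < 8:
            normality_p.append(float("nan"))
            all_normal = False
            notes.append(
                f"{names[i]}: n = {g.size} < 8, normality untestable; "
                "routed to nonparametric path"
            )
        else:
            p = float(stats.normaltest(g).pvalue)
            normality_p.append(p)
            if p < alpha:
                all_normal = False

    if any(g.var(ddof=1) == 0 for g in arrays):
        bartlett_p = 0.0 if len({g.mean() for g in arrays}) > 1 else 1.0
        notes.append("zero-variance group: Bartlett's test degenerate")
    else:
        bartlett_p = float(stats.bartlett(*arrays).pvalue)

    parametric = all_normal and bartlett_p >= alpha
    if parametric:
        omnibus_p = float(stats.f_oneway(*arrays).pvalue)
        pairwise = _pooled_t_pairwise(arrays, names)
        path = "parametric"
    else:
        omnibus_p = float(stats.kruskal(*arrays).pvalue)
        pairwise = _dunn_pairwise(arrays, names)
        path = "nonparametric"

    m = len(pairwise)
    pairwise = pairwise.assign(
        p_adjusted=np.minimum(pairwise["p_value"] * m, 1.0),
    )
    pairwise["significant"] = pairwise["p_adjusted"] < alpha

    return GroupCompareReport(
        path=path,
        normality_p=tuple(normality_p),
        bartlett_p=bartlett_p,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        notes=tuple(notes),
    )


def summarize(values: np.ndarray | list[float]) -> tuple[float, float, int]:
    """Mean, standard error of the mean (SD/sqrt(n)) and n."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size)), int(v.size)
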