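"""Selection of condition-responsive genes.

A gene is responsive in a two-group contrast when its two-sample t-test on
log2 intensities gives p < 0.01 and the linear fold change exceeds 4 or falls
below 0.25 (both gates strict).  The default per-gene test pools the group
variances (exact under homoscedastic log-normal noise and calibrated at the
3-4 replicates typical of these designs); Welch's unequal-variance test is
available for heteroscedastic data.  The network's node universe is the
de-duplicated union of responsive genes over all contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Contrast", "DEGConfig", "welch_t", "fold_change", "select_genes",
           "contrast_from_conditions"]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison given by explicit sample IDs."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.name!r}: each group needs >= 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: groups overlap")


def contrast_from_conditions(
    sheet: pd.Series, condition_a: str, condition_b: str, name: str | None = None
) -> Contrast:
    """Build a contrast from condition labels in a sample sheet."""
    a = tuple(sheet.index[sheet == condition_a])
    b = tuple(sheet.index[sheet == condition_b])
    if not a or not b:
        missing = condition_a if not a else condition_b
        raise ValueError(f"condition {missing!r} has no samples in the sheet")
    return Contrast(name or f"{condition_a}_vs_{condition_b}", a, b)


@dataclass(frozen=True)
class DEGConfig:
    """Selection gates and the per-gene test.

    ``test`` is "student" (pooled-variance two-sample t; exact under the
    homoscedastic noise model and calibrated at small n) or "welch"
    (unequal-variance; conservative below ~8 replicates).
    """

    p_threshold: float = 0.01
    fc_upper: float = 4.0
    fc_lower: float = 0.25
    test: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not self.fc_lower < 1 < self.fc_upper:
            raise ValueError("need fc_lower < 1 < fc_upper")
        if self.test not in ("student", "welch"):
            raise ValueError("test must be 'student' or 'welch'")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t test on log2 values.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Degenerate inputs with
    zero variance in both groups give p = 1 when the means agree and p = 0
    (t = +/-inf, df = n1 + n2 - 2 by convention) when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0

    sem2 = vx / x.size + vy / y.size
    t = float((x.mean() - y.mean()) / np.sqrt(sem2))
    df = float(
        sem2**2
        / (vx**2 / (x.size**2 * (x.size - 1)) + vy**2 / (y.size**2 * (y.size - 1)))
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def fold_change(mean_a_log2: float, mean_b_log2: float) -> float:
    """Linear fold change 2^(mean_a - mean_b) between log2 group means."""
    return float(2.0 ** (mean_a_log2 - mean_b_log2))


def _t_test_vectorized(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Per-row two-sample p-values for gene x sample blocks.

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    agree and p = 0 otherwise.
    """
    na, nb = a.shape[1], b.shape[1]
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    if method == "welch":
        sem2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = sem2**2 / (
                va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1))
            )
    else:  # pooled Student
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        sem2 = pooled * (1.0 / na + 1.0 / nb)
        df = np.full(a.shape[0], float(na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sem2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sem2 == 0
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return p


def select_genes(
    expr: pd.DataFrame,
    sheet: pd.Series,
    contrasts: list[Contrast],
    cfg: DEGConfig = DEGConfig(),
) -> tuple[set[str], pd.DataFrame]:
    """Apply the p/fold-change rule per contrast and union the survivors.

    Returns the non-redundant selected gene set and a long-format table with
    one row per gene per contrast (mean_a, mean_b, fold_change, p_value,
    selected).
    """
    for contrast in contrasts:
        unknown = [
            s for s in contrast.group_a + contrast.group_b if s not in expr.columns
        ]
        if unknown:
            raise ValueError(f"contrast {contrast.name!r}: unknown samples {unknown}")

    frames = []
    selected: set[str] = set()
    for contrast in contrasts:
        a = expr.loc[:, list(contrast.group_a)].to_numpy()
        b = expr.loc[:, list(contrast.group_b)].to_numpy()
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        fc = 2.0 ** (mean_a - mean_b)
        p = _t_test_vectorized(a, b, cfg.test)
        sel = (p < cfg.p_threshold) & ((fc > cfg.fc_upper) | (fc < cfg.fc_lower))
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "contrast": contrast.name,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "fold_change": fc,
                    "p_value": p,
                    "selected": sel,
                }
            )
        )
        selected.update(expr.index[sel])
    table = pd.concat(frames, ignore_index=True)
    return selected, table
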