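"""Synthetic expression and cohort data with planted ground truth.

The expression generator emulates a multi-condition microarray experiment on
mouse aortic tissue: a few co-regulated gene modules shift together (in log2
units) in some conditions, everything else is flat, and i.i.d. Gaussian
measurement noise sits on top.  The cohort generator emulates an animal study
in which each mouse is scored dissection-positive (AD+) or negative and AD+
animals carry a contiguous dilated lesion whose diameter exceeds 1.5x the
segment reference.

Because every signal is planted, downstream stages (gene selection, network
learning, community detection, activation calls, enrichment, incidence and
severity statistics) can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, LesionRecord, SegmentProfile

__all__ = [
    "SynthExprConfig",
    "SynthCohortConfig",
    "DEFAULT_EXPR_CONFIG",
    "DEFAULT_COHORT_CONFIG",
    "generate_expression",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SynthExprConfig:
    """Parameters of the planted-module expression simulator.

    ``effect_matrix[m][c]`` is the log2-unit shift applied to every gene of
    module ``m`` in condition ``c``; background genes sit at ``baseline_mean``
    everywhere.  Defaults encode three 80-gene modules among 2,000 genes and
    four treatment conditions, with module responses chosen so that the
    rapamycin contrast (BA+Rapa vs BA) reverses module 1, leaves module 2
    unchanged and further activates module 3.  Module 3 also responds to
    rapamycin alone, so the three modules carry distinct condition
    signatures (as distinct subnetworks in real data do).
    """

    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (80, 80, 80)
    #                 DMSO  BA   Rapa BA+Rapa
    effect_matrix: tuple[tuple[float, ...], ...] = (
        (0.0, 3.0, 0.0, 0.0),
        (0.0, 3.0, 0.0, 3.0),
        (0.0, 3.0, 2.0, 5.0),
    )
    condition_names: tuple[str, ...] = ("DMSO", "BA", "Rapa", "BA+Rapa")
    baseline_mean: float = 8.0
    noise_sd: float = 0.4
    replicates_per_condition: int = 4
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError(
                f"module_sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        if self.replicates_per_condition < 2:
            raise ConfigError("replicates_per_condition must be >= 2")
        if len(self.effect_matrix) != len(self.module_sizes):
            raise ConfigError("effect_matrix needs one row per module")
        for row in self.effect_matrix:
            if len(row) != len(self.condition_names):
                raise ConfigError("each effect_matrix row needs one entry per condition")


DEFAULT_EXPR_CONFIG = SynthExprConfig()


def generate_expression(
    config: SynthExprConfig = DEFAULT_EXPR_CONFIG,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a log2 expression matrix with planted co-regulated modules.

    Returns
    -------
    expr : DataFrame, genes x samples
        Log2 intensities.  Sample IDs are ``<condition>_<replicate>``.
    sheet : Series, sample id -> condition label
    modules : Series, gene id -> module index (0 = background)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cond = len(config.condition_names)
    reps = config.replicates_per_condition
    samples = [
        f"{cond}_{r + 1}" for cond in config.condition_names for r in range(reps)
    ]
    conditions = np.repeat(np.arange(n_cond), reps)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    assignment = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        assignment[start : start + size] = m
        start += size

    effects = np.asarray(config.effect_matrix, dtype=float)  # modules x conditions
    mean = np.full((config.n_genes, len(samples)), config.baseline_mean)
    for m in range(len(config.module_sizes)):
        rows = assignment == m + 1
        mean[rows] += effects[m, conditions]

    data = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    sheet = pd.Series(
        [config.condition_names[c] for c in conditions],
        index=pd.Index(samples, name="sample"),
        name="condition",
    )
    modules = pd.Series(assignment, index=expr.index, name="module")
    return expr, sheet, modules


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class SynthCohortConfig:
    """Parameters of the animal-cohort simulator.

    Each animal is AD+ with its group's Bernoulli probability; AD+ animals
    receive a lesion length drawn from a Gamma distribution with the group's
    mean/sd (mm) and a per-segment diameter profile realizing that lesion at
    1.6x the reference diameter (AD- animals stay below the 1.5x threshold
    everywhere).  Defaults mirror a therapeutic-intervention design: day-7
    baseline with 48.1% incidence and 4.11 mm mean lesion, day-14 vehicle at
    100% / 8.53 mm and day-14 rapamycin at 69.2% / 3.84 mm; SDs are the
    printed SEMs scaled by sqrt(n).
    """

    group_names: tuple[str, ...] = ("BA+DMSO_day7", "BA+DMSO_day14", "BA+Rapa_day14")
    group_sizes: tuple[int, ...] = (27, 10, 13)
    incidence_probs: tuple[float, ...] = (0.481, 1.0, 0.692)
    lesion_mean: tuple[float, ...] = (4.11, 8.53, 3.84)
    lesion_sd: tuple[float, ...] = (6.50, 5.57, 5.59)
    segment_names: tuple[str, ...] = ("arch", "thoracic", "suprarenal", "infrarenal")
    reference_diameters: tuple[float, ...] = (1.2, 1.0, 0.9, 0.8)
    segment_length_mm: float = 10.0
    spacing_mm: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        n = len(self.group_names)
        for name, vals in (
            ("group_sizes", self.group_sizes),
            ("incidence_probs", self.incidence_probs),
            ("lesion_mean", self.lesion_mean),
            ("lesion_sd", self.lesion_sd),
        ):
            if len(vals) != n:
                raise ConfigError(f"{name} needs one entry per group")
        if any(not 0.0 <= p <= 1.0 for p in self.incidence_probs):
            raise ConfigError("incidence_probs must lie in [0, 1]")
        if any(s < 1 for s in self.group_sizes):
            raise ConfigError("group_sizes must be >= 1")
        if any(m < 0 for m in self.lesion_mean) or any(s < 0 for s in self.lesion_sd):
            raise ConfigError("lesion parameters must be nonnegative")
        if len(self.reference_diameters) != len(self.segment_names):
            raise ConfigError("reference_diameters needs one entry per segment")


DEFAULT_COHORT_CONFIG = SynthCohortConfig()


def _lesion_profile(
    rng: np.ndarray, config: SynthCohortConfig, lesion_mm: float
) -> list[SegmentProfile]:
    """Diameter profiles realizing a total lesion of ``lesion_mm`` mm.

    The lesion is laid down contiguously starting in a random segment at a
    random offset, dilated to 1.6x reference; healthy positions jitter around
    1.0x reference, capped safely below the 1.5x call threshold.
    """
    n_pts = int(round(config.segment_length_mm / config.spacing_mm))
    total_pts = n_pts * len(config.segment_names)
    lesion_pts = min(int(round(lesion_mm / config.spacing_mm)), total_pts)

    healthy = rng.uniform(0.92, 1.08, size=total_pts)
    diam_factor = np.minimum(healthy, 1.45)
    if lesion_pts > 0:
        start = rng.integers(0, total_pts - lesion_pts + 1)
        diam_factor[start : start + lesion_pts] = 1.6

    profiles = []
    for s, (name, ref) in enumerate(
        zip(config.segment_names, config.reference_diameters)
    ):
        factors = diam_factor[s * n_pts : (s + 1) * n_pts]
        profiles.append(
            SegmentProfile(
                name=name,
                reference_diameter=ref,
                spacing=config.spacing_mm,
                diameters=factors * ref,
            )
        )
    return profiles


def generate_cohort(
    config: SynthCohortConfig = DEFAULT_COHORT_CONFIG,
) -> tuple[CohortTable, list[LesionRecord]]:
    """Simulate AD+/AD- outcomes and per-segment diameter profiles.

    Lesion lengths of AD+ animals follow a Gamma distribution parameterized by
    the group mean/sd (a point mass at the mean when sd = 0); AD- animals get
    healthy profiles with zero lesion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ad_pos: list[int] = []
    ad_neg: list[int] = []
    records: list[LesionRecord] = []
    for g, group in enumerate(config.group_names):
        size = config.group_sizes[g]
        status = rng.random(size) < config.incidence_probs[g]
        ad_pos.append(int(status.sum()))
        ad_neg.append(int(size - status.sum()))
        for i in range(size):
            if status[i]:
                m, s = config.lesion_mean[g], config.lesion_sd[g]
                if s == 0 or m == 0:
                    lesion = m
                else:
                    shape = (m / s) ** 2
                    lesion = float(rng.gamma(shape, m / shape))
                lesion = max(lesion, config.spacing_mm)  # AD+ implies a visible lesion
            else:
                lesion = 0.0
            records.append(
                LesionRecord(
                    mouse_id=f"{group}_m{i + 1:03d}",
                    group=group,
                    segments=_lesion_profile(rng, config, lesion),
                )
            )

    table = CohortTable(
        groups=tuple(config.group_names),
        ad_pos=tuple(ad_pos),
        ad_neg=tuple(ad_neg),
    )
    return table, records
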