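"""Incidence and severity statistics on dissection cohorts.

Re-analyzes the published preventive cohort counts (vehicle / gefitinib /
rapamycin) with the exact tests, then simulates a therapeutic cohort and runs
the lesion-length severity comparison with the normality-gated decision
procedure.
"""

import numpy as np

from adnet import (
    CohortTable,
    SynthCohortConfig,
    fisher_2x2,
    fisher_rx2,
    generate_cohort,
    group_compare,
    incidence,
    lesion_length,
    summarize,
)

# Preventive cohort: AD+/AD- counts per treatment group.
preventive = CohortTable(("BA+DMSO", "BA+Gef", "BA+Rapa"), (11, 9, 2), (3, 0, 6))
print("incidence (%):", incidence(preventive))
print(f"3x2 exact test (Freeman-Halton): p = {fisher_rx2(preventive):.4f}")
print(f"vehicle vs rapamycin 2x2: p = {fisher_2x2(11, 3, 2, 6):.4f}")
print(
    "Rapamycin cuts incidence from 78.6% to 25.0%; the three-group exact "
    "test is significant below 0.01.\n"
)

# Simulated therapeutic cohort with the published incidence/severity profile.
table, records = generate_cohort(SynthCohortConfig(seed=1))
print("simulated cohort incidence (%):", incidence(table))
lengths = {}
for rec in records:
    total = lesion_length(rec)["total"]
    if total > 0:
        lengths.setdefault(rec.group, []).append(total)
for group, vals in lengths.items():
    mean, sem, n = summarize(vals)
    print(f"  {group}: lesion length {mean:.2f} +/- {sem:.2f} mm (n = {n})")

report = group_compare(
    [np.array(v) for v in lengths.values()], names=list(lengths)
)
print(f"decision path: {report.path} (omnibus p = {report.omnibus_p:.3g})")
print(report.pairwise.to_string(index=False))
print(
    "Lesion length sums every aortic span whose diameter reaches 1.5x the "
    "segment reference; groups are compared by ANOVA+Bonferroni only when "
    "all pass normality and variance checks, else Kruskal-Wallis + Dunn."
)
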