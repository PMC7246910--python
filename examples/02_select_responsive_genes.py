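"""Select condition-responsive genes with the p < 0.01 and |FC| > 4 rule.

The selected set (the union over contrasts, de-duplicated) is the node
universe for network learning.  With the default fixture nearly all planted
module genes pass and essentially no background gene does.
"""

from adnet import (
    DEGConfig,
    SynthExprConfig,
    contrast_from_conditions,
    generate_expression,
    select_genes,
)

expr, sheet, modules = generate_expression(SynthExprConfig(seed=1))
contrasts = [
    contrast_from_conditions(sheet, "BA", "DMSO"),
    contrast_from_conditions(sheet, "Rapa", "DMSO"),
    contrast_from_conditions(sheet, "BA+Rapa", "BA", "Rapa_effect"),
]
selected, table = select_genes(expr, sheet, contrasts, DEGConfig())

module_genes = set(modules.index[modules > 0])
print(f"selected {len(selected)} of {expr.shape[0]} genes")
print(f"planted module genes recovered: {len(selected & module_genes)}"
      f" / {len(module_genes)}")
print(f"background genes selected: {len(selected - module_genes)}")
per_contrast = table[table.selected].groupby("contrast")["gene"].count()
print(f"selections per contrast:\n{per_contrast.to_string()}")
print(
    "A gene needs p below 0.01 AND a fold change beyond 4x (either "
    "direction) in at least one contrast; the strict double gate keeps the "
    "false-selection rate among 1,760 background genes near zero."
)
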