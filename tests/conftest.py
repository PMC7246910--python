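import dataclasses

import pytest

from adnet.synth import (
    SynthExprConfig,
    generate_expression,
)

# A scaled-down planted fixture: same module/condition design as the default,
# fewer genes, so unit tests stay fast.
SMALL_CONFIG = dataclasses.replace(
    SynthExprConfig(),
    n_genes=300,
    module_sizes=(30, 30, 30),
    seed=42,
)


@pytest.fixture(scope="session")
def small_fixture():
    expr, sheet, modules = generate_expression(SMALL_CONFIG)
    return expr, sheet, modules


@pytest.fixture(scope="session")
def small_pipeline(small_fixture):
    """DE selection + learned network on the small fixture (shared: slow)."""
    from adnet.diffexpr import contrast_from_conditions, select_genes
    from adnet.network import BNConfig, coupling_matrix, learn_structure

    expr, sheet, modules = small_fixture
    contrasts = [
        contrast_from_conditions(sheet, "BA", "DMSO"),
        contrast_from_conditions(sheet, "Rapa", "DMSO"),
        contrast_from_conditions(sheet, "BA+Rapa", "BA", "Rapa_effect"),
    ]
    selected, table = select_genes(expr, sheet, contrasts)
    coup = coupling_matrix(expr, selected)
    net = learn_structure(expr, selected, coup, BNConfig(seed=5, n_restarts=3))
    return expr, sheet, modules, contrasts, selected, coup, net
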