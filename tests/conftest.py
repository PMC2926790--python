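import numpy as np
import pandas as pd
import pytest

import xskew as xs


@pytest.fixture(scope="session")
def default_table():
    """One paper-scale PWD-AKR simulation, shared read-only across tests."""
    return xs.simulate_dataset(xs.default_params("PWD-AKR"), np.random.default_rng(12345))


@pytest.fixture(scope="session")
def default_fit(default_table):
    return xs.fit_nested_anova(default_table)


@pytest.fixture
def tiny_params():
    """A minimal 3-gene design, cheap enough for loops."""
    genes = [
        xs.GeneParams("g_inact_a", "inactivated", eqtl_ratio=0.5),
        xs.GeneParams("g_inact_b", "inactivated", eqtl_ratio=0.6),
        xs.GeneParams("g_auto", "autosomal", eqtl_ratio=0.5),
    ]
    return xs.SimulationParams(
        genes=genes,
        n_females_per_cross=6,
        litters_per_cross=(2, 2),
        include_males=False,
    )


def make_toy_frame(values_by_cell):
    """Observation frame for anova internals from {(gene, cross, ind): [values]}."""
    rows = []
    for (g, c, i), vals in values_by_cell.items():
        for v in vals:
            rows.append({"gene": g, "mother": c, "individual": f"{c}:{i}", "y": float(v)})
    return pd.DataFrame(rows)
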