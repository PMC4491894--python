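import numpy as np
import pandas as pd
import pytest

from rpewound import SimulationConfig

ZERO_EFFECT = {c: 0.0 for c in ("rpe", "wound", "cell_cycle", "housekeeping", "null")}


@pytest.fixture
def small_config():
    """Desk-size simulation: full study structure, few genes."""
    return SimulationConfig(n_genes=300, n_negctrl_probes=40,
                            n_replicate_probes=20, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def donor_matrix(values, genes=None, donors=("D1", "D2", "D3")):
    """Genes x donors frame from a nested list."""
    values = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=list(donors)[:values.shape[1]])
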