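import numpy as np
import pandas as pd
import pytest

from synletscreen import simulate


@pytest.fixture
def tiny_spec():
    """Two-compound, four-cell-line noise-free screen spec."""
    return simulate.ScreenSpec(
        seed=11,
        sigma=0.0,
        compounds=("AZD1390", "KU60019"),
    )


@pytest.fixture
def small_long_table():
    """Minimal raw two-well table: one vehicle (1000) + one treated (500) well."""
    return pd.DataFrame(
        {
            "cell_line": ["L1", "L1"],
            "genotype": ["deficient", "deficient"],
            "compound_a": ["A", "A"],
            "compound_b": ["none", "none"],
            "conc_a": [0.0, 1.0],
            "conc_b": [0.0, 0.0],
            "replicate": [1, 1],
            "value": [1000.0, 500.0],
            "value_kind": ["raw", "raw"],
        }
    )


def random_matrix(rng, n=6):
    """A random (but structurally valid) normalized combination matrix."""
    from synletscreen.screen_model import CombinationMatrix

    conc = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 10.0, n - 1))])
    conc_b = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 10.0, n - 1))])
    viability = rng.uniform(0.0, 1.0, (n, n))
    viability[0, 0] = 1.0
    return CombinationMatrix(
        conc_a=conc,
        conc_b=conc_b,
        viability=viability,
        cell_line="L1",
        genotype="deficient",
        compound_a="A",
        compound_b="B",
        replicate=1,
    )
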