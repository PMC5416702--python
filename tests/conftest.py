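import numpy as np
import pytest

from epiloci import simcohort as sc


@pytest.fixture(scope="session")
def null_tables_small():
    """Two-subpopulation null cohort, m=40, n=200+200, Fst=0.05."""
    spec = sc.AncestralSpec.uniform(40, 2, 100, 100, fst=0.05, seed=42)
    return sc.simulate_tables(spec, sc.truth_null(), seed=42)


@pytest.fixture(scope="session")
def epistatic_tables_small():
    """One-subpopulation cohort with 2 planted marginal-matched pairs, m=30."""
    spec = sc.AncestralSpec.uniform(30, 1, 300, 300, fst=0.0, seed=7)
    truth = sc.truth_epistatic([0, 1, 2, 3], [0.3, 0.3, 0.25, 0.35], 1.5, seed=7)
    return sc.simulate_tables(spec, truth, seed=7), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
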