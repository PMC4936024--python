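import numpy as np
import pytest

import paleorates as pr


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with simple ages: tips at 0, cherries at 5, root at 10."""
    t = pr.parse_newick("((A,B),(C,D));")
    ages = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0}
    for leaf in t.leaves:
        leaf.age = ages[leaf.label]
    for node in t.postorder():
        if not node.is_leaf:
            node.age = max(c.age for c in node.children) + 5.0
    return t


@pytest.fixture(scope="session")
def record():
    """One synthetic fossil record used across the suite (fixed seed)."""
    cfg = pr.SimulationConfig(seed=1234)
    rec = pr.simulate_fossil_record(cfg)
    return cfg, rec


@pytest.fixture(scope="session")
def record_with_matrix(record):
    cfg, rec = record
    matrix, truth = pr.simulate_characters(
        rec.observed_tree, cfg, np.random.default_rng(77))
    return cfg, rec, matrix, truth
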