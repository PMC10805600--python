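import pytest

import claderich as cr


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the smallest interesting ultrametric tree."""
    return cr.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_ladder():
    return cr.parse_newick("(((A:1,B:1):1,C:2):3,D:5);")


@pytest.fixture
def polytomy_tree():
    return cr.parse_newick("((A:1,B:1,C:1):1,D:2);")


@pytest.fixture(scope="session")
def small_forest():
    """10-clade age_driven forest with its truth table (session-cached)."""
    cfg = cr.ScenarioConfig.from_preset("age_driven", seed=101, n_clades=10)
    return cr.simulate_clade_forest(cfg)


@pytest.fixture(scope="session")
def medium_forest():
    """40-clade forest large enough for replicated 50-clade sampling."""
    cfg = cr.ScenarioConfig.from_preset("age_driven", seed=202, n_clades=40)
    return cr.simulate_clade_forest(cfg)
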