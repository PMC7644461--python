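import numpy as np
import pandas as pd
import pytest

import planktonet as pk

#: Reduced community used throughout the tests: same six compartments as the
#: full 110-taxon catalogue but small enough for fast network construction.
SMALL_COUNTS = {
    "virus": 1,
    "bacteria": 2,
    "phytoplankton": 12,
    "HF": 2,
    "naked_ciliate": 6,
    "tintinnid": 6,
}


@pytest.fixture(scope="session")
def small_taxa() -> pd.DataFrame:
    return pk.generate_taxa(group_counts=SMALL_COUNTS, seed=11)


@pytest.fixture(scope="session")
def small_campaign(small_taxa):
    """A 25-week synthetic campaign whose fluorescence carries two bloom
    windows close enough to pool, leaving one pooled bloom flanked by two
    analysable non-bloom periods."""
    plan = pk.default_interaction_plan(small_taxa, n_positive=4, n_negative=4, seed=7)
    abundance = pk.generate_abundances(
        small_taxa, n_weeks=25, plan=plan, seed=7, start_date="2015-01-01"
    )
    fluo = pk.generate_fluorescence(
        175, bloom_windows=[(36, 70), (85, 120)], seed=7, noise_sd=0.0,
        start_date="2015-01-01",
    )
    return {"taxa": small_taxa, "plan": plan, "abundance": abundance, "fluorescence": fluo}


@pytest.fixture()
def toy_network():
    """Hand-built 5-edge negative network on 6 nodes with 3 labels."""
    edges = pd.DataFrame(
        [
            (1, 2, -0.9, 0.01, "-"),
            (1, 3, -0.8, 0.01, "-"),
            (2, 3, -0.7, 0.02, "-"),
            (3, 4, -0.6, 0.02, "-"),
            (5, 6, -0.5, 0.03, "-"),
        ],
        columns=["taxon_a", "taxon_b", "rho", "p", "sign"],
    )
    net = pk.CorrelationNetwork("toy", "negative", edges, alpha=0.05, n_permutations=99)
    labels = {1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "C"}
    return net, labels
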