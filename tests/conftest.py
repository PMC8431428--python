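import pandas as pd
import pytest

from triadex import simulate
from triadex.pipeline import triad_calls, triad_roles


@pytest.fixture(scope="session")
def small_bundle():
    """A modest planted triad bundle shared across read-only tests."""
    cfg = simulate.SimConfig(n_genes=600, time_points=1, seed=11)
    counts, samples, truth = simulate.simulate_triad_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    """Triad relation + DEG calls for the shared bundle."""
    _, counts, samples, truth = small_bundle
    roles = triad_roles(samples, "FO")
    calls, tables = triad_calls(counts, samples, roles, "T1")
    return calls, tables, truth


MODE_TO_CATEGORY = {
    "additive": "additive",
    "eldF": "ELD-F",
    "eldM": "ELD-M",
    "od_down": "down-overdominant",
    "od_up": "up-overdominant",
    "conserved": "conserved",
}


@pytest.fixture(scope="session")
def mode_to_category():
    return dict(MODE_TO_CATEGORY)
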