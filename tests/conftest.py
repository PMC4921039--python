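import warnings

import numpy as np
import pandas as pd
import pytest

import canegwas as cg


@pytest.fixture(autouse=True)
def _quiet():
    # REML boundary warnings and QC flags are expected in simulations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_markers():
    """Hand-built 6-genotype x 5-marker matrix with one missing call."""
    calls = pd.DataFrame(
        {
            "M1": [1, 1, 1, 1, 1, 1],
            "M2": [1, 1, 1, 0, np.nan, 0],
            "M3": [0, 0, 0, 1, 1, 1],
            "M4": [1, 0, 1, 0, 1, 0],
            "M5": [1, 0, 1, 0, 1, 0],
        },
        index=[f"g{i}" for i in range(6)],
        dtype=float,
    )
    meta = pd.DataFrame({"linkage_group": ["LG1", "LG1", "LG2", "LG2", None]},
                        index=calls.columns)
    return cg.MarkerMatrix(calls, meta)


@pytest.fixture(scope="session")
def default_panel():
    """Study-scale synthetic panel: markers, truth and trial phenotypes."""
    cfg = cg.SimConfig(seed=11)
    markers, truth = cg.simulate_population(cfg)
    phenos = cg.simulate_trials(markers, truth, cfg)
    return cfg, markers, truth, phenos


@pytest.fixture(scope="session")
def default_blues(default_panel):
    _, _, _, phenos = default_panel
    return cg.compute_blue_table(phenos)
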