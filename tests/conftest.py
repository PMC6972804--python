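import numpy as np
import pandas as pd
import pytest

import gardenclim as gc


@pytest.fixture(scope="session")
def dataset1():
    """A simulated heritability data set (4 pops x 10 fams x 12 reps,
    6 blocks) with a known h^2 = 0.20 trait."""
    cfg = gc.dataset1_config(traits={"WD": gc.trait_model_for_h2(0.20)})
    return gc.simulate_plantation(cfg, seed=1)


@pytest.fixture(scope="session")
def dataset2():
    """A simulated modelling data set (12 pops x 10 fams x 4 reps) with
    two genetically correlated traits driven by climate."""
    traits = {
        "WD": gc.trait_model_for_h2(0.15, climate_slopes={"P_MA": 1.2}),
        "N_CONC": gc.trait_model_for_h2(0.22, climate_slopes={"T_MA": -1.0}),
    }
    corr = np.array([[1.0, -0.6], [-0.6, 1.0]])
    cfg = gc.dataset2_config(traits=traits, genetic_corr=corr,
                             residual_corr=np.eye(2))
    return gc.simulate_plantation(cfg, seed=23)


@pytest.fixture(scope="session")
def climate12():
    return gc.default_population_climate(12)
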