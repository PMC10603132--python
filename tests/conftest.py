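import numpy as np
import pandas as pd
import pytest

import firelink as fl


@pytest.fixture(scope="session")
def standard_vars():
    """The eleven-variable panel: BA plus ten precursors."""
    return dict(fl.STANDARD_VARIABLES)


@pytest.fixture(scope="session")
def three_var_spec():
    """Tiny scenario with one planted link X -> BA at lag 2, coef 0.6."""
    return fl.ScenarioSpec(
        variables={"BA": "target", "X": "top-down", "S": "bottom-up"},
        links=[fl.PlantedLink("X", "BA", 2, 0.6)],
        n_weeks=2000,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_links(rows):
    """Link table helper: rows of (source, lag, rho)."""
    return pd.DataFrame(rows, columns=["source", "lag", "rho"])


@pytest.fixture(scope="session")
def small_scene():
    """A 2-ecoregion scene with opposite planted dominance, noise-free
    pixels, shared by scene-level tests."""
    variables = dict(fl.STANDARD_VARIABLES)
    mk = lambda links, seed: fl.ScenarioSpec(
        variables=variables, links=links, n_weeks=260, seed=seed, tau_max=10
    )
    climate = np.array([["A", "A"], ["B", "B"]])
    vegetation = np.array([["grassland", "grassland"], ["TBE", "TBE"]])
    scenarios = {
        "A|grassland": mk([fl.PlantedLink("ET0", "BA", 1, 0.7)], 1),
        "B|TBE": mk([fl.PlantedLink("SWDI", "BA", 4, 0.7)], 2),
    }
    return fl.SceneSpec(
        shape=(2, 2),
        climate_code=climate,
        vegetation_code=vegetation,
        scenarios=scenarios,
        pixel_noise_sd=0.0,
        seed=5,
    )
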