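import numpy as np
import pandas as pd
import pytest

import occuwatch as ow


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete simulation: 40 sites, 3 years, 20 days."""
    return ow.SimulationConfig(
        n_sites=40, n_years=3, days_per_deployment=20, beta_year=(0.1, 0.2), seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ow.simulate_dataset(small_config)


@pytest.fixture()
def toy_sites():
    """Two-site table, one per area."""
    return ow.SiteTable.from_frame(
        pd.DataFrame(
            {
                "site_id": ["A1", "B1"],
                "area": ["BB", "NAD"],
                "baited": [True, False],
                "tree_cover": [1, 2],
                "shrub_cover": [0, 3],
                "ground_cover": [2, 1],
                "woody_debris": [0, 0],
                "rocks": [1, 1],
                "leaf_litter": [2, 2],
                "moisture": [0, 1],
            }
        )
    )


def make_dataset(histories, seasons=("2015",)):
    """Build a DetectionDataset from {(species, site, season): list} mappings."""
    return ow.DetectionDataset(
        tuple(seasons),
        {k: np.asarray(v, dtype=float) for k, v in histories.items()},
    )


@pytest.fixture()
def make_ds():
    return make_dataset


def draws_from_chains(chains, columns=("intercept",)):
    """Wrap raw chain arrays as PosteriorDraws (burn-in = half, no sampling)."""
    chains = np.asarray(chains, dtype=float)
    return ow.PosteriorDraws(
        chains=chains,
        burn_in=chains.shape[1] // 2,
        columns=tuple(columns),
        variant=ow.DetectionModel.NULL,
        prior=ow.PriorSpec(),
        seed=0,
        acceptance=np.full((chains.shape[0], chains.shape[2]), 0.3),
    )
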