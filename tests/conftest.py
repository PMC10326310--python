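import numpy as np
import pytest

from sdmpanel.panel_model import SDMSpec
from sdmpanel.synthetic import (
    DGPConfig,
    generate_covariates,
    generate_map,
    generate_outcome,
)
from sdmpanel.weights import contiguity_from_adjacency, row_standardize


RING4_PAIRS = [(1, 2), (2, 3), (3, 4), (4, 1)]


@pytest.fixture(scope="session")
def ring4():
    """Binary contiguity ring over 4 units."""
    return contiguity_from_adjacency(RING4_PAIRS, (1, 2, 3, 4))


@pytest.fixture(scope="session")
def ring4_std(ring4):
    return row_standardize(ring4)


@pytest.fixture(scope="session")
def map30():
    """One fixed synthetic map shared across simulation tests."""
    coords, adjacency, partition = generate_map(30, seed=42)
    W = row_standardize(
        contiguity_from_adjacency(adjacency, tuple(coords.index)))
    return {"coords": coords, "adjacency": adjacency,
            "partition": partition, "W": W}


def simulate_panel(W, config: DGPConfig, seed: int, partition=None,
                   **outcome_kwargs):
    """One panel replicate on a fixed map: child seeds for covariates/outcome."""
    s1, s2 = (int(s.generate_state(1)[0] % 2**31)
              for s in np.random.SeedSequence(seed).spawn(2))
    cov = generate_covariates(config, seed=s1)
    return generate_outcome(cov, W, config, seed=s2, partition=partition,
                            **outcome_kwargs)


@pytest.fixture(scope="session")
def default_config():
    return DGPConfig(rho=-0.5)


@pytest.fixture(scope="session")
def fitted_sdm(map30, default_config):
    """One SDM FE fit on one default synthetic panel (shared, read-only)."""
    from sdmpanel.panel_model import fit_spatial_panel

    panel = simulate_panel(map30["W"], default_config, seed=2024)
    spec = SDMSpec("FME", default_config.covariates, map30["W"])
    return fit_spatial_panel(panel, spec), panel, spec
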