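import numpy as np
import pytest

from veasl import (
    ArteryGeometry,
    LabellingParams,
    ModulationModel,
    SimulationConfig,
    four_artery_scheme,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def corner_arteries() -> ArteryGeometry:
    """Four arteries planned at the corners of the +-10 mm square."""
    return ArteryGeometry(
        names=["RICA", "RVA", "LICA", "LVA"],
        planned=[[10.0, 10.0], [10.0, -10.0], [-10.0, 10.0], [-10.0, -10.0]],
    )


@pytest.fixture(scope="session")
def scheme6():
    return four_artery_scheme(6)


@pytest.fixture(scope="session")
def scheme8():
    return four_artery_scheme(8)


@pytest.fixture(scope="session")
def coarse_bloch() -> ModulationModel:
    """A small Bloch LUT (coarse grids keep the suite fast)."""
    params = LabellingParams(
        speed_grid=np.linspace(15.0, 100.0, 6),
        phase_grid=np.linspace(-np.pi, np.pi, 24, endpoint=False),
        n_laminar=8,
    )
    return ModulationModel.bloch(params)


@pytest.fixture(scope="session")
def dataset6():
    return simulate_dataset(SimulationConfig(n_cycles=6), seed=42)


@pytest.fixture(scope="session")
def dataset8():
    return simulate_dataset(SimulationConfig(n_cycles=8), seed=42)


def planning_arteries(ds):
    """Planning-stage view of a simulated dataset's arteries: planned
    locations, nominal 30 cm/s speeds."""
    return ArteryGeometry(
        names=list(ds.arteries.names),
        planned=ds.arteries.planned.copy(),
        speeds=np.full(ds.arteries.n_arteries, 30.0),
    )
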