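import pytest

from mapweaver import (
    ArmSpec,
    BandSpec,
    ChromosomeFrame,
    ChromosomeSpec,
    SimulationConfig,
    simulate,
)
from mapweaver import reference_data


@pytest.fixture(scope="session")
def meu5_spec():
    """The published chromosome-5 geometry: 340 Mb, 232.68 cM."""
    return ChromosomeSpec("5", 340.0, 232.68)


@pytest.fixture(scope="session")
def meu5_frame(meu5_spec):
    """A chromosome-5-like frame with the published arm split and a simple
    six-band tiling (band boundaries are illustrative, not the published
    curated set)."""
    arms = [
        ArmSpec("p", 66.812, 53.52, 53.52, chromosome="5"),
        ArmSpec("q", 273.188, 179.16, 179.16, chromosome="5"),
    ]
    bands = [
        BandSpec("p3", 20.0, 0.0, 20.0),
        BandSpec("p2", 26.812, 20.0, 46.812),
        BandSpec("p1", 20.0, 46.812, 66.812),
        BandSpec("q1", 70.0, 66.812, 136.812),
        BandSpec("q2", 120.0, 136.812, 256.812),
        BandSpec("q3", 83.188, 256.812, 340.0),
    ]
    return ChromosomeFrame(spec=meu5_spec, arms=arms, bands=bands,
                           centromere_kb=66812.0)


@pytest.fixture(scope="session")
def published_map():
    """Worked rows of the published integrated/virtual map, keyed by locus."""
    return {e.locus: e for e in reference_data.tammar_map_excerpt()}


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 0), shared across tests."""
    return simulate(SimulationConfig(seed=0))
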