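import numpy as np
import pytest

from dropsfx import (BeamlineGeometry, DropModel, SampleModel, SimConfig,
                     UnitCell)


@pytest.fixture(scope="session")
def demo_geom() -> BeamlineGeometry:
    """Small synthetic detector reaching ~1.6 Å at the edge midpoint."""
    return BeamlineGeometry(photon_energy_kev=9.28, detector_distance_mm=20.0,
                            pixel_pitch_um=177.0, beam_center=(127.5, 127.5),
                            frame_shape=(256, 256))


@pytest.fixture(scope="session")
def wide_geom() -> BeamlineGeometry:
    """Geometry with a 1000+ px radial range for hand-derived conversions."""
    return BeamlineGeometry(photon_energy_kev=9.28,
                            detector_distance_mm=120.0, pixel_pitch_um=89.0,
                            beam_center=(1023.5, 1023.5),
                            frame_shape=(2048, 2048))


@pytest.fixture(scope="session")
def cubic_cell() -> UnitCell:
    return UnitCell(50.0, 50.0, 50.0, label="cube50")


@pytest.fixture()
def fast_sim(demo_geom, cubic_cell) -> SimConfig:
    """A quick crystal-bearing run configuration (~2 crystals per drop)."""
    sample = SampleModel(name="cube50", cell=cubic_cell, concentration=400.0)
    return SimConfig(geometry=demo_geom, sample=sample, drop=DropModel(),
                     duration_s=2.0, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
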