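import numpy as np
import pytest

from cryomerge.formats_io import DensityMap, StarTable
from cryomerge.synthetic_fixtures import make_phantom, render


@pytest.fixture(scope="session")
def phantom():
    """Small blob phantom sized for a 64-pixel box at ~1.4 Å/px."""
    return make_phantom(n_blobs=12, extent=64 * 1.40, seed=7)


@pytest.fixture(scope="session")
def phantom_map(phantom):
    """Noiseless rendering of the session phantom at 1.40 Å/px."""
    return render(phantom, box=64, apix=1.40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noise_map(rng):
    """White-noise cube, 64^3 at 1 Å/px."""
    return DensityMap(rng.normal(size=(64, 64, 64)), apix=1.0)


@pytest.fixture()
def particle_table():
    """Minimal picked-particle table with the columns the rescaling touches."""
    return StarTable.from_columns(
        {
            "_rlnMicrographName": ["mics/mic1.mrc", "mics/mic1.mrc", "mics/mic2.mrc"],
            "_rlnCoordinateX": [1000.0, 250.0, 512.0],
            "_rlnCoordinateY": [800.0, 300.0, 512.0],
            "_rlnOriginX": [1.5, -2.0, 0.0],
            "_rlnOriginY": [0.5, 0.0, -1.0],
            "_rlnMagnification": [10000.0, 10000.0, 10000.0],
            "_rlnDetectorPixelSize": [1.36, 1.36, 1.36],
        }
    )


@pytest.fixture()
def ctf_table():
    """Minimal per-micrograph CTF table in RELION column conventions."""
    return StarTable.from_columns(
        {
            "_rlnMicrographName": ["mic1.mrc", "mic2.mrc"],
            "_rlnDefocusU": [20000.0, 15000.0],
            "_rlnDefocusV": [19000.0, 14500.0],
            "_rlnDefocusAngle": [45.0, -30.0],
            "_rlnVoltage": [300.0, 300.0],
            "_rlnSphericalAberration": [2.7, 2.7],
            "_rlnAmplitudeContrast": [0.1, 0.1],
            "_rlnMagnification": [10000.0, 10000.0],
            "_rlnDetectorPixelSize": [0.900, 0.900],
        }
    )
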