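import numpy as np
import pytest

from aneushear import (
    FluidProperties,
    SyntheticPatientSpec,
    make_patient,
    make_waveform,
)


@pytest.fixture(scope="session")
def ica_waveform():
    """Pulsatile ICA-like inflow: mean 4 cm^3/s, PI 1.0, 60 bpm."""
    return make_waveform(4.0, 1.0, 60.0)


@pytest.fixture(scope="session")
def coarse_patient():
    """Small synthetic patient (coarse mesh) with its ground truth."""
    spec = SyntheticPatientSpec(mesh_edge_size=0.06, n_time_samples=20, seed=11)
    return make_patient(spec, FluidProperties())


def random_wss_field(rng, n_points=40, n_times=25):
    """Random smooth WSS vector time series on a tiny two-region mesh."""
    from aneushear import TriSurfaceField

    pts = rng.random((n_points, 3))
    tris = np.array([[i, (i + 1) % n_points, (i + 2) % n_points] for i in range(n_points - 2)])
    region = np.where(np.arange(n_points) % 2 == 0, 1, 2)
    times = np.sort(np.concatenate([[0.0], rng.uniform(0.01, 0.99, n_times - 2), [1.0]]))
    # smooth random Fourier series per point and component
    wss = np.zeros((n_times, n_points, 3))
    for k in range(1, 4):
        amp = rng.normal(size=(n_points, 3))
        phase = rng.uniform(0, 2 * np.pi, size=(n_points, 3))
        wss += amp[None] * np.cos(2 * np.pi * k * times[:, None, None] + phase[None])
    wss += rng.normal(size=(1, n_points, 3)) * 2.0
    return TriSurfaceField(points=pts, triangles=tris, region=region, times=times, wss=wss)
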