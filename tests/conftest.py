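import numpy as np
import pandas as pd
import pytest

from memclust import (DiffusionStateModel, SimulationConfig, TrackSet,
                      simulate_tracks, three_state_kras)


@pytest.fixture()
def straight_track():
    """Deterministic straight-line walk, step 0.1 µm per frame."""
    n = 30
    return TrackSet(data=pd.DataFrame({
        "track_id": 0, "frame": np.arange(n),
        "x_um": 0.1 * np.arange(n), "y_um": np.zeros(n)}), dt=0.01)


@pytest.fixture()
def brownian_tracks():
    """Moderate-size free-diffusion track set, D = 3 µm²/s, no noise."""
    model = DiffusionStateModel(D=[3.0], pi=[1.0], tau=[1.0],
                                Q=[[0.0]], dt=0.01, sigma_loc=0.0)
    cfg = SimulationConfig(n_tracks=400, mean_track_length=40, seed=11)
    return simulate_tracks(model, cfg)


@pytest.fixture(scope="session")
def kras_tracks_small():
    """Three-state tracks at the KRAS-alone condition, reduced count."""
    cfg = SimulationConfig(n_tracks=800, mean_track_length=50, seed=5)
    return simulate_tracks(three_state_kras(), cfg)
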