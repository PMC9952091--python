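import numpy as np
import pandas as pd
import pytest

from chemowave.synthetic import AmplitudeDist, SynthConfig, generate_tracks

NOISE_OFF = {"erk": 0.0, "akt": 0.0, "aspect_ratio": 0.0, "polarization": 0.0}


@pytest.fixture(scope="session")
def default_movie():
    """Moderate-size movie at the default study conditions (shared, read-only)."""
    cfg = SynthConfig(n_cells=150, rng_seed=11)
    tracks, truth = generate_tracks(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free movie with constant unit short-wave amplitude."""
    cfg = SynthConfig(
        n_cells=8, rng_seed=1, noise_sd=dict(NOISE_OFF),
        amp_short_dist=AmplitudeDist("constant", 1.0, 0.0))
    tracks, truth = generate_tracks(cfg)
    return cfg, tracks, truth


def single_track(n=120, dt=4.0, speed=0.0, seed=0, **signal):
    """Minimal uniform track table for one synthetic cell."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    ar = signal.get("aspect_ratio", np.full(n, 1.5))
    erk = signal.get("erk", np.zeros(n))
    step = speed * dt
    x = np.cumsum(np.full(n, step)) if speed else np.zeros(n)
    return pd.DataFrame({
        "cell_id": 0, "frame": np.arange(n), "t_min": t,
        "x_um": x, "y_um": np.zeros(n),
        "nuc_x_um": x, "nuc_y_um": np.zeros(n),
        "erk_ktr": erk, "akt_ktr": signal.get("akt", np.zeros(n)),
        "aspect_ratio": ar,
        "polarization": signal.get("polarization", np.full(n, 0.1)),
        "area_um2": 400.0,
    })
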