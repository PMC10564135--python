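import numpy as np
import pytest

from pilintrack import SimulationConfig, simulate_trackset
from pilintrack.tracks import JumpSample, TrackSet

DT = 0.030


def exact_exponential_sample(d_app: float, n: int, dt: float = DT) -> JumpSample:
    """Noise-free sample placed at the exact model quantiles of one population.

    For a single population, u is exponential with mean 4·D·Δt, so the
    Hazen-position quantiles are u_j = -4·D·Δt·ln(1 - q_j).
    """
    q = (np.arange(1, n + 1) - 0.5) / n
    u = -4.0 * d_app * dt * np.log1p(-q)
    return JumpSample(lag=1, r_um=np.sqrt(u), frame_interval_s=dt)


def random_mixture_sample(
    fractions, d_apps, n: int, seed: int, dt: float = DT
) -> JumpSample:
    """Random draws from the exponential-mixture model for u."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(fractions), size=n, p=fractions)
    u = rng.exponential(scale=4.0 * np.asarray(d_apps)[comp] * dt)
    return JumpSample(lag=1, r_um=np.sqrt(u), frame_interval_s=dt)


def trackset_from_xy(xy_per_track, dt: float = DT) -> TrackSet:
    """Build a TrackSet from a list of (n_i, 2) coordinate arrays."""
    import pandas as pd

    rows = []
    for tid, xy in enumerate(xy_per_track):
        for f, (x, y) in enumerate(np.asarray(xy, dtype=float)):
            rows.append((tid, f, x, y))
    return TrackSet(
        df=pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]),
        frame_interval_s=dt,
    )


@pytest.fixture(scope="session")
def fast_only_trackset():
    """Pure mobile population in an effectively unconfined planar cell."""
    cfg = SimulationConfig(
        n_tracks=2000,
        slow_fraction=0.0,
        D_fast_true=0.5,
        loc_error_um=0.036,
        cell_length_um=100.0,
        cell_width_um=100.0,
        geometry_mode="planar2d",
        seed=11,
    )
    ts, labels = simulate_trackset(cfg)
    return cfg, ts, labels


@pytest.fixture(scope="session")
def immobile_noisy_trackset():
    """Immobile anchors observed with sigma = 30 nm localization error."""
    cfg = SimulationConfig(
        n_tracks=1500,
        slow_fraction=1.0,
        D_fast_true=0.0,
        loc_error_um=0.030,
        bleach_survival_p=0.92,
        geometry_mode="planar2d",
        seed=5,
    )
    ts, labels = simulate_trackset(cfg)
    return cfg, ts, labels
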