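"""Confinement classification, standardized-cell projection, density maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pilintrack import (
    CellOutline,
    ConfinementClassifier,
    SimulationConfig,
    classify_tracks,
    density_map,
    project_standard_cell,
    simulate_trackset,
)
from pilintrack.confinement import read_outlines, write_outlines
from pilintrack.tracks import TrackSet

from conftest import trackset_from_xy

RADIUS = 0.1087  # um, 3x the localization error of the reference acquisition


def brownian_tracks(n, steps, d, dt=0.03, seed=0):
    rng = np.random.default_rng(seed)
    incr = rng.normal(0.0, np.sqrt(2 * d * dt), size=(n, steps, 2))
    return [np.vstack([[0.0, 0.0], incr[i].cumsum(axis=0)]) for i in range(n)]


def test_stationary_tracks_confined():
    ts = trackset_from_xy([np.full((8, 2), 0.5) for _ in range(10)])
    labels = classify_tracks(ts, radius_um=RADIUS)
    assert (labels["label"] == "confined").all()


def test_fast_brownian_tracks_mobile_matches_window_oracle():
    """Classifier agrees with an independent window max-excursion oracle.

    For fixed 20-step tracks at D = 0.5 um^2/s the oracle puts the mobile
    probability at ~0.984 (no window of 6 localizations stays within
    108.7 nm of its centroid); the classifier must reproduce that rate.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    tracks = brownian_tracks(400, 20, 0.5, seed=1)
    ts = trackset_from_xy(tracks)
    labels = classify_tracks(ts, radius_um=RADIUS)
    mobile_rate = (labels["label"] == "mobile").mean()

    # independent oracle: same statistic, separate implementation
    oracle_mobile = 0
    for xy in tracks:
        wins = sliding_window_view(np.asarray(xy), (6, 2)).reshape(-1, 6, 2)
        c = wins.mean(axis=1, keepdims=True)
        inside = np.linalg.norm(wins - c, axis=2).max(axis=1) <= RADIUS
        oracle_mobile += not inside.any()
    assert mobile_rate == oracle_mobile / len(tracks)
    assert mobile_rate > 0.95


def test_constructed_hybrid_track_is_transition():
    still = np.zeros((6, 2))
    jumps = np.cumsum(np.full((6, 2), 0.5), axis=0)
    track = np.vstack([still, still[-1] + jumps])
    labels = classify_tracks(trackset_from_xy([track]), radius_um=RADIUS)
    assert labels["label"].tolist() == ["transition"]


def test_classification_invariant_under_rigid_motion():
    tracks = brownian_tracks(50, 12, 0.02, seed=2)
    base = classify_tracks(trackset_from_xy(tracks), radius_um=RADIUS)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    moved = [xy @ rot.T + [3.1, -2.4] for xy in tracks]
    shifted = classify_tracks(trackset_from_xy(moved), radius_um=RADIUS)
    assert base["label"].tolist() == shifted["label"].tolist()


def test_every_track_gets_exactly_one_label():
    cfg = SimulationConfig(n_tracks=300, slow_fraction=0.4, seed=3)
    ts, _ = simulate_trackset(cfg)
    labels = classify_tracks(ts, radius_um=RADIUS)
    assert len(labels) == ts.n_tracks
    assert labels["track_id"].is_unique
    assert set(labels["label"]) <= {"confined", "transition", "mobile"}


def test_classifier_validation():
    ts = trackset_from_xy([np.zeros((3, 2))])
    with pytest.raises(ValueError, match="radius"):
        ConfinementClassifier(radius_um=0.0).fit()
    with pytest.raises(ValueError, match="filter"):
        classify_tracks(ts, radius_um=RADIUS, window_steps=5)


# --------------------------------------------------------------- outlines


def test_outline_round_trip(tmp_path):
    outlines = {
        "a": CellOutline("a", 0.0, 0.0, 2.0, 0.0, 0.8),
        "b": CellOutline("b", 1.0, 1.0, 1.0, 3.5, 1.0),
    }
    path = tmp_path / "outlines.csv"
    write_outlines(outlines, path)
    back = read_outlines(path)
    assert back["a"].length_um == pytest.approx(2.8)
    assert back["b"].orientation == pytest.approx(np.pi / 2)


def test_outline_validation():
    with pytest.raises(ValueError):
        CellOutline("x", 0, 0, 1, 0, -0.5)
    with pytest.raises(ValueError):
        CellOutline("x", 0, 0, 0, 0, 0)


# -------------------------------------------------------------- projection


def _trackset_in_cell(xy, cell_id="c1"):
    df = pd.DataFrame(
        {"track_id": 0, "frame": np.arange(len(xy)),
         "x_um": xy[:, 0], "y_um": xy[:, 1], "cell_id": cell_id}
    )
    return TrackSet(df=df, frame_interval_s=0.03)


def test_projection_maps_centroid_and_pole():
    # 4 x 0.8 um cell rotated 30 deg, centred at (5, 5)
    theta = np.pi / 6
    half_centerline = (4.0 - 0.8) / 2
    p1 = np.array([5, 5]) - half_centerline * np.array([np.cos(theta), np.sin(theta)])
    p2 = np.array([5, 5]) + half_centerline * np.array([np.cos(theta), np.sin(theta)])
    outline = CellOutline("c1", *p1, *p2, 0.8)
    assert outline.length_um == pytest.approx(4.0)
    pole = np.array([5, 5]) + 2.0 * np.array([np.cos(theta), np.sin(theta)])
    ts = _trackset_in_cell(np.vstack([[5.0, 5.0], pole]))
    proj = project_standard_cell(ts, {"c1": outline})
    assert proj.points[0] == pytest.approx([0.0, 0.0], abs=1e-9)
    assert proj.points[1] == pytest.approx([1.5, 0.0], abs=1e-9)


def test_projection_requires_outline_for_every_cell():
    ts = _trackset_in_cell(np.zeros((3, 2)), cell_id="ghost")
    with pytest.raises(ValueError, match="ghost"):
        project_standard_cell(ts, {})


def test_projection_preserves_count_and_uniformity():
    """Uniform points in a cell stay uniform in the standardized frame."""
    rng = np.random.default_rng(4)
    # same 3:1 aspect as the standardized cell, so scaling is isotropic
    outline = CellOutline("c1", -1.5, 0.0, 1.5, 0.0, 1.5)  # 4.5 x 1.5
    from pilintrack.geometry import Spherocylinder

    cell = Spherocylinder(outline.length_um, outline.width_um)
    pts = cell.sample_uniform_2d(6000, rng)
    ts = _trackset_in_cell(pts)
    proj = project_standard_cell(ts, {"c1": outline})
    assert proj.n_points == 6000
    assert proj.clamped_fraction == 0.0
    # chi-square against uniform occupancy over interior bins only
    grid = density_map(proj, bin_size_um=0.25)
    counts = grid.counts
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    interior = np.abs(xc) < 1.0  # rectangle away from the curved caps
    obs = counts[interior].ravel()
    chi2 = ((obs - obs.mean()) ** 2 / obs.mean()).sum()
    assert stats.chi2.sf(chi2, len(obs) - 1) > 1e-4


def test_points_outside_are_clamped_and_flagged():
    outline = CellOutline("c1", -1.0, 0.0, 1.0, 0.0, 1.0)
    ts = _trackset_in_cell(np.array([[0.0, 0.9], [0.0, 0.0]]))
    proj = project_standard_cell(ts, {"c1": outline})
    assert proj.clamped.tolist() == [True, False]
    assert abs(proj.points[0, 1]) == pytest.approx(0.5)


def test_membrane_confined_density_is_peripheral():
    """Surface diffusion projects to an edge-enhanced cross-axis profile."""
    cfg = SimulationConfig(n_tracks=800, slow_fraction=1.0, loc_error_um=0.01,
                           geometry_mode="surface3d", seed=6)
    ts, _ = simulate_trackset(cfg)
    ts.df["cell_id"] = "c1"
    outline = CellOutline("c1", -1.0, 0.0, 1.0, 0.0, 1.0)
    proj = project_standard_cell(ts, {"c1": outline})
    grid = density_map(proj, bin_size_um=0.1)
    profile = grid.counts.sum(axis=0)  # across the short axis (10 bins)
    edge = profile[[0, -1]].mean()
    core = profile[4:6].mean()
    assert edge > 1.5 * core


# ------------------------------------------------------------ density map


def test_density_single_point_and_conservation():
    outline = CellOutline("c1", -1.0, 0.0, 1.0, 0.0, 1.0)
    ts = _trackset_in_cell(np.array([[0.51, 0.11]]))
    proj = project_standard_cell(ts, {"c1": outline})
    grid = density_map(proj, bin_size_um=0.05)
    assert grid.counts.shape == (60, 20)
    assert grid.counts.sum() == 1
    assert grid.counts.max() == 1
    assert grid.normalized.max() == 1.0


def test_density_bin_larger_than_cell_rejected():
    outline = CellOutline("c1", -1.0, 0.0, 1.0, 0.0, 1.0)
    ts = _trackset_in_cell(np.zeros((2, 2)))
    with pytest.raises(ValueError, match="bin"):
        density_map(project_standard_cell(ts, {"c1": outline}), bin_size_um=1.5)


def test_density_subset_by_classification_label():
    outline = CellOutline("c1", -1.0, 0.0, 1.0, 0.0, 1.0)
    df = pd.DataFrame(
        {"track_id": [0, 0, 1, 1], "frame": [0, 1, 0, 1],
         "x_um": [0.0, 0.0, 0.5, 0.5], "y_um": 0.0, "cell_id": "c1"}
    )
    ts = TrackSet(df=df, frame_interval_s=0.03)
    cls = pd.DataFrame({"track_id": [0, 1], "label": ["confined", "mobile"]})
    proj = project_standard_cell(ts, {"c1": outline}, classifications=cls)
    grid = density_map(proj, subset="confined")
    assert grid.counts.sum() == 2
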