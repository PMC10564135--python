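"""Seeded generators for tracks, filaments and bleach traces with known truth.

The generative model is the minimal one consistent with a two-population
jump-distance analysis of a membrane pilin:

* each molecule starts in a *slow* (pilus-engaged, tethered to an anchor;
  immobile by default) or *fast* (freely membrane-diffusing, Brownian with
  per-coordinate step variance 2·D·Δt) state, drawn with ``slow_fraction``;
* an optional two-state Markov switch (rates in 1/s) produces
  transition-type tracks; it is off by default because the mixture fits
  assume static populations within a track;
* every localization of every frame gets independent Gaussian localization
  noise of σ per coordinate — which is what makes the immobile population's
  *apparent* diffusion coefficient σ²/Δt rather than zero;
* track length is bleaching-limited: steps = 1 + Geometric(1 − p) with
  per-frame survival probability p, and tracks shorter than ``min_steps``
  are discarded, mirroring the acquisition-side filter;
* motion is constrained to a 3 × 1 μm spherocylindrical cell, either as
  reflected 2-D diffusion inside the silhouette (``planar2d``) or as
  diffusion on the 3-D surface orthographically projected onto the focal
  plane (``surface3d``, the membrane-protein default).

With the default composition the generator reproduces the study conditions
of the tracked pilin: a ~32% immobile fraction with apparent
D ≈ σ²/Δt ≈ 0.042 μm²/s (σ ≈ 35.5 nm, Δt = 30 ms) and a ~68% mobile
fraction with apparent D ≈ 0.51 μm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Spherocylinder
from .tracks import IntensityTrace, TrackSet

__all__ = [
    "EmptyTrackSetError",
    "FilamentSimConfig",
    "GroundTruthLabels",
    "REFERENCE_CONDITIONS",
    "SimulationConfig",
    "recovery_config",
    "simulate_bleach_trace",
    "simulate_filaments",
    "simulate_trackset",
]

SLOW, FAST = 0, 1
STATE_NAMES = {SLOW: "slow", FAST: "fast"}


class EmptyTrackSetError(RuntimeError):
    """No simulated track survived the minimum-steps filter."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative parameters for a simulated track set.

    ``D_slow_true`` and ``D_fast_true`` are true (pre-noise) coefficients in
    μm²/s; apparent coefficients recovered from the data include the
    localization-error term σ²/Δt on top.  ``confinement_radius_true_um``
    bounds the slow state's excursion around its anchor (0 = perfectly
    immobile anchor, the default).  ``switch_rate_sm`` / ``switch_rate_ms``
    are slow→mobile / mobile→slow rates in 1/s (0 disables switching).
    """

    n_tracks: int
    frame_interval_s: float = 0.030
    slow_fraction: float = 0.324
    D_slow_true: float = 0.0
    D_fast_true: float = 0.468
    loc_error_um: float = 0.0355
    confinement_radius_true_um: float = 0.0
    switch_rate_sm: float = 0.0
    switch_rate_ms: float = 0.0
    bleach_survival_p: float = 0.9
    min_steps: int = 5
    cell_length_um: float = 3.0
    cell_width_um: float = 1.0
    geometry_mode: str = "surface3d"
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "frame_interval_s": self.frame_interval_s,
            "slow_fraction": self.slow_fraction,
            "D_slow_true": self.D_slow_true,
            "D_fast_true": self.D_fast_true,
            "loc_error_um": self.loc_error_um,
            "confinement_radius_true_um": self.confinement_radius_true_um,
            "switch_rate_sm": self.switch_rate_sm,
            "switch_rate_ms": self.switch_rate_ms,
            "cell_length_um": self.cell_length_um,
            "cell_width_um": self.cell_width_um,
        }
        for name, value in numeric.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValueError("slow_fraction must be in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not self.cell_length_um >= self.cell_width_um > 0:
            raise ValueError("require cell_length >= cell_width > 0")
        if not 0.0 < self.bleach_survival_p < 1.0:
            raise ValueError("bleach_survival_p must be in (0, 1)")
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")
        if self.geometry_mode not in ("surface3d", "planar2d"):
            raise ValueError(f"unknown geometry_mode {self.geometry_mode!r}")


@dataclass
class GroundTruthLabels:
    """Per-track truth for recovery scoring.

    ``table`` has one row per surviving track (``track_id, dominant_state``);
    ``state_sequences`` maps track_id to the per-step state array
    ('slow'/'fast', one entry per displacement).
    """

    table: pd.DataFrame
    state_sequences: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def slow_track_fraction(self) -> float:
        return float((self.table["dominant_state"] == "slow").mean())


#: Reported two-population compositions used as simulation ground truth:
#: slow-fraction and *apparent* diffusion coefficients (μm²/s) of the
#: tracked pilin without and with added chromosomal DNA.
REFERENCE_CONDITIONS: dict[str, dict[str, float]] = {
    "-DNA": {"slow_fraction": 0.324, "d_slow_app": 0.042, "d_fast_app": 0.51},
    "+DNA": {"slow_fraction": 0.473, "d_slow_app": 0.038, "d_fast_app": 0.22},
}


def recovery_config(
    condition: str = "-DNA",
    n_tracks: int = 5000,
    seed: int = 0,
    frame_interval_s: float = 0.030,
) -> SimulationConfig:
    """Simulation config whose displacement statistics carry a reference
    composition exactly.

    The slow state is an immobile anchor observed with σ chosen so that
    σ²/Δt equals the condition's slow apparent D, and the fast state's true
    D is the fast apparent D minus σ²/Δt.  Geometry is planar and
    effectively unconfined (100 × 100 μm) so no boundary reflection distorts
    the step distribution; the rod geometries serve the spatial-mapping
    stages, not parameter recovery.
    """
    ref = REFERENCE_CONDITIONS[condition]
    sigma = math.sqrt(ref["d_slow_app"] * frame_interval_s)
    d_fast_true = ref["d_fast_app"] - ref["d_slow_app"]
    return SimulationConfig(
        n_tracks=n_tracks,
        frame_interval_s=frame_interval_s,
        slow_fraction=ref["slow_fraction"],
        D_slow_true=0.0,
        D_fast_true=d_fast_true,
        loc_error_um=sigma,
        confinement_radius_true_um=0.0,
        bleach_survival_p=0.9,
        min_steps=5,
        cell_length_um=100.0,
        cell_width_um=100.0,
        geometry_mode="planar2d",
        seed=seed,
    )


def _state_sequences(
    cfg: SimulationConfig, n_steps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n_tracks, max_steps) int array of per-step states (padded)."""
    n = len(n_steps)
    max_steps = int(n_steps.max())
    states = np.empty((n, max_steps), dtype=np.int8)
    initial = np.where(rng.random(n) < cfg.slow_fraction, SLOW, FAST)
    states[:, 0] = initial
    if cfg.switch_rate_sm == 0.0 and cfg.switch_rate_ms == 0.0:
        states[:] = initial[:, None]
        return states
    p_sm = 1.0 - math.exp(-cfg.switch_rate_sm * cfg.frame_interval_s)
    p_ms = 1.0 - math.exp(-cfg.switch_rate_ms * cfg.frame_interval_s)
    for t in range(1, max_steps):
        u = rng.random(n)
        prev = states[:, t - 1]
        flip = np.where(prev == SLOW, u < p_sm, u < p_ms)
        states[:, t] = np.where(flip, 1 - prev, prev)
    return states


def _confine_to_anchor(
    pos: np.ndarray, anchor: np.ndarray, radius: float
) -> np.ndarray:
    """Fold positions back inside a disc/sphere of given radius around anchor."""
    v = pos - anchor
    d = np.linalg.norm(v, axis=-1)
    out = d > radius
    if out.any():
        # mirror the excess across the spherical boundary, then clamp
        scale = np.ones_like(d)
        excess = d[out] - radius
        folded = np.maximum(radius - excess, 0.0)
        scale[out] = np.where(d[out] > 0, folded / np.maximum(d[out], 1e-300), 0.0)
        pos = anchor + v * scale[..., None]
    return pos


def simulate_trackset(
    cfg: SimulationConfig,
) -> tuple[TrackSet, GroundTruthLabels]:
    """Simulate a two-state track set; returns the tracks and their truth.

    Identical configs (including seed) reproduce byte-identical output.
    Raises :class:`EmptyTrackSetError` if no track survives ``min_steps``.
    """
    rng = np.random.default_rng(cfg.seed)
    cell = Spherocylinder(cfg.cell_length_um, cfg.cell_width_um)
    n = cfg.n_tracks
    if n == 0:
        raise EmptyTrackSetError("n_tracks = 0")

    # bleaching-limited track lengths (in steps), then state sequences
    n_steps = 1 + rng.geometric(1.0 - cfg.bleach_survival_p, size=n)
    states = _state_sequences(cfg, n_steps, rng)
    max_steps = int(n_steps.max())

    three_d = cfg.geometry_mode == "surface3d"
    dim = 3 if three_d else 2
    if three_d:
        pos = cell.sample_uniform_surface(n, rng)
    else:
        pos = cell.sample_uniform_2d(n, rng)
    anchor = pos.copy()  # tether point while in the slow state

    step_sd_fast = math.sqrt(2.0 * cfg.D_fast_true * cfg.frame_interval_s)
    step_sd_slow = math.sqrt(2.0 * cfg.D_slow_true * cfg.frame_interval_s)

    true_pos = np.empty((n, max_steps + 1, dim))
    true_pos[:, 0] = pos
    for t in range(max_steps):
        active = t < n_steps
        state_t = states[:, t]
        sd = np.where(state_t == FAST, step_sd_fast, step_sd_slow)
        raw = rng.normal(size=(n, dim)) * sd[:, None]
        if three_d:
            normal = cell.surface_normal(pos)
            raw -= np.sum(raw * normal, axis=1, keepdims=True) * normal
        cand = pos + raw
        slow_now = state_t == SLOW
        if slow_now.any():
            if cfg.confinement_radius_true_um > 0:
                cand[slow_now] = _confine_to_anchor(
                    cand[slow_now], anchor[slow_now], cfg.confinement_radius_true_um
                )
            else:
                cand[slow_now] = anchor[slow_now]
        if three_d:
            cand = cell.project_to_surface(cand)
        else:
            cand = cell.reflect_into_2d(cand)
        pos = np.where(active[:, None], cand, pos)
        # molecules leaving the slow state re-anchor wherever they next stop
        if t + 1 < max_steps:
            entering_slow = (states[:, t + 1] == SLOW) & (state_t == FAST)
            anchor[entering_slow] = pos[entering_slow]
        true_pos[:, t + 1] = pos

    projected = true_pos[:, :, :2]  # surface3d: orthographic drop of z
    noise = rng.normal(scale=cfg.loc_error_um, size=projected.shape)
    observed = projected + noise

    keep = np.flatnonzero(n_steps >= cfg.min_steps)
    if len(keep) == 0:
        raise EmptyTrackSetError(
            f"no track reached min_steps={cfg.min_steps} "
            f"(bleach_survival_p={cfg.bleach_survival_p})"
        )

    records = []
    seqs: dict[int, np.ndarray] = {}
    dominant = []
    for new_id, i in enumerate(keep):
        s = int(n_steps[i])
        for f in range(s + 1):
            records.append((new_id, f, observed[i, f, 0], observed[i, f, 1]))
        seq = np.where(states[i, :s] == SLOW, "slow", "fast")
        seqs[new_id] = seq
        n_slow = int((states[i, :s] == SLOW).sum())
        dominant.append("slow" if n_slow * 2 >= s else "fast")
    df = pd.DataFrame(records, columns=["track_id", "frame", "x_um", "y_um"])
    ts = TrackSet(
        df=df,
        frame_interval_s=cfg.frame_interval_s,
        loc_error_um=cfg.loc_error_um,
    )
    labels = GroundTruthLabels(
        table=pd.DataFrame(
            {"track_id": np.arange(len(keep)), "dominant_state": dominant}
        ),
        state_sequences=seqs,
    )
    return ts, labels


# ---------------------------------------------------------------- filaments


@dataclass(frozen=True)
class FilamentSimConfig:
    """Generator parameters for surface-anchored filament polylines.

    Arc lengths are drawn from Normal(mean, sd) truncated at > 0 (nm);
    ``curvature_sd`` perturbs the heading by that many radians per node.
    Defaults follow the measured pilus-length distribution under full
    induction (505 ± 155 nm).
    """

    n_filaments: int
    length_mean_nm: float = 505.0
    length_sd_nm: float = 155.0
    curvature_sd: float = 0.1
    nodes_per_filament: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_mean_nm <= 0:
            raise ValueError("length_mean_nm must be > 0")
        if self.length_sd_nm < 0:
            raise ValueError("length_sd_nm must be >= 0")
        if self.nodes_per_filament < 2:
            raise ValueError("nodes_per_filament must be >= 2")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        if self.curvature_sd < 0:
            raise ValueError("curvature_sd must be >= 0")


def simulate_filaments(cfg: FilamentSimConfig, outline) -> pd.DataFrame:
    """Simulate filament traces anchored on a cell outline.

    Each filament starts on the silhouette boundary heading along the
    outward normal; successive segments of equal length turn by
    N(0, curvature_sd) radians.  Returns a tidy frame
    ``filament_id, node_index, x_nm, y_nm, cell_id`` (world coordinates, nm).
    ``outline`` is a :class:`pilintrack.confinement.CellOutline`.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_filaments == 0:
        return pd.DataFrame(
            columns=["filament_id", "node_index", "x_nm", "y_nm", "cell_id"]
        )
    cell = Spherocylinder(outline.length_um, outline.width_um)
    starts, normals = cell.boundary_points_2d(cfg.n_filaments, rng)

    # truncated-normal arc lengths (> 0) by rejection
    lengths = np.empty(cfg.n_filaments)
    todo = np.ones(cfg.n_filaments, dtype=bool)
    while todo.any():
        draw = rng.normal(cfg.length_mean_nm, cfg.length_sd_nm, int(todo.sum()))
        lengths[todo] = draw
        todo &= lengths <= 0

    n_seg = cfg.nodes_per_filament - 1
    records = []
    cos_o, sin_o = math.cos(outline.orientation), math.sin(outline.orientation)
    centre = outline.centroid_um
    for fid in range(cfg.n_filaments):
        seg = lengths[fid] / n_seg
        heading = math.atan2(normals[fid, 1], normals[fid, 0])
        node = starts[fid] * 1e3  # μm -> nm, cell frame
        pts = [node.copy()]
        for _ in range(n_seg):
            heading += rng.normal(0.0, cfg.curvature_sd)
            node = node + seg * np.array([math.cos(heading), math.sin(heading)])
            pts.append(node.copy())
        for idx, p in enumerate(pts):
            # rotate into the world frame and translate to the cell position
            wx = cos_o * p[0] - sin_o * p[1] + centre[0] * 1e3
            wy = sin_o * p[0] + cos_o * p[1] + centre[1] * 1e3
            records.append((fid, idx, wx, wy, outline.cell_id))
    return pd.DataFrame(
        records, columns=["filament_id", "node_index", "x_nm", "y_nm", "cell_id"]
    )


# ------------------------------------------------------------ bleach traces


def simulate_bleach_trace(
    n_frames: int,
    n0: float,
    k_bleach: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityTrace:
    """Exponential bleach curve n0·exp(−k·i) with Gaussian noise, clipped at 0."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if k_bleach < 0:
        raise ValueError("k_bleach must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    clean = n0 * np.exp(-k_bleach * frames)
    noisy = clean + rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else clean
    return IntensityTrace(frames, np.clip(noisy, 0.0, None))
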