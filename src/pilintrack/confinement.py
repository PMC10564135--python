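"""Per-track mobility classification and standardized-cell projection.

A track is scanned with sliding windows of ``window_steps`` displacements
(``window_steps + 1`` localizations).  A window is *inside* if the maximum
distance of its localizations from the window centroid is at most the
confinement radius (3× the localization error by the MSD-intercept rule,
108.7 nm for σ = 36.23 nm).  Tracks whose windows are all inside are
``confined``, none inside ``mobile``, anything else ``transition`` — the
three classes of a confinement map.

Localizations from many cells are compared in a common frame by projecting
each cell onto a standardized 3 × 1 μm rod: rotate into the cell frame,
centre, and scale the long/short axes; binned 2-D densities of the projected
points give the heat maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .geometry import Spherocylinder
from .tracks import TrackSet

__all__ = [
    "CellOutline",
    "ConfinementClassifier",
    "DensityMap",
    "NormalizedProjection",
    "STANDARD_CELL_LENGTH_UM",
    "STANDARD_CELL_WIDTH_UM",
    "classify_tracks",
    "density_map",
    "project_standard_cell",
    "read_outlines",
    "write_outlines",
]

LABELS = ("confined", "transition", "mobile")
STANDARD_CELL_LENGTH_UM = 3.0
STANDARD_CELL_WIDTH_UM = 1.0


@dataclass(frozen=True)
class CellOutline:
    """Rod parameterization of one segmented cell.

    ``(x1, y1)`` and ``(x2, y2)`` are the centreline endpoints (centres of
    the two cap hemispheres), so the total cell length is the centreline
    length plus the width.
    """

    cell_id: str
    x1_um: float
    y1_um: float
    x2_um: float
    y2_um: float
    width_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("width_um must be > 0")
        if self.length_um < self.width_um:
            raise ValueError("cell length must be >= width")

    @property
    def centerline_length_um(self) -> float:
        return math.hypot(self.x2_um - self.x1_um, self.y2_um - self.y1_um)

    @property
    def length_um(self) -> float:
        return self.centerline_length_um + self.width_um

    @property
    def orientation(self) -> float:
        return math.atan2(self.y2_um - self.y1_um, self.x2_um - self.x1_um)

    @property
    def centroid_um(self) -> tuple[float, float]:
        return (
            0.5 * (self.x1_um + self.x2_um),
            0.5 * (self.y1_um + self.y2_um),
        )

    def to_cell_frame(self, xy: np.ndarray) -> np.ndarray:
        """World coordinates -> cell frame (long axis along x, centred)."""
        xy = np.asarray(xy, dtype=float)
        cx, cy = self.centroid_um
        c, s = math.cos(-self.orientation), math.sin(-self.orientation)
        dx, dy = xy[..., 0] - cx, xy[..., 1] - cy
        return np.stack([c * dx - s * dy, s * dx + c * dy], axis=-1)


def read_outlines(path) -> dict[str, CellOutline]:
    """Read an outlines CSV `cell_id,x1_um,y1_um,x2_um,y2_um,width_um`."""
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "x1_um", "y1_um", "x2_um", "y2_um", "width_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.cell_id)] = CellOutline(
            cell_id=str(row.cell_id),
            x1_um=row.x1_um, y1_um=row.y1_um,
            x2_um=row.x2_um, y2_um=row.y2_um,
            width_um=row.width_um,
        )
    return out


def write_outlines(outlines: dict[str, CellOutline], path) -> None:
    rows = [
        (o.cell_id, o.x1_um, o.y1_um, o.x2_um, o.y2_um, o.width_um)
        for o in outlines.values()
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "x1_um", "y1_um", "x2_um", "y2_um", "width_um"]
    ).to_csv(path, index=False)


# ----------------------------------------------------------- classification


def _classify_xy(xy: np.ndarray, radius: float, window_steps: int) -> str:
    """Label one track from its (n, 2) coordinates."""
    w = window_steps + 1  # localizations per window
    windows = sliding_window_view(xy, (w, 2)).reshape(-1, w, 2)
    centroids = windows.mean(axis=1, keepdims=True)
    max_excursion = np.linalg.norm(windows - centroids, axis=2).max(axis=1)
    inside = max_excursion <= radius
    if inside.all():
        return "confined"
    if not inside.any():
        return "mobile"
    return "transition"


class ConfinementClassifier(BaseEstimator):
    """Rule-based confined/transition/mobile track classifier.

    Parameters
    ----------
    radius_um : confinement radius (3σ by the MSD rule; 0.1087 μm in the
        reference acquisition).
    window_steps : displacements per sliding window; the default equals the
        minimum admissible track length, so the shortest kept track forms
        exactly one window.

    The rule is centroid-based and therefore invariant under global
    translation and rotation of the coordinates.
    """

    def __init__(self, radius_um: float = 0.1087, window_steps: int = 5):
        self.radius_um = radius_um
        self.window_steps = window_steps

    def fit(self, X=None, y=None) -> "ConfinementClassifier":
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.window_steps < 1:
            raise ValueError("window_steps must be >= 1")
        self.is_fitted_ = True
        return self

    def predict(self, ts: TrackSet) -> pd.DataFrame:
        """Label every track; returns a `track_id,label` frame."""
        if not getattr(self, "is_fitted_", False):
            self.fit()
        too_short = []
        rows = []
        for tid, sub in ts.iter_tracks():
            xy = sub[["x_um", "y_um"]].to_numpy(float)
            if len(xy) < self.window_steps + 1:
                too_short.append(tid)
                continue
            rows.append((tid, _classify_xy(xy, self.radius_um, self.window_steps)))
        if too_short:
            raise ValueError(
                f"tracks shorter than window ({self.window_steps} steps): "
                f"{too_short[:10]}{'...' if len(too_short) > 10 else ''}; "
                "filter tracks first"
            )
        return pd.DataFrame(rows, columns=["track_id", "label"])


def classify_tracks(
    ts: TrackSet, radius_um: float, window_steps: int = 5
) -> pd.DataFrame:
    """Classify all tracks as confined / transition / mobile."""
    return ConfinementClassifier(radius_um=radius_um,
                                 window_steps=window_steps).fit().predict(ts)


# --------------------------------------------------------------- projection


@dataclass
class NormalizedProjection:
    """Localizations mapped into the standardized 3 × 1 μm cell.

    ``points`` spans [−1.5, 1.5] μm along the long axis and [−0.5, 0.5] μm
    across; ``clamped`` flags points that fell outside the standardized
    silhouette (localization noise near the boundary) and were clamped onto
    it.
    """

    points: np.ndarray
    track_id: np.ndarray
    labels: np.ndarray | None
    clamped: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def clamped_fraction(self) -> float:
        return float(self.clamped.mean()) if len(self.clamped) else 0.0


def project_standard_cell(
    ts: TrackSet,
    outlines: dict[str, CellOutline],
    classifications: pd.DataFrame | None = None,
) -> NormalizedProjection:
    """Map localizations of many cells into the standardized cell frame.

    Each localization is rotated into its cell's frame, centred on the cell
    centroid, and the long/short axes are scaled to 3 μm / 1 μm.  Points
    beyond the standardized silhouette are clamped to its boundary and
    flagged.  ``classifications`` (a `track_id,label` frame) attaches
    per-point labels for downstream subsetting.
    """
    if "cell_id" not in ts.df.columns:
        raise ValueError("track table has no cell_id column")
    cell_ids = ts.df["cell_id"].astype(str)
    missing = sorted(set(cell_ids) - set(outlines))
    if missing:
        raise ValueError(f"no outline for cell_ids: {missing}")

    std = Spherocylinder(STANDARD_CELL_LENGTH_UM, STANDARD_CELL_WIDTH_UM)
    xy = ts.df[["x_um", "y_um"]].to_numpy(float)
    out = np.empty_like(xy)
    for cid, idx in ts.df.groupby(cell_ids).indices.items():
        o = outlines[cid]
        local = o.to_cell_frame(xy[idx])
        local[:, 0] *= STANDARD_CELL_LENGTH_UM / o.length_um
        local[:, 1] *= STANDARD_CELL_WIDTH_UM / o.width_um
        out[idx] = local
    inside = std.contains_2d(out)
    clamped = ~inside
    if clamped.any():
        out[clamped] = std.clamp_to_silhouette(out[clamped])

    labels = None
    if classifications is not None:
        lut = dict(zip(classifications["track_id"], classifications["label"]))
        labels = ts.df["track_id"].map(lut).to_numpy()
    return NormalizedProjection(
        points=out,
        track_id=ts.df["track_id"].to_numpy(),
        labels=labels,
        clamped=clamped,
    )


@dataclass
class DensityMap:
    """Binned localization density over the standardized cell."""

    counts: np.ndarray
    bin_size_um: float
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        peak = self.counts.max()
        return self.counts / peak if peak > 0 else self.counts

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# bin_size_um={self.bin_size_um} "
                f"x=[{self.x_edges[0]},{self.x_edges[-1]}] "
                f"y=[{self.y_edges[0]},{self.y_edges[-1]}] "
                "rows=y columns=x\n"
            )
            pd.DataFrame(self.counts.T).to_csv(fh, index=False, header=False)


def density_map(
    projection: NormalizedProjection,
    bin_size_um: float = 0.05,
    subset: str | None = None,
) -> DensityMap:
    """2-D histogram of projected points, optionally restricted by label.

    The default 50 nm bins give a 60 × 20 grid over the standardized cell.
    The counts sum to the number of binned points.
    """
    if projection.n_points == 0:
        raise ValueError("empty projection")
    if bin_size_um > min(STANDARD_CELL_LENGTH_UM, STANDARD_CELL_WIDTH_UM):
        raise ValueError("bin size exceeds the standardized cell")
    pts = projection.points
    if subset is not None:
        if projection.labels is None:
            raise ValueError("projection carries no labels to subset on")
        pts = pts[projection.labels == subset]
    half_l = STANDARD_CELL_LENGTH_UM / 2.0
    half_w = STANDARD_CELL_WIDTH_UM / 2.0
    nx = int(round(STANDARD_CELL_LENGTH_UM / bin_size_um))
    ny = int(round(STANDARD_CELL_WIDTH_UM / bin_size_um))
    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=[nx, ny],
        range=[[-half_l, half_l], [-half_w, half_w]],
    )
    return DensityMap(counts=counts, bin_size_um=bin_size_um,
                      x_edges=x_edges, y_edges=y_edges)
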