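"""Track containers, CSV I/O, track filters and displacement statistics.

Single-molecule trajectories are held as a tidy :class:`pandas.DataFrame`
with one row per localization (``track_id, frame, x_um, y_um`` and optional
``cell_id, intensity`` columns), wrapped in :class:`TrackSet` together with
the acquisition metadata every diffusion statistic needs: the frame interval
Δt and, when known, the localization error σ.

The statistics implemented here are the standard SPT primitives:

* jump-distance / squared-displacement samples pooled over tracks at a given
  frame lag, the raw material for mixture fitting;
* the time- and ensemble-averaged MSD curve, whose short-lag linear fit gives
  the diffusion coefficient via ``slope = 4D`` and the per-coordinate
  localization error via ``intercept = 4σ²``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CsvDialect",
    "IntensityTrace",
    "JumpSample",
    "MsdCurve",
    "TrackSet",
    "TrackParseError",
    "displacement_sample",
    "filter_tracks",
    "msd_localization",
    "read_intensity_trace",
    "read_tracks",
    "trim_bleaching",
    "write_tracks",
]

REQUIRED_COLUMNS = ("track_id", "frame", "x_um", "y_um")
OPTIONAL_COLUMNS = ("cell_id", "intensity")


class TrackParseError(ValueError):
    """Raised when a track table file violates the CSV dialect."""


@dataclass(frozen=True)
class CsvDialect:
    """Options resolving unit and origin conventions at read time.

    ``unit`` scales coordinates into μm on input ("um" or "nm");
    ``origin_offset_um`` is subtracted from (x, y) after scaling, resolving
    any pixel-origin convention of the upstream tracker (default: none).
    """

    unit: str = "um"
    origin_offset_um: tuple[float, float] = (0.0, 0.0)
    comment: str = "#"

    def scale(self) -> float:
        if self.unit == "um":
            return 1.0
        if self.unit == "nm":
            return 1e-3
        raise ValueError(f"unknown unit {self.unit!r}")


@dataclass
class TrackSet:
    """A set of single-molecule tracks sharing one acquisition.

    ``df`` holds one row per localization; frames within a track are kept
    sorted and unique.  ``condition_label`` tags experimental conditions
    (e.g. "-DNA" / "+DNA"); ``loc_error_um`` is the per-coordinate σ when
    known (from simulation ground truth or an MSD fit).
    """

    df: pd.DataFrame
    frame_interval_s: float
    condition_label: str | None = None
    loc_error_um: float | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or not np.isfinite(self.frame_interval_s):
            raise ValueError("frame_interval_s must be positive and finite")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        self.df = self.df.sort_values(["track_id", "frame"], kind="stable").reset_index(
            drop=True
        )
        if self.df.duplicated(["track_id", "frame"]).any():
            raise ValueError("duplicate (track_id, frame) pairs")
        xy = self.df[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates")
        if (self.df["frame"] < 0).any():
            raise ValueError("negative frame indices")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def n_localizations(self) -> int:
        return len(self.df)

    def track_ids(self) -> np.ndarray:
        return self.df["track_id"].unique()

    def iter_tracks(self):
        """Yield ``(track_id, sub_frame)`` with rows sorted by frame."""
        yield from self.df.groupby("track_id", sort=False)

    def track_lengths(self) -> pd.Series:
        """Number of localizations per track (steps = length − 1)."""
        return self.df.groupby("track_id", sort=False).size()


@dataclass
class IntensityTrace:
    """Frame-indexed fluorescence intensity, e.g. a field-of-view bleach curve."""

    frame: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frame.shape != self.intensity.shape:
            raise ValueError("frame and intensity must have equal length")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class JumpSample:
    """Pooled displacements at one frame lag.

    ``r_um`` are Euclidean jump distances between localizations ``lag``
    frames apart within the same track; ``u_um2 = r²`` are the squared
    displacements whose cumulative distribution the SQD analysis fits.
    """

    lag: int
    r_um: np.ndarray
    frame_interval_s: float
    condition_label: str | None = None

    def __post_init__(self) -> None:
        self.r_um = np.asarray(self.r_um, dtype=float)
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.n_steps == 0:
            warnings.warn("empty jump sample", stacklevel=2)

    @property
    def u_um2(self) -> np.ndarray:
        return self.r_um**2

    @property
    def n_steps(self) -> int:
        return len(self.r_um)

    @property
    def dt_s(self) -> float:
        """Time separation of the sampled pairs (lag × frame interval)."""
        return self.lag * self.frame_interval_s


@dataclass
class MsdCurve:
    """MSD(τ) with its short-lag linear fit.

    slope = 4D, intercept = 4σ²; the confinement radius used for track
    classification is defined as 3σ.
    """

    lags: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    frame_interval_s: float
    slope_um2_per_s: float
    intercept_um2: float
    negative_intercept: bool = False

    @property
    def d_um2_per_s(self) -> float:
        return self.slope_um2_per_s / 4.0

    @property
    def loc_error_um(self) -> float:
        return float(np.sqrt(max(self.intercept_um2, 0.0) / 4.0))

    @property
    def confinement_radius_um(self) -> float:
        return 3.0 * self.loc_error_um


# --------------------------------------------------------------------- I/O


def _metadata_comments(ts: TrackSet) -> list[str]:
    lines = [f"# frame_interval_s={ts.frame_interval_s!r}"]
    if ts.condition_label is not None:
        lines.append(f"# condition={ts.condition_label}")
    if ts.loc_error_um is not None:
        lines.append(f"# loc_error_um={ts.loc_error_um!r}")
    return lines


def write_tracks(ts: TrackSet, path, dialect: CsvDialect = CsvDialect()) -> None:
    """Write a track table in the plain CSV dialect (μm coordinates)."""
    if dialect.unit != "um":
        raise ValueError("writer emits μm only")
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in ts.df.columns]
    with open(path, "w") as fh:
        for line in _metadata_comments(ts):
            fh.write(line + "\n")
        ts.df[cols].to_csv(fh, index=False)


def read_tracks(
    path,
    dialect: CsvDialect = CsvDialect(),
    frame_interval_s: float | None = None,
) -> TrackSet:
    """Read a track table CSV (`track_id,frame,x_um,y_um[,cell_id,intensity]`).

    Comment lines start with ``#``; ``# key=value`` comments written by
    :func:`write_tracks` restore the acquisition metadata, so write→read
    round-trips losslessly.  An explicit ``frame_interval_s`` overrides the
    file metadata.
    """
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    line_numbers: list[int] = []  # original 1-based line numbers of data rows
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            if stripped.startswith(dialect.comment):
                body = stripped.lstrip(dialect.comment).strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            data_lines.append(raw)
            line_numbers.append(ln)
    if not data_lines:
        raise TrackParseError(f"{path}: no data rows")
    try:
        df = pd.read_csv(io.StringIO("".join(data_lines)))
    except Exception as exc:  # pragma: no cover - malformed CSV structure
        raise TrackParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing required columns {missing}")
    for col in ("frame", "x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrackParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at line {line_numbers[row + 1]}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise TrackParseError(
                f"{path}: missing value in column {col!r} at line "
                f"{line_numbers[row + 1]}"
            )
        df[col] = coerced
    dup = df.duplicated(["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrackParseError(
            f"{path}: duplicate (track_id, frame) at line {line_numbers[row + 1]}"
        )
    scale = dialect.scale()
    ox, oy = dialect.origin_offset_um
    df["x_um"] = df["x_um"] * scale - ox
    df["y_um"] = df["y_um"] * scale - oy
    df["frame"] = df["frame"].astype(int)
    if frame_interval_s is None:
        if "frame_interval_s" not in meta:
            raise TrackParseError(
                f"{path}: frame_interval_s neither given nor found in file metadata"
            )
        frame_interval_s = float(meta["frame_interval_s"])
    loc_error = float(meta["loc_error_um"]) if "loc_error_um" in meta else None
    return TrackSet(
        df=df,
        frame_interval_s=frame_interval_s,
        condition_label=meta.get("condition"),
        loc_error_um=loc_error,
    )


def read_intensity_trace(path) -> IntensityTrace:
    """Read a two-column `frame,intensity` CSV."""
    df = pd.read_csv(path, comment="#")
    if not {"frame", "intensity"}.issubset(df.columns):
        raise TrackParseError(f"{path}: expected columns frame,intensity")
    return IntensityTrace(df["frame"].to_numpy(), df["intensity"].to_numpy())


# ----------------------------------------------------------------- filters


def filter_tracks(
    ts: TrackSet, min_steps: int = 5, require_uninterrupted: bool = True
) -> TrackSet:
    """Keep tracks with at least ``min_steps`` displacements.

    A track of n localizations has n − 1 steps, so the default keeps tracks
    of ≥ 6 localizations.  With ``require_uninterrupted`` (default) tracks
    whose frames are not strictly consecutive are dropped as well.  Track
    order is preserved and the operation is idempotent.
    """
    keep: list = []
    for tid, sub in ts.iter_tracks():
        frames = sub["frame"].to_numpy()
        if len(frames) - 1 < min_steps:
            continue
        if require_uninterrupted and not np.all(np.diff(frames) == 1):
            continue
        keep.append(tid)
    out = ts.df[ts.df["track_id"].isin(set(keep))]
    return replace(ts, df=out.reset_index(drop=True))


def trim_bleaching(
    trace: IntensityTrace, decline_threshold: float = 0.10, window: int = 1
) -> int | None:
    """First frame at which the bleach curve has settled.

    Stream-acquisition movies begin at an intensity too high for single
    molecules; the analysis starts once the relative decline over the
    trailing window, ``(I[t−w] − I[t]) / I[t−w]``, first falls below
    ``decline_threshold``.  Returns that frame index, or ``None`` if the
    trace keeps declining faster than the threshold throughout (no cut
    point).
    """
    if not (0.0 < decline_threshold <= 1.0):
        raise ValueError("decline_threshold must be in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    intensity = np.asarray(trace.intensity, dtype=float)
    if len(intensity) < window + 1:
        raise ValueError("trace shorter than window + 1")
    if np.all(intensity == 0):
        raise ValueError("all-zero intensity trace")
    past = intensity[:-window]
    now = intensity[window:]
    with np.errstate(divide="ignore", invalid="ignore"):
        decline = np.where(past > 0, (past - now) / past, 0.0)
    hits = np.flatnonzero(decline < decline_threshold)
    if len(hits) == 0:
        return None
    return int(hits[0] + window)


# -------------------------------------------------------------- statistics


def displacement_sample(ts: TrackSet, lag: int = 1) -> JumpSample:
    """Pool jump distances at a given frame lag over all tracks.

    Pairs are localizations ``lag`` frames apart within the same track
    (frame-based, so interrupted tracks contribute only pairs that exist).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    rs: list[np.ndarray] = []
    for _, sub in ts.iter_tracks():
        frames = sub["frame"].to_numpy()
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        pos = dict(zip(frames, range(len(frames))))
        j = np.array([pos.get(f + lag, -1) for f in frames])
        ok = j >= 0
        if ok.any():
            d = xy[j[ok]] - xy[ok]
            rs.append(np.hypot(d[:, 0], d[:, 1]))
    r = np.concatenate(rs) if rs else np.empty(0)
    return JumpSample(
        lag=lag,
        r_um=r,
        frame_interval_s=ts.frame_interval_s,
        condition_label=ts.condition_label,
    )


def msd_localization(ts: TrackSet, max_lag: int = 4) -> MsdCurve:
    """Time- and ensemble-averaged MSD with a weighted linear fit.

    MSD(τ) is averaged over all within-track pairs at each lag 1..max_lag.
    The fit against τ·Δt (weights ∝ pair counts) yields ``slope = 4D`` and
    ``intercept = 4σ²``; a negative fitted intercept is floored at zero and
    flagged.  Short default lag range (4) keeps the σ estimate unbiased by
    confinement curvature at larger lags.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    lags = np.arange(1, max_lag + 1)
    msd = np.zeros(max_lag)
    n_pairs = np.zeros(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        sample = displacement_sample(ts, lag=int(lag))
        n_pairs[i] = sample.n_steps
        msd[i] = float(np.mean(sample.u_um2)) if sample.n_steps else np.nan
    valid = n_pairs > 0
    if valid.sum() < 2:
        raise ValueError("need MSD values at >= 2 lags to fit")
    t = lags[valid] * ts.frame_interval_s
    w = np.sqrt(n_pairs[valid].astype(float))
    slope, intercept = np.polyfit(t, msd[valid], 1, w=w)
    negative = intercept < 0
    return MsdCurve(
        lags=lags,
        msd_um2=msd,
        n_pairs=n_pairs,
        frame_interval_s=ts.frame_interval_s,
        slope_um2_per_s=float(slope),
        intercept_um2=float(max(intercept, 0.0)),
        negative_intercept=bool(negative),
    )
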