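"""Morphometric and plate-assay calculations outside the tracking chain.

Covers the small quantitative operations of a competence-pilus study:
filament (pilus) arc-length statistics from traced polylines, the fraction
of pilus-positive cells with a Wilson score interval, transformation
frequency from plate counts, and the dye-mass formula for labelling DNA
with an N-fold molar excess of fluorophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FilamentLengthStats",
    "PositiveFraction",
    "dye_mass",
    "filament_length_stats",
    "positive_fraction",
    "read_filaments",
    "transformation_frequency",
    "write_filaments",
]

FILAMENT_COLUMNS = ("filament_id", "node_index", "x_nm", "y_nm")


def read_filaments(path) -> pd.DataFrame:
    """Read a filament trace CSV `filament_id,node_index,x_nm,y_nm[,cell_id]`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FILAMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values(["filament_id", "node_index"]).reset_index(drop=True)


def write_filaments(traces: pd.DataFrame, path) -> None:
    cols = [c for c in (*FILAMENT_COLUMNS, "cell_id") if c in traces.columns]
    traces[cols].to_csv(path, index=False)


@dataclass
class FilamentLengthStats:
    """Per-filament arc lengths (nm) with sample mean and SD (n−1)."""

    lengths_nm: pd.Series
    mean_nm: float
    sd_nm: float
    n: int


def filament_length_stats(traces: pd.DataFrame) -> FilamentLengthStats:
    """Arc length of each filament polyline plus sample statistics.

    Length is the sum of consecutive node-to-node Euclidean distances, so it
    is invariant under rigid motions of the node set and additive under
    concatenation of polylines.
    """
    if len(traces) == 0:
        raise ValueError("no filament traces")
    lengths = {}
    for fid, sub in traces.groupby("filament_id", sort=False):
        sub = sub.sort_values("node_index")
        if len(sub) < 2:
            raise ValueError(f"filament {fid!r} has fewer than 2 nodes")
        xy = sub[["x_nm", "y_nm"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError(f"filament {fid!r} has non-finite coordinates")
        seg = np.diff(xy, axis=0)
        lengths[fid] = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    series = pd.Series(lengths, name="length_nm")
    n = len(series)
    sd = float(series.std(ddof=1)) if n > 1 else float("nan")
    return FilamentLengthStats(
        lengths_nm=series, mean_nm=float(series.mean()), sd_nm=sd, n=n
    )


@dataclass
class PositiveFraction:
    """Fraction of positive cells with a 95% Wilson score interval."""

    fraction: float
    ci95_low: float
    ci95_high: float
    positives: int
    total: int


def positive_fraction(positives: int, total: int) -> PositiveFraction:
    """Fraction of e.g. pilus-carrying cells among those analyzed."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positives <= total:
        raise ValueError("require 0 <= positives <= total")
    low, high = proportion_confint(positives, total, alpha=0.05, method="wilson")
    return PositiveFraction(
        fraction=positives / total,
        ci95_low=float(low),
        ci95_high=float(high),
        positives=positives,
        total=total,
    )


def transformation_frequency(
    cfu_per_ml: float, viable_per_ml: float, dna_ug: float
) -> float:
    """Transformants per viable cell per μg DNA: (CFU/ml ÷ viable/ml) ÷ μg."""
    if cfu_per_ml < 0:
        raise ValueError("cfu_per_ml must be >= 0")
    if viable_per_ml <= 0:
        raise ValueError("viable_per_ml must be > 0")
    if dna_ug <= 0:
        raise ValueError("dna_ug must be > 0")
    return (cfu_per_ml / viable_per_ml) / dna_ug


def dye_mass(
    m_dna_ug: float,
    molar_mass_dna: float,
    molar_mass_fluor: float,
    excess: float = 10.0,
) -> float:
    """Fluorophore mass (μg) for labelling DNA at an N-fold molar excess.

    m_fluor = (m_DNA / M_DNA) · excess · M_fluor, with the conventional
    tenfold dye excess as default.
    """
    if m_dna_ug < 0:
        raise ValueError("m_dna_ug must be >= 0")
    if molar_mass_dna <= 0 or molar_mass_fluor <= 0:
        raise ValueError("molar masses must be > 0")
    if excess <= 0:
        raise ValueError("excess must be > 0")
    return m_dna_ug / molar_mass_dna * excess * molar_mass_fluor
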