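"""ENCC migration-wavefront speed estimation from cell-track tables, plus
wavefront shape metrics and proliferation density at the migratory front.

The wavefront at each frame is the most distal tracked cell; its advance is
summarized by an ordinary-least-squares slope in microns per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import regionprops

TRACK_COLUMNS = ("cell_id", "t", "x", "y")


class TrackError(ValueError):
    pass


@dataclass(frozen=True)
class SpeedEstimate:
    """Wavefront migration speed (um/min) with OLS standard error and r^2."""

    speed: float
    stderr: float
    r_squared: float
    n_frames: int


@dataclass(frozen=True)
class ShapeMetrics:
    """Area, moment-based major axis and roundness of a wavefront mask.

    Roundness = 4*area / (pi * major_axis^2): 1 for a disk, ->0 for an
    elongated streak.  Discretization can push it slightly above 1 for tiny
    masks.
    """

    area_px2: float
    major_axis_px: float
    roundness: float


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise TrackError(f"track table missing columns {missing}")
    if tracks.duplicated(subset=["cell_id", "t"]).any():
        raise TrackError("duplicate (cell_id, t) rows in track table")
    if (tracks["t"] < 0).any():
        raise TrackError("negative time points in track table")
    return tracks


def wavefront_series(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-frame wavefront position: the most distal (max x) cell per frame.

    Frames in which every cell was missed are simply absent from the series.
    """
    tracks = validate_tracks(tracks)
    series = (tracks.groupby("t", sort=True)["x"].max()
              .reset_index().rename(columns={"x": "x_front"}))
    if series["t"].nunique() < 3:
        raise TrackError("need at least 3 distinct time points")
    return series


def estimate_speed(series: pd.DataFrame) -> SpeedEstimate:
    """OLS wavefront speed in um/min from a (t [s], x_front [um]) series."""
    t = np.asarray(series["t"], dtype=float)
    x = np.asarray(series["x_front"], dtype=float)
    if len(t) < 3:
        raise TrackError("need at least 3 points")
    if np.ptp(t) == 0:
        raise TrackError("all time points identical; slope undefined")
    if np.ptp(x) == 0:
        # constant front: exact zero-slope fit
        return SpeedEstimate(speed=0.0, stderr=0.0, r_squared=1.0,
                             n_frames=len(t))
    fit = sps.linregress(t, x)
    return SpeedEstimate(speed=fit.slope * 60.0, stderr=fit.stderr * 60.0,
                         r_squared=fit.rvalue ** 2, n_frames=len(t))


def percent_change(reference_speed: float, test_speed: float) -> float:
    """Percent reduction of the test speed relative to the reference."""
    if reference_speed <= 0:
        raise ValueError("reference speed must be > 0")
    return 100.0 * (reference_speed - test_speed) / reference_speed


def shape_metrics(mask: np.ndarray) -> ShapeMetrics:
    """Shape metrics of a binary wavefront mask (all foreground pixels taken
    as one object; the major axis is that of the ellipse with matching second
    central moments)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    major = float(props.axis_major_length)
    roundness = 4.0 * area / (np.pi * major ** 2) if major > 0 else np.nan
    return ShapeMetrics(area_px2=area, major_axis_px=major, roundness=roundness)


def proliferation_density(positions_um: np.ndarray, marker_positive: np.ndarray,
                          window_um: float = 220.0,
                          anchor_um: float | None = None
                          ) -> tuple[int, int, float]:
    """Marker-positive and total cell counts in the distal wavefront window.

    The window extends ``window_um`` oralward from the most distal cell (or
    from an explicit ``anchor_um``).  Returns (marker+ count, total count,
    fraction); the fraction is NaN when the window holds no cells.
    """
    positions = np.asarray(positions_um, dtype=float)
    marker = np.asarray(marker_positive, dtype=bool)
    if positions.size == 0:
        raise ValueError("need at least one cell")
    if positions.shape != marker.shape:
        raise ValueError("positions and marker flags must align")
    anchor = float(positions.max()) if anchor_um is None else float(anchor_um)
    in_window = (positions <= anchor) & (positions >= anchor - window_um)
    total = int(in_window.sum())
    pos = int((marker & in_window).sum())
    fraction = pos / total if total > 0 else float("nan")
    return pos, total, fraction
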