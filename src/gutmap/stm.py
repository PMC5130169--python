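"""Spatiotemporal-map construction: gut segmentation, centerline extraction
and width profiling of a motility frame stack.

The map records gut WIDTH (local diameter, mm) over arc position x time;
contraction waves appear as slanted bands of reduced width.  One centerline is
computed per recording (on the temporal median frame) and reused for every
frame — larvae are anaesthetised and mounted, so the gut does not drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize


class SegmentationError(ValueError):
    pass


@dataclass
class FrameStack:
    """A motility recording: T x H x W intensities plus acquisition metadata."""

    frames: np.ndarray
    frame_rate: float       # frames/s
    pixel_size: float       # mm/pixel

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be T x H x W with T >= 2")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def median_frame(self) -> np.ndarray:
        return np.median(self.frames, axis=0)


@dataclass
class Centerline:
    """Ordered midline of the gut, oral end first.

    ``points`` are float (row, col) pixel coordinates; ``arc_length_mm`` is
    the cumulative arc length from the oral end, strictly increasing.
    """

    points: np.ndarray          # (N, 2) float, (row, col)
    arc_length_mm: np.ndarray   # (N,)
    pixel_size: float

    def __post_init__(self) -> None:
        if len(self.points) != len(self.arc_length_mm):
            raise ValueError("points and arc_length_mm lengths differ")
        if np.any(np.diff(self.arc_length_mm) <= 0):
            raise ValueError("arc_length must be strictly increasing")

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1] - self.arc_length_mm[0])

    def normals(self) -> np.ndarray:
        """Unit normals per point, from a smoothed tangent."""
        sm = ndimage.gaussian_filter1d(self.points, sigma=3.0, axis=0,
                                       mode="nearest")
        tang = np.gradient(sm, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tang = tang / norm
        return np.stack([-tang[:, 1], tang[:, 0]], axis=1)


@dataclass
class SpatioTemporalMap:
    """Gut width (mm) over position (rows) x time (columns)."""

    width: np.ndarray           # (P, T) mm, NaN = missing
    positions: np.ndarray       # (P,) mm arc length from oral end
    times: np.ndarray           # (T,) s
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        if self.width.shape != (len(self.positions), len(self.times)):
            raise ValueError("width dims inconsistent with positions/times")
        if np.nanmin(self.width) < 0:
            raise ValueError("widths must be >= 0")


@dataclass
class NormalizedSTM:
    """Fractional contraction C = 1 - width/baseline; baseline per position."""

    contraction: np.ndarray     # (P, T); >0 = narrowing, <0 = dilation
    baseline: np.ndarray        # (P,) mm
    positions: np.ndarray
    times: np.ndarray


# ---------------------------------------------------------------------------


def segment_gut(reference: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Segment the gut from a reference image (temporal mean or median).

    Global threshold (Otsu by default, or an explicit override) followed by
    keeping the largest connected foreground component.
    """
    ref = np.asarray(reference, dtype=float)
    if threshold is None:
        if np.ptp(ref) == 0:
            raise SegmentationError(
                "reference image is constant; pass an explicit threshold")
        threshold = threshold_otsu(ref)
    fg = ref > threshold
    if not fg.any():
        raise SegmentationError(
            "no foreground above threshold; override the threshold")
    labels = cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == np.argmax(sizes)


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest path through a skeleton via double BFS; prunes side branches."""
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise SegmentationError("empty skeleton")
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NEIGHBOURS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(src: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(coords), -1)
        parent = np.full(len(coords), -1)
        dist[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    d0, _ = bfs(0)
    u = int(np.argmax(d0))
    d1, parent = bfs(u)
    v = int(np.argmax(d1))
    path = [v]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return coords[path[::-1]]


def extract_centerline(mask: np.ndarray, pixel_size: float,
                       orientation: str = "auto",
                       smooth_sigma: float = 2.0) -> Centerline:
    """Extract the oral->anal centerline of a segmented gut.

    Skeletonizes the mask and keeps the longest skeleton path.  Orientation:
    ``"auto"`` puts position 0 at the wider end (the intestinal bulb is the
    wider compartment); ``"left"``/``"right"`` force the oral end to that
    image side.
    """
    skel = skeletonize(mask)
    path = _skeleton_longest_path(skel)

    # skeletons grow diagonal spurs into the tube-end corners; trim leading
    # and trailing points where the inscribed radius collapses
    dt = ndimage.distance_transform_edt(mask)
    radius = dt[tuple(path.T)]
    good = radius >= 0.8 * np.median(radius)
    lo = int(np.argmax(good))
    hi = len(good) - int(np.argmax(good[::-1]))
    path = path[lo:hi]
    if len(path) < 10:
        raise SegmentationError(
            f"skeleton path only {len(path)} px; gut not resolved")

    pts = path.astype(float)
    if orientation == "left":
        flip = pts[0, 1] > pts[-1, 1]
    elif orientation == "right":
        flip = pts[0, 1] < pts[-1, 1]
    elif orientation == "auto":
        # compare local tube radius (distance transform) near the two ends
        k = min(20, len(path))
        r_start = dt[tuple(path[:k].T)].mean()
        r_end = dt[tuple(path[-k:].T)].mean()
        flip = r_end > r_start
    else:
        raise ValueError(f"unknown orientation hint {orientation!r}")
    if flip:
        pts = pts[::-1]

    if smooth_sigma > 0:
        pts = ndimage.gaussian_filter1d(pts, sigma=smooth_sigma, axis=0,
                                        mode="nearest")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)]) * pixel_size
    keep = np.concatenate([[True], seg > 0])
    return Centerline(points=pts[keep], arc_length_mm=arc[keep],
                      pixel_size=pixel_size)


def resample_centerline(cl: Centerline, spacing_mm: float) -> Centerline:
    """Resample a centerline to uniform arc-length spacing."""
    n = max(int(np.floor(cl.length_mm / spacing_mm)) + 1, 2)
    arc = cl.arc_length_mm[0] + np.arange(n) * spacing_mm
    rows = np.interp(arc, cl.arc_length_mm, cl.points[:, 0])
    cols = np.interp(arc, cl.arc_length_mm, cl.points[:, 1])
    return Centerline(points=np.stack([rows, cols], axis=1),
                      arc_length_mm=arc, pixel_size=cl.pixel_size)


def _sampling_coords(cl: Centerline, max_halfwidth_px: float,
                     step_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Normal-line sample coordinates for every centerline point.

    Returns (coords, offsets): coords is (2, N, S) row/col positions, offsets
    the signed distances (px) along the normal.
    """
    offsets = np.arange(-max_halfwidth_px, max_halfwidth_px + step_px / 2,
                        step_px)
    normals = cl.normals()                              # (N, 2)
    pts = cl.points                                     # (N, 2)
    coords = pts[:, :, None] + normals[:, :, None] * offsets[None, None, :]
    return np.moveaxis(coords, 1, 0), offsets           # (2, N, S)


def _edge_cross(profile: np.ndarray, above: np.ndarray, center: int,
                threshold: float, direction: int) -> np.ndarray:
    """Sub-sample threshold-crossing offset index on one side of the center.

    Vectorised over rows: walks from the center outward (direction +1/-1) to
    the first below-threshold sample and linearly interpolates the crossing.
    Returns fractional sample indices; NaN where the run reaches the window
    edge (unbounded width, flagged missing by the caller).
    """
    n_rows, n_samp = profile.shape
    out = np.full(n_rows, np.nan)
    if direction > 0:
        scan = above[:, center:]
        first_below = np.argmin(scan, axis=1)           # 0 if none below
        has_below = ~scan.all(axis=1)
        idx = center + first_below                      # first below-threshold
        ok = has_below & (idx > 0)
        lo = profile[np.arange(n_rows), np.clip(idx - 1, 0, n_samp - 1)]
        hi = profile[np.arange(n_rows), np.clip(idx, 0, n_samp - 1)]
    else:
        scan = above[:, :center + 1][:, ::-1]
        first_below = np.argmin(scan, axis=1)
        has_below = ~scan.all(axis=1)
        idx = center - first_below
        ok = has_below & (idx < n_samp - 1)
        lo = profile[np.arange(n_rows), np.clip(idx + 1, 0, n_samp - 1)]
        hi = profile[np.arange(n_rows), np.clip(idx, 0, n_samp - 1)]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (lo - threshold) / (lo - hi)
    frac = np.clip(frac, 0.0, 1.0)
    cross = idx - direction + direction * frac
    out[ok] = cross[ok]
    return out


def measure_widths(frame: np.ndarray, cl: Centerline,
                   threshold: float | None = None,
                   max_halfwidth_px: float | None = None,
                   step_px: float = 1.0,
                   _coords_cache: tuple | None = None) -> np.ndarray:
    """Width profile (mm per centerline point) of one frame.

    Samples intensity along the local normal at each point; the width is the
    contiguous above-threshold extent containing the centerline point, with
    sub-pixel edges by linear interpolation.  Points whose normal leaves the
    image, whose center sample is below threshold, or whose run reaches the
    sampling window edge are flagged missing (NaN), never zero.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if np.ptp(frame) == 0:
            return np.full(len(cl.points), np.nan)
        threshold = 0.5 * (frame.max() + frame.min())
    if _coords_cache is not None:
        coords, offsets = _coords_cache
    else:
        if max_halfwidth_px is None:
            max_halfwidth_px = frame.shape[0] / 2
        coords, offsets = _sampling_coords(cl, max_halfwidth_px, step_px)

    n_pts, n_samp = coords.shape[1], coords.shape[2]
    inside = ((coords[0] >= 0) & (coords[0] <= frame.shape[0] - 1)
              & (coords[1] >= 0) & (coords[1] <= frame.shape[1] - 1))
    profile = ndimage.map_coordinates(frame, coords.reshape(2, -1), order=1,
                                      mode="constant", cval=np.nan
                                      ).reshape(n_pts, n_samp)
    above = (profile >= threshold) & inside
    center = n_samp // 2

    right = _edge_cross(profile, above, center, threshold, +1)
    left = _edge_cross(profile, above, center, threshold, -1)
    widths = (right - left) * step_px * cl.pixel_size
    widths[~above[:, center]] = np.nan
    return widths


def _fill_short_gaps(row: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap along one row."""
    out = row.copy()
    isnan = np.isnan(row)
    if not isnan.any() or isnan.all():
        return out
    idx = np.arange(len(row))
    # find NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start <= max_gap and start > 0 and stop < len(row):
            out[start:stop] = np.interp(idx[start:stop],
                                        [start - 1, stop], [row[start - 1], row[stop]])
    return out


def build_stm(stack: FrameStack, cl: Centerline,
              threshold: float | None = None,
              max_halfwidth_px: float | None = None,
              step_px: float = 1.0,
              max_gap_frames: int = 2,
              max_missing_fraction: float = 0.2) -> SpatioTemporalMap:
    """Build the width spatiotemporal map of a recording.

    One centerline is reused for all frames.  Missing widths are linearly
    interpolated along time for gaps of at most ``max_gap_frames``; longer
    gaps stay missing.  Raises if more than ``max_missing_fraction`` of the
    entries are missing before interpolation (bad segmentation).
    """
    if max_halfwidth_px is None:
        max_halfwidth_px = stack.frames.shape[1] / 2
    cache = _sampling_coords(cl, max_halfwidth_px, step_px)
    width = np.empty((len(cl.points), stack.n_frames))
    for j in range(stack.n_frames):
        width[:, j] = measure_widths(stack.frames[j], cl, threshold=threshold,
                                     _coords_cache=cache, step_px=step_px)
    # the extreme ends of the centerline can overshoot the measurable tube;
    # drop leading/trailing positions that are mostly unmeasurable
    row_missing = np.isnan(width).mean(axis=1)
    ok = row_missing <= 0.5
    lo = int(np.argmax(ok))
    hi = len(ok) - int(np.argmax(ok[::-1]))
    width = width[lo:hi]
    positions = cl.arc_length_mm[lo:hi].copy()

    missing = np.isnan(width).mean()
    if missing > max_missing_fraction:
        raise SegmentationError(
            f"{missing:.0%} of width samples missing; re-segment or adjust "
            "the threshold")
    for i in range(width.shape[0]):
        if np.isnan(width[i]).any():
            width[i] = _fill_short_gaps(width[i], max_gap_frames)
    return SpatioTemporalMap(width=width, positions=positions,
                             times=stack.times(), pixel_size=stack.pixel_size,
                             frame_rate=stack.frame_rate)


def normalize_stm(stm: SpatioTemporalMap) -> NormalizedSTM:
    """Normalize an STM to fractional contraction C = 1 - width/baseline.

    The baseline is the temporal median of width at each position — robust as
    long as contractions occupy a minority of frames at any given position.
    C > 0 marks narrowing (a contraction band), C < 0 dilation.
    """
    baseline = np.nanmedian(stm.width, axis=1)
    if np.any(~np.isfinite(baseline)) or np.any(baseline <= 0):
        raise ValueError("baseline width is zero or undefined at some position")
    contraction = 1.0 - stm.width / baseline[:, None]
    return NormalizedSTM(contraction=contraction, baseline=baseline,
                         positions=stm.positions, times=stm.times)
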