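"""Contraction-event detection on a normalized spatiotemporal map and the
derived motility metrics: frequency (waves per 1000 s), travel distance,
velocity, inter-contraction interval, bulb-pattern classification and the
per-larva contraction endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
STATIONARY = "stationary"


@dataclass
class ContractionEvent:
    """One detected contraction wave.

    The ridge is the per-frame position of maximal contraction within the
    event's connected component; the event's endpoints are the ridge extremes
    in time.  Velocity is the average speed over the total propagated
    distance: distance / duration.
    """

    onset: float          # s, first active frame
    offset: float         # s, last active frame
    start_pos: float      # mm, ridge position at onset
    end_pos: float        # mm, ridge position at offset
    direction: str        # anterograde | retrograde | stationary
    peak_C: float         # maximal fractional contraction
    ridge_times: np.ndarray = field(repr=False, default=None)
    ridge_positions: np.ndarray = field(repr=False, default=None)

    @property
    def distance(self) -> float:
        return abs(self.end_pos - self.start_pos)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def velocity(self) -> float:
        return self.distance / self.duration if self.duration > 0 else 0.0

    @property
    def most_anal_pos(self) -> float:
        return float(np.max(self.ridge_positions))


@dataclass(frozen=True)
class RegionSpec:
    """Bulb and intestine intervals (mm, oral->anal) and their junction.

    The junction is a soft anatomical boundary (waves commonly originate
    right at it), so membership tests expand each interval by
    ``boundary_tol_mm``.
    """

    bulb: tuple[float, float]
    intestine: tuple[float, float]
    boundary_tol_mm: float = 0.05

    def __post_init__(self) -> None:
        if not (self.bulb[0] <= self.bulb[1] <= self.intestine[0] <= self.intestine[1]):
            raise ValueError("regions must be disjoint and ordered oral->anal")

    @property
    def junction(self) -> float:
        return self.bulb[1]

    def in_bulb(self, pos: float) -> bool:
        t = self.boundary_tol_mm
        return self.bulb[0] - t <= pos <= self.bulb[1] + t

    def in_intestine(self, pos: float) -> bool:
        t = self.boundary_tol_mm
        return self.intestine[0] - t <= pos <= self.intestine[1] + t


@dataclass
class MotilitySummary:
    """Per-recording anterograde wave statistics plus bulb pattern.

    ``frequency`` is waves per 1000 s of recording.  Mean fields are NaN when
    no anterograde event was detected (frequency is then 0).
    """

    n_anterograde: int
    frequency: float            # waves / 1000 s
    mean_distance: float        # mm
    mean_velocity: float        # mm/s
    mean_interval: float        # s, onset-to-onset
    bulb_pattern: str           # cyclical | continuous | absent
    endpoint: float             # mm, per-larva median of event endpoints

    def to_dict(self) -> dict:
        return {
            "n_anterograde": self.n_anterograde,
            "frequency_per_1000s": self.frequency,
            "mean_distance_mm": self.mean_distance,
            "mean_velocity_mm_s": self.mean_velocity,
            "mean_interval_s": self.mean_interval,
            "bulb_pattern": self.bulb_pattern,
            "endpoint_mm": self.endpoint,
        }


# ---------------------------------------------------------------------------


def regions_from_baseline(nstm, smooth_bins: int = 15) -> RegionSpec:
    """Locate the bulb/intestine junction from the relaxed calibre profile.

    The intestinal bulb is the wide rostral compartment; the junction is
    taken where the (smoothed) relaxed-width profile first drops below the
    midpoint between the bulb and intestine calibres.  The relaxed profile is
    the 90th temporal percentile of width — unlike the median it stays at the
    resting diameter even where churning occupies most of the recording.
    Falls back to the oral quarter of the map if there is no calibre step.
    """
    from scipy import ndimage

    pos = nstm.positions
    width = nstm.baseline[:, None] * (1.0 - nstm.contraction)
    relaxed = np.nanquantile(width, 0.9, axis=1)
    b = ndimage.uniform_filter1d(relaxed.astype(float), smooth_bins,
                                 mode="nearest")
    hi, lo = np.percentile(b, 95), np.percentile(b, 5)
    if hi - lo < 0.05 * hi:                       # no visible compartment step
        junction = pos[0] + 0.25 * (pos[-1] - pos[0])
    else:
        below = np.flatnonzero(b <= 0.5 * (hi + lo))
        junction = pos[below[0]] if below.size else pos[len(pos) // 4]
    return RegionSpec(bulb=(float(pos[0]), float(junction)),
                      intestine=(float(junction), float(pos[-1])))


def classify_direction(ridge_times: np.ndarray, ridge_positions: np.ndarray,
                       dead_band_mm: float) -> str:
    """Direction of one event from a least-squares fit of its ridge.

    Total displacements smaller than the dead band are called stationary
    (localized, non-propagating contraction); otherwise the sign of the
    fitted slope decides anterograde (oral->anal) vs retrograde.
    """
    if len(ridge_times) < 2:
        return STATIONARY
    if abs(ridge_positions[-1] - ridge_positions[0]) < dead_band_mm:
        return STATIONARY
    slope = np.polyfit(ridge_times, ridge_positions, 1)[0]
    if slope > 0:
        return ANTEROGRADE
    if slope < 0:
        return RETROGRADE
    return STATIONARY


def detect_events(nstm, threshold: float = 0.10,
                  min_duration_s: float | None = None,
                  min_extent_mm: float = 0.05,
                  dead_band_mm: float | None = None) -> list[ContractionEvent]:
    """Detect contraction events on a normalized STM.

    Binarizes C >= threshold, labels 8-connected components in
    (position, time), extracts each component's ridge (per-frame position of
    maximal C), and keeps components lasting at least ``min_duration_s`` with
    a spatial extent of at least ``min_extent_mm``.  An empty list is a valid
    result.
    """
    C = nstm.contraction
    times = nstm.times
    positions = nstm.positions
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    bin_mm = float(np.median(np.diff(positions))) if len(positions) > 1 else 1.0
    if min_duration_s is None:
        min_duration_s = 2 * dt
    if dead_band_mm is None:
        dead_band_mm = 3 * bin_mm

    active = np.nan_to_num(C, nan=0.0) >= threshold
    labels = cc_label(active, connectivity=2)
    events: list[ContractionEvent] = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        t_idx = np.flatnonzero(comp.any(axis=0))
        if (t_idx[-1] - t_idx[0]) * dt < min_duration_s:
            continue
        # ridge: per active frame, position of maximal C within the component
        masked = np.where(comp, np.nan_to_num(C, nan=-np.inf), -np.inf)
        ridge_rows = np.argmax(masked[:, t_idx], axis=0)
        ridge_pos = positions[ridge_rows]
        ridge_t = times[t_idx]
        p_idx = np.flatnonzero(comp.any(axis=1))
        extent = positions[p_idx[-1]] - positions[p_idx[0]]
        if extent < min_extent_mm:
            continue
        direction = classify_direction(ridge_t, ridge_pos, dead_band_mm)
        events.append(ContractionEvent(
            onset=float(ridge_t[0]), offset=float(ridge_t[-1]),
            start_pos=float(ridge_pos[0]), end_pos=float(ridge_pos[-1]),
            direction=direction,
            peak_C=float(np.max(masked[:, t_idx])),
            ridge_times=ridge_t, ridge_positions=ridge_pos))
    events.sort(key=lambda e: e.onset)
    return events


def endpoint_position(events: list[ContractionEvent]) -> float:
    """Per-larva contraction endpoint: median over anterograde events of the
    most anal ridge position.  NaN when there is no anterograde event."""
    ends = [e.most_anal_pos for e in events if e.direction == ANTEROGRADE]
    if not ends:
        return math.nan
    return float(np.median(ends))


def assess_bulb_pattern(bulb_events: list[ContractionEvent],
                        recording_duration_s: float,
                        continuous_duty: float = 0.8,
                        cyclical_cv: float = 0.5,
                        min_cyclical_events: int = 3) -> str:
    """Classify bulb motility as cyclical, continuous or absent.

    Duty cycle = fraction of the recording covered by the union of bulb-event
    active windows; at or above ``continuous_duty`` the pattern is continuous.
    Otherwise at least ``min_cyclical_events`` retrograde events whose
    onset-interval coefficient of variation is at most ``cyclical_cv`` make it
    cyclical; anything else is absent.
    """
    if not bulb_events:
        return "absent"
    windows = sorted((e.onset, e.offset) for e in bulb_events)
    covered, cur_start, cur_end = 0.0, windows[0][0], windows[0][1]
    for s, e in windows[1:]:
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start
    if covered / recording_duration_s >= continuous_duty:
        return "continuous"
    retro = sorted(e.onset for e in bulb_events if e.direction == RETROGRADE)
    if len(retro) >= min_cyclical_events:
        gaps = np.diff(retro)
        cv = np.std(gaps) / np.mean(gaps) if np.mean(gaps) > 0 else np.inf
        if cv <= cyclical_cv:
            return "cyclical"
    return "absent"


def summarize_motility(events: list[ContractionEvent], regions: RegionSpec,
                       recording_duration_s: float) -> MotilitySummary:
    """Per-recording motility summary over anterograde intestinal waves.

    Frequency is reported in waves per 1000 s over the full recording
    duration; velocity is computed per event (distance/duration) and then
    averaged; the interval is the mean onset-to-onset gap of consecutive
    anterograde events.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be > 0")
    antero = [e for e in events
              if e.direction == ANTEROGRADE and regions.in_intestine(e.start_pos)]
    bulb = [e for e in events if regions.in_bulb(e.start_pos)]
    n = len(antero)
    frequency = n / recording_duration_s * 1000.0
    if n == 0:
        dist = vel = interval = math.nan
    else:
        dist = float(np.mean([e.distance for e in antero]))
        vel = float(np.mean([e.velocity for e in antero]))
        onsets = sorted(e.onset for e in antero)
        interval = float(np.mean(np.diff(onsets))) if n >= 2 else math.nan
    return MotilitySummary(
        n_anterograde=n, frequency=frequency, mean_distance=dist,
        mean_velocity=vel, mean_interval=interval,
        bulb_pattern=assess_bulb_pattern(bulb, recording_duration_s),
        endpoint=endpoint_position(antero))
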