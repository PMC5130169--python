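"""Ground-truth simulators for larval-gut motility recordings, ENCC migration
tracks, and enteric-neuron phenotype cohorts.

The motility simulator models the gut as a tapering tube whose local diameter
is transiently reduced by travelling contraction waves.  Each wave is a spatial
Gaussian notch of fractional amplitude that advances at constant velocity, so
the resulting width kymograph shows the familiar slanted bands of a
spatiotemporal map.  Every generator is a pure function of (config, seed) and
returns the realized ground truth alongside the simulated output, so each
downstream measurement stage can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"

#: fraction of the resting diameter below which a contraction cannot close
#: the lumen further (the gut wall never collapses completely)
MIN_DIAMETER_FRACTION = 0.1


class SimulationError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass(frozen=True)
class WaveSpec:
    """One travelling contraction wave.

    Positions are millimetres of arc length from the oral end; anterograde
    waves travel toward increasing position (oral to anal).
    """

    direction: str               # "anterograde" | "retrograde"
    onset_time: float            # s
    origin_pos: float            # mm from oral end
    velocity: float              # mm/s, > 0
    travel_distance: float       # mm, > 0
    amplitude: float             # fractional diameter reduction, (0, 1]
    half_width: float            # mm, spatial Gaussian sigma

    def __post_init__(self) -> None:
        if self.direction not in (ANTEROGRADE, RETROGRADE):
            raise SimulationError(f"unknown wave direction {self.direction!r}")
        if self.velocity <= 0:
            raise SimulationError("wave velocity must be > 0")
        if self.travel_distance <= 0:
            raise SimulationError("wave travel_distance must be > 0")
        if not (0 < self.amplitude <= 1):
            raise SimulationError("wave amplitude must be in (0, 1]")
        if self.half_width <= 0:
            raise SimulationError("wave half_width must be > 0")

    @property
    def sign(self) -> int:
        return 1 if self.direction == ANTEROGRADE else -1

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.travel_distance / self.velocity

    @property
    def end_pos(self) -> float:
        return self.origin_pos + self.sign * self.travel_distance

    def center_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Wave-centre position at time(s) ``t`` (valid while active)."""
        return self.origin_pos + self.sign * self.velocity * (np.asarray(t) - self.onset_time)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GutGeometry:
    """Static geometry of the two-compartment gut.

    The rostral intestinal bulb is wider than the intestine; the junction sits
    at ``bulb_fraction * length_mm`` from the oral end and the resting-diameter
    profile blends smoothly between the two calibres over ``taper_mm``.
    """

    length_mm: float = 3.2
    bulb_fraction: float = 0.25
    bulb_diameter_mm: float = 0.35
    intestine_diameter_mm: float = 0.20
    taper_mm: float = 0.15
    pixel_size_mm: float = 0.00625        # 6.25 um/px
    frame_height_px: int = 128

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.pixel_size_mm <= 0:
            raise SimulationError("length and pixel size must be > 0")
        if not (0 < self.bulb_fraction < 1):
            raise SimulationError("bulb_fraction must be in (0, 1)")
        if min(self.bulb_diameter_mm, self.intestine_diameter_mm) <= 0:
            raise SimulationError("diameters must be > 0")

    @property
    def junction_mm(self) -> float:
        """Arc position of the intestinal bulb / intestine junction."""
        return self.bulb_fraction * self.length_mm

    @property
    def n_columns(self) -> int:
        return int(round(self.length_mm / self.pixel_size_mm))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height_px, self.n_columns)

    def positions(self) -> np.ndarray:
        """Arc positions (mm) of the kymograph bins: one per image column."""
        return (np.arange(self.n_columns) + 0.5) * self.pixel_size_mm

    def resting_diameter(self, x: np.ndarray | float) -> np.ndarray:
        """Resting diameter profile D0(x) in mm (bulb wider than intestine)."""
        x = np.asarray(x, dtype=float)
        # logistic blend from bulb to intestine calibre around the junction
        z = (x - self.junction_mm) / max(self.taper_mm, 1e-9)
        s = 1.0 / (1.0 + np.exp(-4.0 * z))
        return self.bulb_diameter_mm + (self.intestine_diameter_mm - self.bulb_diameter_mm) * s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MotilitySimConfig:
    """Parameters of one simulated motility recording.

    Defaults follow the acquisition settings of the recordings this package
    analyses: 400 s at 2.5 frames/s.  ``waves=None`` generates a periodic
    wild-type-like pattern (anterograde intestinal peristalsis plus cyclical
    retrograde churning confined to the bulb).
    """

    geometry: GutGeometry = field(default_factory=GutGeometry)
    waves: tuple[WaveSpec, ...] | None = None
    anterograde_period_s: float = 50.0
    retrograde_period_s: float = 40.0
    duration_s: float = 400.0
    frame_rate: float = 2.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * self.frame_rate < 2:
            raise SimulationError("recording must span at least 2 frames")
        if self.frame_rate <= 0:
            raise SimulationError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class MigrationSimConfig:
    """Parameters of a simulated ENCC migration time-lapse.

    The default frame interval matches the confocal acquisition the track
    format was designed for (374 s between z-stacks).
    """

    true_speed_um_min: float = 1.2
    n_cells: int = 10
    frame_interval_s: float = 374.0
    duration_s: float = 8 * 3600.0
    position_noise_sd_um: float = 0.0
    dropout_prob: float = 0.0
    x0_um: float = 100.0
    trail_span_um: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_speed_um_min < 0:
            raise SimulationError("true_speed must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise SimulationError("dropout_prob must be in [0, 1)")
        if self.n_cells < 1:
            raise SimulationError("need at least one cell")

    @property
    def n_frames(self) -> int:
        return int(self.duration_s // self.frame_interval_s) + 1


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a genotype label plus its phenotype distributions.

    ``count_dist`` is either ``("normal", mu, sigma)`` or
    ``("mixture", w, mu1, sigma1, mu2, sigma2)`` for distal neuron counts
    (mixtures emulate modifier-genotype cohorts with a severe subpopulation).
    ``last_pos_dist`` is ``(mu, sigma)`` of the most-distal neuron position in
    somite-lengths from the anal pore, truncated at 0.
    """

    label: str
    count_dist: tuple
    last_pos_dist: tuple[float, float] = (1.0, 0.8)
    endpoint_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        kind = self.count_dist[0]
        if kind == "normal":
            _, mu, sigma = self.count_dist
            if sigma <= 0:
                raise SimulationError("sigma must be > 0")
        elif kind == "mixture":
            _, w, mu1, s1, mu2, s2 = self.count_dist
            if not (0 <= w <= 1):
                raise SimulationError("mixture weight must be in [0, 1]")
            if s1 <= 0 or s2 <= 0:
                raise SimulationError("sigma must be > 0")
        else:
            raise SimulationError(f"unknown count distribution {kind!r}")


def wt_like_group(label: str = "wt", endpoint_noise_sd: float = 0.0) -> GroupSpec:
    """Wild-type-like group: unimodal distal counts, neurons to the anal pore."""
    return GroupSpec(label, ("normal", 137.0, 17.0), (0.5, 0.3), endpoint_noise_sd)


def modifier_like_group(label: str = "modifier", endpoint_noise_sd: float = 0.0) -> GroupSpec:
    """Modifier-genotype-like group: bimodal counts with a severe component."""
    return GroupSpec(label, ("mixture", 0.5, 10.0, 5.0, 70.0, 5.0), (4.0, 2.0),
                     endpoint_noise_sd)


def ret_het_like_group(label: str = "ret_het") -> GroupSpec:
    """Sensitized-heterozygote-like group: unimodal distal counts with a
    small severe tail (roughly one larva in ten below 24 neurons)."""
    return GroupSpec(label, ("normal", 37.0, 10.0), (3.0, 1.5))


def ret_het_modifier_group(label: str = "ret_het_modifier") -> GroupSpec:
    """Heterozygote with homozygous modifier loss: an even mixture of the
    heterozygote distribution and a severely affected component, so about
    half the larvae fall below the 24-neuron severity threshold."""
    return GroupSpec(label, ("mixture", 0.5, 10.0, 5.0, 37.0, 10.0), (5.0, 2.0))


@dataclass(frozen=True)
class CohortSimConfig:
    groups: tuple[GroupSpec, ...]
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SimulationError("n_per_group must be >= 1")
        if len(self.groups) < 1:
            raise SimulationError("need at least one group")


@dataclass
class SimGroundTruth:
    """Everything a simulation realized, for recovery testing."""

    waves: list[WaveSpec] = field(default_factory=list)
    kymograph: np.ndarray | None = None      # positions x frames, mm
    positions: np.ndarray | None = None      # mm
    times: np.ndarray | None = None          # s
    tracks: pd.DataFrame | None = None       # true (noiseless) cell tracks
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# motility


def default_wave_set(cfg: MotilitySimConfig) -> list[WaveSpec]:
    """Periodic wild-type-like wave pattern for the configured recording."""
    g = cfg.geometry
    waves: list[WaveSpec] = []
    junction = g.junction_mm
    t = 10.0
    while t < cfg.duration_s - 1.0:
        waves.append(WaveSpec(ANTEROGRADE, onset_time=t, origin_pos=junction,
                              velocity=0.05, travel_distance=0.55 * g.length_mm,
                              amplitude=0.5, half_width=0.10))
        t += cfg.anterograde_period_s
    t = 5.0
    while t < cfg.duration_s - 1.0:
        waves.append(WaveSpec(RETROGRADE, onset_time=t, origin_pos=0.55 * junction,
                              velocity=0.03, travel_distance=0.4 * junction,
                              amplitude=0.4, half_width=0.06))
        t += cfg.retrograde_period_s
    return waves


def _validate_waves(waves: Sequence[WaveSpec], geometry: GutGeometry,
                    duration_s: float) -> None:
    for i, w in enumerate(waves):
        if not (0 <= w.origin_pos <= geometry.length_mm):
            raise SimulationError(
                f"wave {i} ({w.direction}, onset {w.onset_time:g} s) starts at "
                f"{w.origin_pos:g} mm, outside the gut [0, {geometry.length_mm:g}] mm")
        if not (0 <= w.end_pos <= geometry.length_mm):
            raise SimulationError(
                f"wave {i} ({w.direction}, onset {w.onset_time:g} s) would end at "
                f"{w.end_pos:g} mm, outside the gut [0, {geometry.length_mm:g}] mm")
        if w.onset_time < 0 or w.offset_time > duration_s:
            raise SimulationError(
                f"wave {i} active window [{w.onset_time:g}, {w.offset_time:g}] s "
                f"exceeds the recording [0, {duration_s:g}] s")


def simulate_kymograph(cfg: MotilitySimConfig) -> tuple[np.ndarray, SimGroundTruth]:
    """Simulate the ground-truth width kymograph of one recording.

    Returns ``(width, truth)`` where ``width`` is a positions x frames matrix
    in mm:  ``width(x, t) = D0(x) * (1 - sum_i a_i * G(x - x_i(t)))`` while
    wave *i* is active, clipped below at ``0.1 * D0(x)``.
    """
    waves = list(cfg.waves) if cfg.waves is not None else default_wave_set(cfg)
    _validate_waves(waves, cfg.geometry, cfg.duration_s)

    x = cfg.geometry.positions()                      # (P,)
    t = cfg.times()                                   # (T,)
    d0 = cfg.geometry.resting_diameter(x)             # (P,)
    reduction = np.zeros((x.size, t.size))
    for w in waves:
        active = (t >= w.onset_time) & (t <= w.offset_time)
        if not active.any():
            continue
        xc = w.center_at(t[active])                   # (Ta,)
        g = np.exp(-((x[:, None] - xc[None, :]) ** 2) / (2.0 * w.half_width ** 2))
        reduction[:, active] += w.amplitude * g
    width = d0[:, None] * (1.0 - reduction)
    width = np.maximum(width, MIN_DIAMETER_FRACTION * d0[:, None])

    truth = SimGroundTruth(waves=waves, kymograph=width, positions=x, times=t,
                           params={"config": _config_dict(cfg), "seed": cfg.seed})
    return width, truth


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def render_frames(kymograph: np.ndarray, geometry: GutGeometry,
                  noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render a frame stack (T x H x W, float32) from a width kymograph.

    Each frame draws the gut as a bright horizontal tube (intensity 1.0) on a
    dark background (0.0); the vertical extent at column *j* equals
    ``kymograph[j, t] / pixel_size``.  Identical (kymograph, seed) gives a
    bit-identical stack.
    """
    width_px = kymograph / geometry.pixel_size_mm     # (P, T)
    if np.any(width_px < 1.0):
        raise SimulationError(
            "tube narrower than 1 pixel somewhere; use a smaller pixel_size")
    n_pos, n_frames = kymograph.shape
    height = geometry.frame_height_px
    if np.any(width_px > height):
        raise SimulationError("tube wider than the frame; increase frame height")
    center = (height - 1) / 2.0
    rows = np.arange(height, dtype=float)
    # frame[r, c] = 1 where |r - center| <= width/2
    half = width_px.T[:, None, :] / 2.0               # (T, 1, P)
    stack = (np.abs(rows[None, :, None] - center) <= half).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)
    return stack


def simulate_motility_recording(cfg: MotilitySimConfig
                                ) -> tuple[np.ndarray, SimGroundTruth]:
    """Full pipeline: kymograph plus rendered frame stack."""
    width, truth = simulate_kymograph(cfg)
    stack = render_frames(width, cfg.geometry, cfg.noise_sd, cfg.seed)
    return stack, truth


def random_wave_set(rng: np.random.Generator, geometry: GutGeometry,
                    duration_s: float, n_waves: int,
                    velocity_range: tuple[float, float] = (0.01, 0.1),
                    amplitude_range: tuple[float, float] = (0.2, 0.6),
                    direction: str = ANTEROGRADE,
                    half_width: float = 0.08,
                    gap_s: float = 6.0,
                    min_travel_s: float = 20.0) -> list[WaveSpec]:
    """Draw up to ``n_waves`` sequential non-overlapping waves for recovery
    testing.

    Waves are scheduled one after another with at least ``gap_s`` between the
    offset of one and the onset of the next, emulating the sequential nature
    of peristalsis and keeping detected events separable.  Each wave persists
    for at least ``min_travel_s`` so its kinematics are resolvable at typical
    frame rates; the per-wave velocity is capped accordingly where the
    compartment is short (retrograde bulb waves).  ``direction`` may also be
    ``"mixed"`` for an even random choice per wave.
    """
    waves = []
    t = gap_s
    junction = geometry.junction_mm
    for _ in range(n_waves):
        d = direction
        if direction == "mixed":
            d = ANTEROGRADE if rng.random() < 0.5 else RETROGRADE
        if d == ANTEROGRADE:
            origin = rng.uniform(junction, junction + 0.2)
            max_dist = geometry.length_mm - origin - 0.1
        else:
            origin = rng.uniform(0.6 * junction, 0.9 * junction)
            max_dist = origin - 0.05
        v_hi = min(velocity_range[1], max_dist / min_travel_s)
        v = rng.uniform(velocity_range[0], max(v_hi, velocity_range[0]))
        a = rng.uniform(*amplitude_range)
        dist = rng.uniform(max(0.4 * max_dist, v * min_travel_s), max_dist)
        w = WaveSpec(d, onset_time=t, origin_pos=origin, velocity=v,
                     travel_distance=dist, amplitude=a, half_width=half_width)
        if w.offset_time > duration_s - gap_s:
            break
        waves.append(w)
        t = w.offset_time + gap_s
    return waves


# ---------------------------------------------------------------------------
# migration


def simulate_migration(cfg: MigrationSimConfig) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Simulate an ENCC track table with a linearly advancing lead cell.

    The lead cell advances at ``true_speed_um_min``; trailing cells keep
    random (noiseless) offsets strictly behind it.  Rows are dropped
    independently with ``dropout_prob`` to emulate missed detections.
    Returns a table with columns ``cell_id, t, x, y`` (t in s, x/y in um).
    """
    if cfg.n_frames < 3:
        raise SimulationError(
            "fewer than 3 frames: wavefront slope is unidentifiable")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s
    lead = cfg.x0_um + cfg.true_speed_um_min * t / 60.0
    offsets = np.concatenate([[0.0],
                              np.sort(rng.uniform(1.0, cfg.trail_span_um,
                                                  cfg.n_cells - 1))])
    true_x = lead[None, :] - offsets[:, None]          # (cells, frames)
    y = rng.uniform(-20.0, 20.0, cfg.n_cells)

    rows = []
    for i in range(cfg.n_cells):
        for j in range(cfg.n_frames):
            rows.append((i, t[j], true_x[i, j], y[i]))
    df = pd.DataFrame(rows, columns=["cell_id", "t", "x", "y"])
    true_df = df.copy()

    if cfg.position_noise_sd_um > 0:
        df["x"] = df["x"] + rng.normal(0.0, cfg.position_noise_sd_um, len(df))
    if cfg.dropout_prob > 0:
        keep = rng.random(len(df)) >= cfg.dropout_prob
        df = df[keep].reset_index(drop=True)

    truth = SimGroundTruth(tracks=true_df,
                           params={"config": _config_dict(cfg), "seed": cfg.seed})
    return df, truth


# ---------------------------------------------------------------------------
# cohorts


def _draw_counts(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist[0] == "normal":
        _, mu, sigma = dist
        raw = rng.normal(mu, sigma, n)
    else:
        _, w, mu1, s1, mu2, s2 = dist
        pick = rng.random(n) < w
        raw = np.where(pick, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
    return np.maximum(np.round(raw), 0).astype(int)


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Simulate a per-larva phenotype table.

    Each larva gets a genotype label, a distal neuron count drawn from its
    group's distribution (truncated at zero and rounded), a most-distal-neuron
    position (somite-lengths from the anal pore, truncated at 0) and a
    contraction endpoint tied to that position plus Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    next_id = 0
    for grp in cfg.groups:
        counts = _draw_counts(grp.count_dist, cfg.n_per_group, rng)
        mu, sigma = grp.last_pos_dist
        last_pos = np.maximum(rng.normal(mu, sigma, cfg.n_per_group), 0.0)
        endpoint = last_pos.copy()
        if grp.endpoint_noise_sd > 0:
            endpoint = endpoint + rng.normal(0.0, grp.endpoint_noise_sd,
                                             cfg.n_per_group)
        frames.append(pd.DataFrame({
            "larva_id": np.arange(next_id, next_id + cfg.n_per_group),
            "genotype": grp.label,
            "distal_count": counts,
            "last_neuron_pos": last_pos,
            "endpoint": endpoint,
        }))
        next_id += cfg.n_per_group
    table = pd.concat(frames, ignore_index=True)
    truth = SimGroundTruth(params={"config": _config_dict(cfg), "seed": cfg.seed})
    return table, truth
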