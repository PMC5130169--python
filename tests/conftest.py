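import numpy as np
import pytest

from gutmap import simulate, stm


@pytest.fixture(scope="session")
def small_geometry():
    """Half-length gut at full resolution: fast to render and measure."""
    return simulate.GutGeometry(length_mm=1.6, frame_height_px=64,
                                bulb_diameter_mm=0.25,
                                intestine_diameter_mm=0.15)


@pytest.fixture(scope="session")
def single_wave(small_geometry):
    return simulate.WaveSpec("anterograde", onset_time=10.0,
                             origin_pos=0.5, velocity=0.05,
                             travel_distance=0.9, amplitude=0.4,
                             half_width=0.08)


@pytest.fixture(scope="session")
def single_wave_recording(small_geometry, single_wave):
    """Noiseless 60 s recording with one anterograde wave."""
    cfg = simulate.MotilitySimConfig(geometry=small_geometry,
                                     waves=(single_wave,), duration_s=60.0,
                                     seed=3)
    frames, truth = simulate.simulate_motility_recording(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def recovered_stm(single_wave_recording):
    """Segment -> centerline -> STM of the single-wave recording."""
    cfg, frames, truth = single_wave_recording
    stack = stm.FrameStack(frames=frames, frame_rate=cfg.frame_rate,
                           pixel_size=cfg.geometry.pixel_size_mm)
    mask = stm.segment_gut(stack.median_frame())
    cl = stm.extract_centerline(mask, stack.pixel_size)
    return stack, cl, stm.build_stm(stack, cl), truth


def kymograph_as_nstm(kymograph, positions, times):
    """Wrap a ground-truth kymograph as a normalized STM (median baseline)."""
    m = stm.SpatioTemporalMap(width=kymograph, positions=positions,
                              times=times, pixel_size=positions[1] - positions[0],
                              frame_rate=1.0 / (times[1] - times[0]))
    return stm.normalize_stm(m)
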