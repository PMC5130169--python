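"""File I/O: frame stacks (multi-page TIFF), STM matrices (TSV + JSON
sidecar), event/track/cohort tables (CSV), configs (YAML) and reports (JSON).

Acquisition metadata (frame rate, pixel size) is never silently defaulted:
loading a stack fails unless the values are present in the file or supplied
explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stm import FrameStack, SpatioTemporalMap
from .waves import ContractionEvent

EVENT_COLUMNS = ["onset_s", "offset_s", "start_pos_mm", "end_pos_mm",
                 "direction", "distance_mm", "duration_s", "velocity_mm_s",
                 "peak_C", "most_anal_pos_mm"]


class MetadataError(ValueError):
    pass


def write_stack(path, stack: FrameStack) -> None:
    """Write a frame stack as multi-page TIFF with embedded metadata."""
    meta = {"frame_rate": stack.frame_rate, "pixel_size": stack.pixel_size}
    tifffile.imwrite(str(path), stack.frames,
                     description=json.dumps({"gutmap": meta}))


def load_frames(path, frame_rate: float | None = None,
                pixel_size: float | None = None) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of frames.

    Metadata embedded by :func:`write_stack` is honoured; explicit arguments
    override it.  Missing frame_rate or pixel_size is a hard error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no frame files in {path}")
        frames = [tifffile.imread(str(f)) if f.suffix.lower() in (".tif", ".tiff")
                  else np.asarray(_read_image(f)) for f in files]
        shapes = {f.name: a.shape for f, a in zip(files, frames)}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"inconsistent frame dimensions: {shapes}")
        arr = np.stack(frames)
    else:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = _parse_meta(desc)
        if frame_rate is None:
            frame_rate = meta.get("frame_rate")
        if pixel_size is None:
            pixel_size = meta.get("pixel_size")
    if frame_rate is None or pixel_size is None:
        raise MetadataError(
            "frame_rate and pixel_size must be embedded in the file or "
            "given explicitly; refusing to guess")
    return FrameStack(frames=arr, frame_rate=float(frame_rate),
                      pixel_size=float(pixel_size))


def _read_image(path):
    import imageio.v3 as iio
    return iio.imread(str(path))


def _parse_meta(description: str) -> dict:
    try:
        return json.loads(description).get("gutmap", {})
    except (json.JSONDecodeError, AttributeError):
        return {}


# ---------------------------------------------------------------------------
# STM


def write_stm(prefix, stm: SpatioTemporalMap) -> None:
    """Write an STM as `<prefix>.tsv` (rows = positions) plus a JSON sidecar
    `<prefix>.json` with the axes and acquisition metadata."""
    prefix = Path(prefix)
    np.savetxt(str(prefix.with_suffix(".tsv")), stm.width, delimiter="\t",
               fmt="%.17g")
    sidecar = {"positions_mm": stm.positions.tolist(),
               "times_s": stm.times.tolist(),
               "pixel_size": stm.pixel_size,
               "frame_rate": stm.frame_rate}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_stm(prefix) -> SpatioTemporalMap:
    prefix = Path(prefix)
    width = np.loadtxt(str(prefix.with_suffix(".tsv")), delimiter="\t", ndmin=2)
    side = json.loads(prefix.with_suffix(".json").read_text())
    return SpatioTemporalMap(width=width,
                             positions=np.asarray(side["positions_mm"]),
                             times=np.asarray(side["times_s"]),
                             pixel_size=side["pixel_size"],
                             frame_rate=side["frame_rate"])


def save_stm_png(path, stm: SpatioTemporalMap) -> None:
    """Render an STM image: time on the horizontal axis, oral end at top,
    darker = narrower (contraction bands show dark)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(stm.width, aspect="auto", cmap="gray",
                   extent=[stm.times[0], stm.times[-1],
                           stm.positions[-1], stm.positions[0]])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position from oral end (mm)")
    fig.colorbar(im, ax=ax, label="gut width (mm)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# tables


def events_to_dataframe(events: list[ContractionEvent]) -> pd.DataFrame:
    rows = [{"onset_s": e.onset, "offset_s": e.offset,
             "start_pos_mm": e.start_pos, "end_pos_mm": e.end_pos,
             "direction": e.direction, "distance_mm": e.distance,
             "duration_s": e.duration, "velocity_mm_s": e.velocity,
             "peak_C": e.peak_C, "most_anal_pos_mm": e.most_anal_pos}
            for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(path, events: list[ContractionEvent]) -> None:
    events_to_dataframe(events).to_csv(path, index=False, float_format="%.10g")


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configs / reports


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                                     allow_nan=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(obj), sort_keys=True))
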