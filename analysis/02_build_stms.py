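"""Build spatiotemporal width maps for the simulated recordings.

Reads the frame stacks written by 01_simulate_recordings.py, segments the
gut on the temporal median frame, extracts one centerline per recording and
measures the width profile on every frame.  Large STM matrices go to
scratch/ (TSV); per-recording provenance goes to results/.
"""

import json
from pathlib import Path

import numpy as np

from gutmap import io, stm

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    (SCRATCH / "stm").mkdir(parents=True, exist_ok=True)
    meta = {}
    for tif in sorted((SCRATCH / "recordings").glob("*.tif")):
        name = tif.stem
        stack = io.load_frames(tif)
        mask = stm.segment_gut(stack.median_frame())
        cl = stm.extract_centerline(mask, stack.pixel_size)
        m = stm.build_stm(stack, cl)
        io.write_stm(SCRATCH / "stm" / name, m)
        io.save_stm_png(SCRATCH / "stm" / f"{name}.png", m)
        meta[name] = {
            "n_positions": int(m.width.shape[0]),
            "n_frames": int(m.width.shape[1]),
            "gut_length_mm": round(float(cl.length_mm), 4),
            "median_width_mm": round(float(np.nanmedian(m.width)), 4),
            "missing_fraction": round(float(np.isnan(m.width).mean()), 5),
        }
        print(f"{name}: {meta[name]}")
    (RESULTS / "stm_provenance.json").write_text(json.dumps(meta, indent=2))


if __name__ == "__main__":
    main()
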