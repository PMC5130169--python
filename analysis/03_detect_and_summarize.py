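"""Detect contraction events and summarize motility per condition.

Normalizes each stored STM, detects events at the default 10% diameter
threshold and reports the four wave metrics (frequency, travel distance,
velocity, interval) plus the bulb pattern and the contraction endpoint.
Writes results/motility_summary.csv and per-condition event tables.
"""

from pathlib import Path

import pandas as pd

from gutmap import io, stm, waves

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for tsv in sorted((SCRATCH / "stm").glob("*.tsv")):
        name = tsv.stem
        m = io.read_stm(tsv.with_suffix(""))
        nstm = stm.normalize_stm(m)
        events = waves.detect_events(nstm, threshold=0.10)
        regions = waves.regions_from_baseline(nstm)
        duration = float(m.times[-1] - m.times[0]) + 1.0 / m.frame_rate
        s = waves.summarize_motility(events, regions, duration)
        io.write_events(RESULTS / f"{name}_events.csv", events)
        rows.append({"condition": name, **s.to_dict()})
        print(f"{name}: {len(events)} events, "
              f"frequency {s.frequency:.1f}/1000 s, bulb {s.bulb_pattern}, "
              f"endpoint {s.endpoint:.3f} mm" if s.n_anterograde else
              f"{name}: {len(events)} events, no anterograde waves, "
              f"bulb {s.bulb_pattern}")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "motility_summary.csv", index=False,
              float_format="%.5g")
    print(f"\nwrote {RESULTS / 'motility_summary.csv'}:")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
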