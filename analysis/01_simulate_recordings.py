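"""Simulate one motility recording per genotype-like condition.

Three conditions emulate the qualitative motility classes seen in a
ret-dosage series: a wild-type-like gut (regular anterograde peristalsis plus
cyclical retrograde bulb churning), a sensitized-heterozygote-like gut
(sparser, shorter anterograde waves) and a null-like gut (no anterograde
waves, near-continuous bulb activity).  Frame stacks go to scratch/ (binary);
the realized ground truth goes to results/ as YAML.
"""

from pathlib import Path

from gutmap import io, simulate, stm

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "recordings"
RESULTS = ROOT / "results"


def wave_sets(cfg: simulate.MotilitySimConfig) -> dict[str, list]:
    g = cfg.geometry
    j = g.junction_mm
    wt = simulate.default_wave_set(cfg)
    het = [
        simulate.WaveSpec("anterograde", t, j, 0.04, 0.35 * g.length_mm,
                          0.35, 0.10)
        for t in (30.0, 150.0, 290.0)
    ] + [w for w in wt if w.direction == "retrograde"]
    # dense retrograde churning: successive waves overlap in time so bulb
    # activity covers nearly the whole recording (duty cycle ~1)
    null = [
        simulate.WaveSpec("retrograde", t, 0.55 * j, 0.03, 0.4 * j, 0.4, 0.06)
        for t in [5.0 + 8.0 * k for k in range(48)]
    ]
    return {"wt_like": wt, "het_p_like": het, "null_like": null}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    base = simulate.MotilitySimConfig(seed=0)
    for name, waves in wave_sets(base).items():
        cfg = simulate.MotilitySimConfig(waves=tuple(waves), seed=0,
                                         noise_sd=0.05)
        frames, truth = simulate.simulate_motility_recording(cfg)
        stack = stm.FrameStack(frames, cfg.frame_rate,
                               cfg.geometry.pixel_size_mm)
        io.write_stack(SCRATCH / f"{name}.tif", stack)
        io.write_yaml(RESULTS / f"{name}_truth.yaml",
                      {"waves": [w.to_dict() for w in truth.waves],
                       "seed": cfg.seed, "noise_sd": cfg.noise_sd})
        n_ant = sum(w.direction == "anterograde" for w in truth.waves)
        print(f"{name}: {frames.shape[0]} frames, {len(truth.waves)} waves "
              f"({n_ant} anterograde) -> {SCRATCH / (name + '.tif')}")


if __name__ == "__main__":
    main()
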