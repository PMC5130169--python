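# gutmap

Quantitative analysis of enteric-nervous-system (ENS) phenotypes in larval
zebrafish models of Hirschsprung disease, built around three measurements:

1. **Gut motility from video.** A spatiotemporal map (STM) of gut width is
   built from a time-lapse recording of the larval gut: the gut tube is
   segmented on the temporal median frame, a centerline is extracted, and the
   local diameter is measured along centerline normals in every frame,
   giving a matrix `width(x, t)` (arc position × time, mm). Contraction
   waves appear as slanted bands of reduced width. Events are detected on the
   normalized map `C(x, t) = 1 − width/baseline(x)` (baseline = temporal
   median per position) and summarized by the standard motility metrics:
   frequency (waves · 1000 s⁻¹), travel distance (mm), velocity
   (distance / duration, mm s⁻¹), inter-contraction interval (s), the
   retrograde churning pattern of the intestinal bulb
   (cyclical / continuous / absent), and the per-larva contraction endpoint.
2. **ENCC migration-wavefront speed.** From any tracker's cell-track export
   (`cell_id, t, x, y`), the wavefront is the most distal cell per frame;
   its advance is fit by ordinary least squares and reported in µm/min with
   standard error and r². Wavefront shape is scored by
   roundness = 4·area/(π·major_axis²) and proliferation density in a 220 µm
   window behind the front.
3. **Phenotype / expressivity statistics.** Distal neuron counts within a
   somite-length window of the anal pore, the position of the k-th most
   distal neuron, phenotypic (P/NP) and severity calls (severe =
   fewer than 24 distal neurons), exact small-sample tests implemented from
   first principles (permutation Spearman, Fisher 2×2) and the classical
   suite (ANOVA + Bonferroni/Tukey, Welch ANOVA, Shapiro–Wilk,
   Brown–Forsythe).

Because the underlying animal recordings are not publicly deposited, the
package ships a first-class synthetic-data generator (`gutmap.simulate`)
that produces motility videos, migration tracks and phenotype cohorts with
known ground truth, so every stage is validated end-to-end by recovery
testing.

## Worked example

Simulate three genotype-like recordings, build their STMs, and summarize
motility (this is `analysis/01…03`, or `gutmap run-all` from the shell):

```bash
python analysis/01_simulate_recordings.py
python analysis/02_build_stms.py
python analysis/03_detect_and_summarize.py
```

prints

```
 condition  n_anterograde  frequency_per_1000s  mean_distance_mm  mean_velocity_mm_s  mean_interval_s bulb_pattern  endpoint_mm
het_p_like              3                  7.5          1.122917            0.040104            130.0     cyclical     1.751855
 null_like              0                  0.0               NaN                 NaN              NaN   continuous          NaN
   wt_like              8                 20.0          1.766406            0.050182             50.0     cyclical     2.398730
```

The wild-type-like gut shows 8 anterograde peristaltic waves in 400 s
(20 waves/1000 s) at 0.050 mm/s — the generator's ground truth is
0.05 mm/s — with regular 50 s intervals and cyclical retrograde bulb
churning. The heterozygote-like gut has fewer, slower, shorter waves with a
more rostral endpoint, and the null-like gut has lost anterograde
peristalsis entirely while its bulb churns continuously.

Wavefront migration speed from a simulated track table:

```bash
gutmap simulate-migration --out tracks.csv --speed 1.2 --n-cells 10
gutmap migration-speed tracks.csv
# speed 1.2000 um/min (SE 0.0000, r^2 1.0000, 78 frames)
```

and `analysis/04_migration_speed.py` recovers the generative 30% / 25%
speed reductions of mutant-like cohorts (noise sd 2 µm, 5% dropout):

```
early-stage mutant-like cohort: 0.834 um/min, 31.5% below WT-like
late-stage mutant-like cohort: 0.891 um/min, 26.8% below WT-like
```

Expressivity statistics on a two-genotype cohort
(`analysis/05_cohort_statistics.py`): the heterozygote-like group keeps a
normal distribution of distal neuron counts while the modifier-loss group is
bimodal with a severe cluster:

```
het: mean 34.4 +/- 10.8, Shapiro-Wilk p=0.4386, 8/60 severe
het_modifier: mean 22.3 +/- 14.2, Shapiro-Wilk p=7.502e-05, 33/60 severe
Brown-Forsythe p=0.006981; severity Fisher p=2.281e-06
endpoint vs last-neuron position: rs=0.8857, exact p=0.0333 (n=6)
```

The last line is the exact permutation Spearman test: at n = 6 with rank
discrepancy Σd² = 4, rs = 1 − 6·4/210 = 0.8857 and the two-sided
enumeration p over all 720 rank permutations is 24/720 = 0.0333.

## Layout

- `src/gutmap/` — the library: `simulate` (ground-truth generators), `stm`
  (segmentation → centerline → width map), `waves` (event detection and
  motility metrics), `migration` (wavefront speed, shape, proliferation),
  `stats` (phenotyping and tests), `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and end-to-end recovery tests.
- `docs/methods.md` — model, parameters, numerical choices and limitations.
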