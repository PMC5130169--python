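# Methods

## The gut model and its simulator

The larval zebrafish gut is modelled as a tapering tube of length *L*
(default 3.2 mm) lying roughly along the image axis. Its resting diameter
profile D₀(x) blends logistically from the wide intestinal bulb calibre
(0.35 mm) to the intestine calibre (0.20 mm) around the bulb/intestine
junction at `bulb_fraction · L` (default 0.25, i.e. 0.8 mm from the oral
end), over a 0.15 mm taper. Arc position x runs oral → anal from 0;
anterograde means increasing x.

A contraction wave is a travelling Gaussian notch in diameter:

    width(x, t) = D₀(x) · (1 − Σᵢ aᵢ · exp(−(x − xᵢ(t))² / 2wᵢ²) · 1[onsetᵢ ≤ t ≤ offsetᵢ])

with xᵢ(t) advancing at ±vᵢ from its origin, amplitude aᵢ ∈ (0, 1] a
*fractional* diameter reduction (making detection thresholds scale-free),
and wᵢ a spatial sigma. The width is clipped below at 0.1·D₀(x): the gut
wall never closes completely. A wave whose trajectory would leave the gut
or the recording is rejected at config validation, naming the wave.

Frames are rendered as a bright tube (intensity 1) on dark background
(intensity 0): at column j the tube's vertical extent is
`width/pixel_size` pixels centred on the image midline, plus optional
additive Gaussian noise. Rendering is a pure function of
(kymograph, seed) — bit-identical on repeat.

Defaults encode the acquisition settings of the recordings this package is
designed for: 400 s at 2.5 frames/s (motility), 374 s frame interval
(migration time-lapse), 6.25 µm pixels with 512×128 px frames. The numeric
wave parameters of a healthy gut are not published, so the wild-type-like
defaults are field-realistic choices fixed once: anterograde waves at
0.05 mm/s, amplitude 0.5, every 50 s, starting at the junction and
travelling 55% of the gut; retrograde bulb waves at 0.03 mm/s, amplitude
0.4, every 40 s, confined to the bulb.

Migration tracks place a lead cell at x(t) = x₀ + v·t/60 (µm, t in s) with
trailing cells at fixed random offsets strictly behind it, Gaussian
positional noise, and i.i.d. row dropout. Cohort tables draw per-larva
distal neuron counts from a normal or two-component-mixture distribution
(truncated at 0, rounded), a most-distal-neuron position (somite-lengths
from the anal pore, truncated at 0), and a contraction endpoint equal to
that position plus Gaussian noise — the mixture emulates modifier-genotype
cohorts whose severe subpopulation makes the count distribution bimodal.
The severity-benchmark groups are normal(37, 10) for the sensitized
heterozygote (about one larva in ten below the 24-neuron severity cut) and
an even mixture with normal(10, 5) for the modifier-loss genotype (about
half severe).

### What the simulator does not emulate

Real recordings have uneven illumination, luminal contents, gut curvature in
3-D, slow drift, and waves whose amplitude and velocity vary along their
path; the simulator has none of these. Passing recovery tests therefore
demonstrates that the measurement chain is *correct* (it recovers what the
model generates, to stated tolerances), not that it is robust to every
artefact of live imaging. Segmentation assumes a single bright connected
gut; the package deliberately performs no motion correction (larvae are
anaesthetised and mounted) and no multi-animal scene parsing.

## STM construction

One centerline per recording, computed on the temporal median frame:
Otsu threshold (overridable) → largest connected component → skeleton →
longest skeleton path by double BFS (side branches are pruned by
construction). Skeletons grow diagonal spurs into the tube-end corners, so
the path is trimmed where the inscribed radius (distance transform) falls
below 0.8× its median; coordinates are then smoothed (Gaussian, σ = 2 px)
and arc length accumulated, which keeps the length of a synthetic sinusoid
within 2% of its analytic value. Orientation: oral end = the wider end
(the bulb), or an explicit side flag.

Width at each centerline point is the contiguous above-threshold extent of
the intensity profile sampled along the local normal (normal from a
smoothed tangent), with sub-pixel edges by linear interpolation between the
bracketing samples; the default threshold is the frame's intensity
midpoint. A point whose normal leaves the image, whose centre sample is
below threshold, or whose run reaches the sampling window edge is missing
(NaN), never zero. Temporal gaps of ≤ 2 frames are linearly interpolated;
positions that stay > 50% unmeasurable (centerline tips overshooting the
tube) are dropped from the map's ends, and > 20% missing entries overall is
an error pointing back at segmentation. Arc positions therefore start at
the trimmed skeleton, slightly inside the anatomical oral end.

On noiseless renders this chain reproduces the generating kymograph to
within 1 px (tolerance 2 px) away from the gut ends, and added noise of
10% contrast changes recovered widths by under 1 px RMS.

## Event detection and motility metrics

The STM is normalized to C(x, t) = 1 − width/baseline(x) with baseline the
temporal **median** width per position — robust as long as contractions
occupy a minority of frames at each position, which fails under
near-continuous churning (C is then measured against a partially
contracted reference; event detection still works but amplitudes are
compressed). Detection binarizes C ≥ θ (default θ = 0.10, i.e. a 10%
diameter reduction; no published threshold exists, so it is configurable
and echoed in output), labels 8-connected components in (position, time),
and takes each component's ridge — the per-frame position of maximal C.
Events shorter than 2 frame intervals or narrower than `min_extent`
(default 0.05 mm) are discarded. Direction is the sign of the least-squares
ridge slope, with a dead band (default 3 position bins) calling localized
contractions stationary.

Metrics follow the conventional definitions: frequency =
anterograde count / recording duration × 1000 (waves per 1000 s); distance
= |ridge end − ridge start|; velocity = distance/duration per event
("average speed over the total propagated distance"), then averaged across
events; interval = mean onset-to-onset gap of consecutive anterograde
events; per-larva endpoint = median over anterograde events of the most
anal ridge position. Bulb pattern: duty cycle (union of bulb-event windows
/ duration) ≥ 0.8 → continuous; else ≥ 3 retrograde events with onset-
interval CV ≤ 0.5 → cyclical; else absent. The duty and CV cutoffs are
package conventions, configurable.

Regions: anterograde statistics are taken over events starting in the
intestine. Because STM coordinates start at the trimmed skeleton, the
bulb/intestine junction is located from the data — the calibre step of the
relaxed-width profile (90th temporal percentile of width, which unlike the
median stays at resting calibre even under heavy churning) — and region
membership allows a 0.05 mm boundary tolerance since peristaltic waves
originate at the junction itself. Explicit region intervals can always be
supplied instead.

Resolvability: at 2.5 frames/s the onset/offset of an event is quantized
to 0.4 s, so a wave must persist ≳ 20 s for its velocity and distance to be
measurable to within 10%; the recovery benchmark's wave generator enforces
that persistence (velocities 0.01–0.1 mm/s, capped by compartment length).

## Migration and shape

Wavefront position is the per-frame maximum of x (the most distal cell);
the axis orientation of the track export is the caller's responsibility.
Speed is the OLS slope in µm/min with its standard error and r² — OLS over
the whole series rather than an endpoint difference, for noise robustness;
on noiseless linear tracks it is exact, and over 200 noisy replicates the
mean estimate is within 2 SE of truth. A constant series is reported as
0 µm/min with r² = 1 (the zero-slope fit is exact). Shape metrics use the
moment-based ellipse: major axis = 4√(largest eigenvalue of the normalized
second central moments), roundness = 4·area/(π·major²); rasterization can
push roundness slightly above 1 for tiny masks. Proliferation density
counts marker-positive and total cells in a 220 µm window anchored at the
most distal cell (or an explicit anchor), fraction NaN when the window is
empty.

## Statistics

`spearman_exact` computes rs = 1 − 6Σd²/(n(n²−1)) on ranks and, for untied
samples with n ≤ 8, an exact two-sided p by full enumeration of rank
permutations: the one-sided tail of Σd² (≤ observed when rs ≥ 0, ≥ when
rs < 0) is doubled and capped at 1. At n = 6, Σd² = 4 this gives
rs = 0.8857, p = 24/720 = 0.0333. Ties fall back to midrank rs with the
asymptotic t approximation and a warning. `fisher_exact_2x2` sums
hypergeometric probabilities of all fixed-margin tables no more probable
than the observed one (with a 1e−7 relative slack against ties in floating
point); degenerate margins give p = 1 with a warning. Both agree with
exhaustive-enumeration references across all small inputs (n ≤ 6 / total
≤ 20) in the test suite.

The classical tests are contract-defined to match the standard numerical
implementations: one-way ANOVA (scipy), Welch's ANOVA (own implementation
of the Welch F with Satterthwaite-style df, verified against pingouin to
1e−6), Shapiro–Wilk (scipy), Brown–Forsythe (Levene with median centring),
Tukey HSD (statsmodels), and a Bonferroni post-hoc of pairwise t tests on
the pooled ANOVA error term. All four omnibus/normality tests hold their
nominal 5% type-I rate within ±0.02 over 1000 null simulations.
Phenotyping conventions: distal windows are boundary-inclusive (≤ 5 or 10
somite-lengths); "phenotypic" (P) means the most distal neuron lies more
than 1 somite-length (configurable) from the anal pore; severe means
strictly fewer than 24 distal neurons.

## Reproducibility and problem sizes

Every generator and the pipeline are pure functions of (config, seed); the
run report echoes the config verbatim with a SHA-256 hash and contains no
timestamps, so a repeated run is byte-identical. The validation suite uses
a full-scale recording (400 s × 2.5 fps at 512×128 px) for the
reconstruction check, 50 seeded recordings for metric recovery, 200
replicates for speed unbiasedness and 1000 for type-I calibration; unit
tests run on a half-length gut (1.6 mm, 256×64 px) for speed.
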