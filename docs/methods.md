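# Methods

## Sensor signal model

Each channel of the 8-sensor MOS array is modeled as a first-order
exponential charge/discharge system — the minimal model that reproduces
the rise–plateau–decay morphology of a MOS sensor exposed to an odor
pulse. With baseline `b` (V), drift rate `d` (V/s), rise/recovery time
constants `τ_r`, `τ_f` (s) and effective amplitude `A_eff`, the noise-free
output is

```
v(t) = b + d·t                                          t < t_on
v(t) = b + d·t + A_eff·(1 − exp(−(t − t_on)/τ_r))       t_on ≤ t < t_off
v(t) = b + d·t + P·exp(−(t − t_off)/τ_f)                t ≥ t_off
```

where `P = A_eff·(1 − exp(−(t_off − t_on)/τ_r))` is the plateau excess at
switch-off, making the trace exactly continuous there. I.i.d. Gaussian
noise of standard deviation `noise_sd_v` is added per sample. Humidity
enters as a multiplicative attenuation of amplitude,
`A_eff = A·(1 − c·h)` with `c ∈ [0, 1]` per unit relative humidity
`h ∈ [0, 1]` — higher humidity lowers MOS sensitivity by blocking
adsorption sites, which scales the response rather than offsetting it.

An aroma class is a profile: one steady-state amplitude per sensor. The
pattern across sensors, not any single channel, is the class signature.

### Default parameters (stand-ins)

No public dataset or datasheet pins down kinetics, noise, drift or
humidity coefficients for roasted-coffee headspace on these sensors, so
the defaults are explicit stand-ins, chosen once to make the nominal
500–1500 s window a plateau:

| parameter | default | unit | rationale |
|---|---|---|---|
| rise_tau_s | 60 | s | plateau reached well before window midpoint |
| fall_tau_s | 120 | s | recovery slower than response, typical of MOS |
| noise_sd_v | 0.01 | V | ~1% of a mid-range response |
| drift_v_per_s | 1e−5 | V/s | 20 mV over a 2000 s recording |
| baseline_v | 0.55–1.45 | V | spread per channel; MQ7 highest (1.45 V) |
| humidity_coeff | 0.10–0.25 | — | MQ-series more humidity-sensitive than TGS26xx |

The nine default origin profiles (La Flor del, Kona, Mandheling, Sigri,
Bunum Wo, Ipanema, Yirgacheffe, Dongshan, Tolima) are likewise invented
amplitude patterns constrained by two qualitative facts about roasted
coffee: the CO-sensitive MQ7 channel reads highest for every origin
(roasting releases CO) — guaranteed jointly by MQ7's largest amplitude and
largest baseline — and Mandheling's MQ7 response is the largest overall.

Timing defaults follow the measurement protocol: 2000 s per recording at
1 Hz, exposure (and stable window) 500–1500 s. Per-measurement noise
seeds are derived from (master seed, class index, replicate index) via
`numpy.random.SeedSequence`, so datasets are bit-reproducible and a given
recording is independent of how many others are generated.

## Feature extraction

The stable window is half-open, `start ≤ t < end`, with 0-based row
indexing; a window extending beyond the recording raises an error rather
than clipping silently. Within the window, rows are partitioned into k
contiguous blocks (k = 8 default); when T is not divisible by k the first
`T mod k` blocks receive one extra row — a deterministic convention that
also makes the block-length-weighted mean of block means equal the
whole-window mean exactly. Features are ordered sensor-major. `k = 1`
yields the 8-feature variant (one whole-window mean per sensor); k = 8 is
the default because 64 features preserve strictly more temporal
information and degrade to the 8-feature variant by averaging.

No baseline subtraction is applied by default — absolute voltages carry
class information. `subtract_baseline` optionally removes each channel's
mean over the first 100 pre-exposure seconds. `detect_plateau` offers an
automatic window (longest run where every channel's smoothed slope
magnitude stays below a threshold, default 1 mV/s with 30 s smoothing)
for recordings with unknown timing.

## Fingerprints

Z-score normalization uses the population SD (divisor n); PCA covariance
uses divisor n − 1. Constant feature columns get SD 1 with a warning and
normalize to 0. PCA is computed by SVD of the centered matrix; axes are
sorted by descending eigenvalue with the sign fixed so each axis's
largest-magnitude loading is positive, making outputs reproducible across
eigensolvers. PCA is fitted once on the pooled training matrix so
fingerprints of different origins share one coordinate system.

Rendering: a block of up to 100 recordings is laid on a 10×10 cell grid
in row-major order (empty cells neutral gray 128); each sample's first
three PC scores are min–max scaled per channel over the block to [0, 255]
(constant channel → 128) and become R, G, B; the grid is upsampled to
128×128 by nearest neighbor, pixel (i, j) ← cell (⌊i·10/128⌋,
⌊j·10/128⌋). Incomplete final blocks are padded with neutral gray so
every sample appears in exactly one fingerprint. Given the stored
per-channel (min, max), the mapping is invertible back to scores.

A consequence of per-block min–max scaling worth knowing: the scaling
stretches whatever variation the block contains. A block holding a single
tight cluster (one class at low noise) therefore amplifies measurement
noise to the full color range, and two such blocks are *not* visually
near-identical even though the underlying scores are. Blocks of matched
class composition, whose range is set by between-class separation, are
near-identical up to noise/separation — this is the regime in which
fingerprints are comparable across runs. An alternative reading of
"blocks of 100" as 100 time points rather than 100 recordings exists; the
recording-block reading is implemented.

## Benchmark design

Stratified 80/20 splits round the per-class train count to nearest (ties
up), giving 144/36 on 180 samples and 320/80 on 400. One-vs-rest tasks
balance the negative class by drawing an equal-size uniform random subset
of all non-target samples (seeded); the negative-class composition is a
design choice, recorded in the task's counts. Accuracy
(correct/total on the held-out set) is the primary metric.

Backends sit behind a uniform fit/predict contract with fixed default
hyperparameters: decision tree and random forest (100 trees) from
scikit-learn, XGBoost (100 rounds, depth 4), RBF-SVM (C = 1, scale
gamma). Classifier internals are deliberately not re-derived. The deep
backends (a 1-D CNN over the 64-feature vector and a CNN feeding a
recurrent layer) require PyTorch; without it they are reported as failed
results with an explanatory message rather than aborting a run. Features,
not raw time series, are the classifier input.

## Numerical and I/O conventions

Recordings serialize as CSV (`time_s,<sensor>,...`) with 6-decimal volts
(round-trip precision 5 × 10⁻⁷ V), UTF-8, LF endings; parse errors carry
the offending line number. Manifests and PCA models are JSON; fingerprints
are 8-bit RGB PNG. Configuration is a flat YAML mapping with a closed
schema — unknown keys are errors — and every pipeline output is
accompanied by the SHA-256 hash of the resolved configuration that
produced it.

## Test problem sizes

The test suite exercises the full 2000 s protocol where the check depends
on it (simulator closed form, 64-feature extraction, the two-class
parameter-recovery study at 180 samples over 10 seeds) and scaled-down
recordings (200 s, exposure 50–150 s) elsewhere, a choice that keeps the
suite's statistical checks identical in structure while the deterministic
ones need no scale. The discriminability study uses amplitude separation
of 5× sensor noise for the recoverable regime, identical profiles for the
chance-level regime, and profiles shrunk toward their grand mean (factor
0.01, bringing per-sensor separations to the order of feature-level
noise) for the non-saturated regime where multi-class difficulty exceeds
two-class difficulty.

## What the synthetic data does and does not show

The generator reproduces the temporal structure (calibration/exposure
segments, first-order kinetics, plateau), per-class amplitude patterns,
Gaussian noise, linear drift and multiplicative humidity attenuation. It
does not model chemical speciation of volatiles, sensor cross-sensitivity
dynamics, nonlinear drift or aging, pump/pressure dynamics, or
between-session variability of real coffee headspace. Passing benchmarks
on synthetic data therefore validate the pipeline's correctness and its
statistical behavior under known ground truth — not any claim about
classification accuracy on real coffee recordings, which are not publicly
available.
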