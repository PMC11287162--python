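# Methods

## Signal model

A well's luminescence is modelled as the product of an ATP-dependent
magnitude and a circadian component, with multiplicative noise:

```
L(t) = b · m · exp(−κt) · [1 + a · exp(−λt) · cos(2π(t − φ)/τ)] · exp(σZ_t)
```

| symbol | meaning | unit | default |
|--------|---------|------|---------|
| `b`    | baseline photon counts per interval | counts | 1000 |
| `m`    | condition (drug) multiplier on the magnitude | — | 1 |
| `κ`    | slow substrate/ATP drift | 1/h | 0.005 |
| `a`    | relative oscillation amplitude (must be < 1) | — | 0.3 |
| `λ`    | damping of the oscillation | 1/h | 0.005 |
| `τ`    | period | h | 24 |
| `φ`    | peak-time phase | h | 0 |
| `σ`    | lognormal noise SD (of the log) | — | scenario-dependent |

Noise is multiplicative (lognormal) because photon counting and gain
variation act multiplicatively on luminescence; Poisson counting can be
stacked on top. Small nonzero defaults for `κ` and `λ` make simulated traces
resemble real LumiCycle records (declining baseline, decaying oscillation).
Sampling follows the recording convention: counts at 10-min intervals over
84 h, of which the first 12 h are a burn-in discarded before analysis
(re-labelling the first retained timepoint as T0) and the remaining 72 h are
the analysis window. Ground-truth parameters are attached to every simulated
object so each downstream stage is testable as a recovery problem.

This is deliberately *not* a mechanistic transcription–translation feedback
model: the scientific claims the pipeline supports operate at the level of a
damped cosine with a multiplicative confound, and that is the level
simulated.

### What the generators emulate — and what they do not

`simulate_condition_plate` reproduces the structure of a drug-treatment
experiment: all wells share clock/magnitude parameters; a condition either
multiplies the magnitude (an OxPhos modulator acting through ATP) or the
clock amplitude (a genuine clock effect); each well has an independent,
seed-derived noise stream. `simulate_mito_stress` produces four-phase
OCR/ECAR traces (baseline → oligomycin → FCCP → rotenone/antimycin A) with
iid Gaussian cycle noise. `simulate_panel` draws a latent per-line metabolic
activity `m ~ N(0, 1)` and maps it linearly to ATP-linked respiration
(60 + 25·m ± 5), basal glycolysis (30 + 12·m ± 3) and clock amplitude
(0.25 − 0.08·m ± 0.02, truncated at 0) — a panel distributed along a
hypometabolic-to-hypermetabolic axis with ~12 lines, OCR/ECAR magnitudes and
amplitude ranges typical of such panels.

Not emulated: well-to-well phase desynchronization, position/edge effects on
plates, media-change artefacts, heteroskedastic instrument drift, cell death
during recording, or any feedback of metabolism on the clock parameters
themselves. A passing recovery test therefore shows the estimators are
correct under the stated noise model, not that real plates are this clean.

## Normalization

The rolling average is centered, with partial (truncated) windows in the
first and last half-window; a trailing variant is provided. Centered is the
symmetric default; its edge bias is confined to the window ends. Control
wells are averaged into a single reference signal per experiment before the
rolling mean is taken. Nonpositive counts are rejected rather than offset —
a silent additive offset would distort amplitude ratios, which are the
quantity of interest.

Self-normalization is exactly invariant to rescaling the trace
(`self_normalize(c·L) ≡ self_normalize(L)`), which is the decomposition's
defining property; control normalization is exactly magnitude-preserving
(scaling the treated trace by `c` scales its output by `c`).

## Rhythm detection

Traces are binned to 1 h (mean of six 10-min samples, timestamps at bin
centers) before scanning, keeping exact-null computation tractable without
materially attenuating a circadian signal (the binning gain at 24 h is
0.997). References are cosines over periods 20–28 h and phases covering one
period, both at the bin resolution; the score is Kendall's S with pairs tied
in either series contributing zero, and tau is tie-corrected (tau-b).

The null distribution of S under exchangeability depends only on the series
length and the reference's tie pattern, so null tables are cached per
pattern: exact enumeration over all n! orderings for n ≤ 10, a seeded
20,000-draw permutation table for longer series (draws shared across
patterns of one grid), or a tie-corrected normal approximation with
continuity correction. When the data themselves contain ties (possible but
rare for binned photon counts; certain for noise-free periodic simulations)
the cached tie-free tables do not apply, and the scan falls back to the
normal approximation with the full two-sample tie correction. The
permutation null's seed defaults to a fixed internal value so the table is
a deterministic object independent of the analysis seed.

The scan reports the reference with minimal raw p (ties broken by larger
|tau|, then smaller period, then smaller phase) and a Bonferroni adjustment
over all scanned (period, phase) pairs — conservative, but downstream use is
ranking and thresholding, for which order preservation suffices. The
single-reference p-value is calibrated (type-I ≈ α under iid noise); the
scan's *minimum* raw p over ~216 correlated references is by construction
anti-conservative, and the Bonferroni-adjusted p conservative — neither is a
calibrated per-trace p-value, and the arrhythmicity threshold (adjusted
p < 0.05) should be read as a screening rule.

### Amplitude

The amplitude is a fixed-period cosinor least-squares fit
`v(t) ≈ m + A·cos(2π(t − φ)/P)` with the phase free, reported as `A ≥ 0`.
Two refinements matter in practice:

* **Period refinement.** The rank test reports the grid period, but the
  cosinor fit uses the SSE-optimal period within one grid step of it, so
  grid truncation (e.g. truth 28 h scored best at 27 h) does not bias `A`.
* **Window-gain correction.** Dividing by a W-hour rolling mean multiplies
  the oscillatory component by approximately `1 − sinc(W/τ)` — ~1 at
  τ = W = 24 h, +16% at τ = 20 h, −16% at τ = 28 h — plus edge distortion
  from the truncated windows. For self-normalized traces the scan divides
  the fitted amplitude by a numerically measured gain: a unit-mesor probe
  cosine at the fitted period and phase is pushed through the same pipeline
  the data saw (rolling-mean division on the original 10-min grid,
  reconstructed from the bin centers, then binning), and its amplitude
  attenuation is the correction factor. The correction is applied only for
  centered self-normalization; control-normalized traces keep the raw
  cosinor amplitude.

With damping (λ > 0) the fitted amplitude reflects a window-average of the
decaying depth — about 0.84·a for λ = 0.005/h over 72 h — not the initial
depth; no damping correction is attempted, matching common practice.
Recovery studies of the estimator therefore simulate with λ = 0. Under those
conditions (a ∈ {0.1, 0.2, 0.3}, τ ∈ 20–28 h, σ = 0.05) the period is
recovered within one grid step in ~100% of runs and the mean amplitude per
level is within ~6% of truth; the residual negative bias is dominated by the
κ-drift interaction with the rolling window.

## Respirometry

Metrics follow the standard stress-test partition (non-mitochondrial OCR,
basal and ATP-linked respiration, maximal respiration, spare capacity, basal
glycolysis as mean baseline ECAR, uncorrected). Which cycle represents a
phase is configurable: the default follows the instrument-vendor report
convention (baseline: last cycle before injection; oligomycin and
rotenone/antimycin A: minimum; FCCP: maximum), and a uniform `mean` mode is
provided — the latter is the unbiased choice for Monte-Carlo work, the
former matches instrument reports. Metrics are computed per well before any
group averaging (replicate-level n); group summaries report mean ± SEM
(SD/√n, ddof = 1). Negative difference metrics are possible under noise and
are returned as-is with a warning flag rather than clipped.

## Metabolomics

Intensity = area / internal-standard area / protein amount. Metabolites
without their own internal standard must be mapped (by the user) to the
designated nearest-retention-time standard; the mapping is an input, never
inferred. The QC stability filter uses the two-point relative SD between the
begin- and end-of-sequence QC samples with the n−1 convention
(SD = |x₁ − x₂|/√2), retaining metabolites with RSD < 25% by default.
Min-max scaling is per metabolite across lines; a metabolite constant across
lines is emitted as missing rather than an arbitrary constant (no contrast,
should not color a heatmap). The phenotype classifier dichotomizes pyruvate
and lactate at the panel median — the minimal assumption consistent with
relative language like "high lactate relative to pyruvate" — and flags
exact-median ties as ambiguous instead of silently assigning them; calls are
rank-based and hence invariant to min-max scaling.

## Panel statistics

Exclusion order: arrhythmic lines first (JTK adjusted p ≥ α, α = 0.05 by
default), then amplitude outliers among the rhythmic subset with Z > 2
computed leave-in (the point under test included in mean and SD, ddof = 1).
Leave-in is the plain reading of a Z-score threshold, but it self-masks
single extreme points in small panels (one 10 in four 1s has Z = 1.79); a
leave-one-out option is provided, and the behavior is pinned by tests.
Regressions are simple OLS with two-sided t p-values (n − 2 df). Holm–Šidák
adjustment delegates to statsmodels; the Benjamini–Krieger–Yekutieli
two-stage step-up is implemented directly from its definition (stage 1: BH
at q/(1+q); estimate true nulls as m − r₁; stage 2: BH at q/(1+q)·m/(m−r₁))
and cross-checked against statsmodels' implementation in the tests.

## Reproducibility and problem sizes

One root seed drives everything; per-stage and per-well seeds are derived by
SHA-256 hashing of (root seed, stage, well), so adding a well never perturbs
another well's stream, and identical configs give byte-identical outputs
(verified by test). The study sizes used by the test suite and the
acceptance script — chosen as the package's own defaults — are: 12 wells per
condition for the decomposition experiment; 105 simulated traces
(3 amplitudes × 5 periods × 7 seeds) for recovery; 1,000 iid-noise traces
for type-I calibration; 200 plates for the stress-test Monte Carlo; 12-line
panels with 500 null panels for the false-positive calibration.

## Known limitations

* The cosinor amplitude is proportional to, but not numerically identical
  with, MetaCycle's JTK AMP output; agreement is monotone, which is what the
  downstream ranking and regressions need.
* The Bonferroni grid adjustment is conservative; no attempt is made to
  reproduce MetaCycle's internal Harding-table null with ties.
* Amplitude estimates under damping reflect window-averaged depth.
* No batch/mixed-effect modelling across experiments; regressions are
  per-panel.
* The κ-drift × rolling-window interaction leaves a residual amplitude bias
  of order κ·W (≈ 1–2% at defaults) that the window-gain correction does not
  remove.
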