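# lumiclock

Decomposition and analysis of circadian luciferase-reporter signals that are
confounded by the reporter enzyme's ATP dependence.

## The problem

Firefly luciferase consumes ATP to cleave luciferin, so the luminescence of a
circadian reporter line (e.g. *Bmal1*::luc or *Per2*::luc recorded in a
LumiCycle) is not a clean readout of clock-driven transcription: it is the
product of an ATP-dependent signal magnitude and the circadian oscillation,

```
L(t) = b · exp(−κt) · [1 + a · exp(−λt) · cos(2π(t − φ)/τ)] · noise
```

with baseline counts `b`, slow substrate/ATP drift `κ`, relative amplitude
`a`, damping `λ`, period `τ` and phase `φ`. A drug that changes cellular ATP
production moves the whole trace up or down without touching the clock, and a
naive analysis misreads that as a circadian effect. Two rolling-mean ratio
modes separate the components:

* **control (DMSO) normalization** — divide each timepoint by the 24-h rolling
  average of the control condition: preserves between-condition magnitude
  differences (the ATP-dependent part);
* **self-normalization** — divide each timepoint by the trace's *own* 24-h
  rolling average: exactly cancels any multiplicative, slowly varying
  component and leaves the circadian oscillation alone.

On top of the decomposition the package provides, for anyone analyzing
circadian/metabolic crosstalk in cell-line panels:

* a from-scratch **JTK-style rhythm test**: Kendall-S scoring against cosine
  references over a 20–28 h period × phase grid, with exact (n ≤ 10),
  permutation, or tie-corrected normal nulls, Bonferroni adjustment over the
  grid, and a cosinor amplitude corrected for the rolling-window frequency
  response;
* **mito stress-test metrics** from phase-labelled Seahorse OCR/ECAR traces
  (ATP-linked, basal, maximal, spare, non-mitochondrial respiration, basal
  glycolysis);
* **metabolomics peak-table** normalization (internal standard + protein),
  the begin/end QC relative-SD filter, min-max scaling, and the
  pyruvate/lactate quadrant phenotype classifier
  (hypometabolic / hypermetabolic / glycolytic / OxPhos);
* **panel statistics**: arrhythmic and amplitude-outlier (Z > 2) exclusion,
  the three amplitude/metabolism regressions, one-way ANOVA, Holm–Šidák, the
  Benjamini–Krieger–Yekutieli two-stage FDR, comparative-Ct expression;
* seeded **synthetic-data generators** for all of the above, with ground
  truth attached so every stage doubles as a recovery test.

## Worked example

Simulate the default scenario — a DMSO control, a "BEZ-like" condition that
doubles only the ATP-dependent magnitude, and a "DMF-like" condition that
dampens only the clock amplitude to 0.4× — and run the full pipeline:

```bash
lumiclock run --seed 1 --out results/demo
```

which prints

```
amplitude~ATP: slope=-0.002812 R2=0.924 p=6.28e-07 n=12; outputs in results/demo
```

and writes `plate_condition_summary.tsv`:

| condition | n  | amplitude_mean | control_norm_level_mean |
|-----------|----|----------------|-------------------------|
| BEZ       | 12 | 0.2332         | 1.9784                  |
| DMF       | 12 | 0.0947         | 0.9908                  |
| DMSO      | 12 | 0.2356         | 0.9893                  |

Read it as the decomposition working: the magnitude-doubling condition sits
at 2.0× the control level but its self-normalized amplitude is within 1% of
the control's, while the clock-dampening condition leaves the level at 1.0×
and scales the amplitude by 0.40 (0.0947/0.2356). The simulated cell-line
panel, where a latent metabolic activity drives ATP production and basal
glycolysis up and clock amplitude down, yields the three regressions in
`panel_regressions.json` — amplitude vs. ATP production slope −0.0028
(R² = 0.92, p = 6.3e−07, n = 12), amplitude vs. basal glycolysis negative,
ATP vs. glycolysis positive — the signature of a hypometabolic-to-
hypermetabolic axis anticorrelated with clock amplitude.

The same stages are available as library calls (`simulate_trace`,
`self_normalize`, `jtk_scan`, `compute_metrics`, `run_panel_analysis`, ...)
and as individual CLI subcommands (`lumiclock simulate|normalize|rhythm|
mito|metab|panel|run`).

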