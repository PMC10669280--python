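# mitoquant

Quantification pipelines for cellular bioenergetics experiments:
mitochondrial membrane-potential imaging with the cationic dye TMRM,
mito-stress-test respirometry, plate-reader assays, and the group
statistics used to compare treatments against an untreated control.

The package is aimed at researchers who have (or want to simulate)
three kinds of raw data:

- **Confocal TMRM images** of cells or isolated mitochondria, acquired
  before and after addition of the uncoupler FCCP. TMRM accumulates in
  mitochondria in proportion to the inner-membrane potential, so bright
  pixels report hyperpolarisation and the FCCP-induced signal loss
  isolates the potential-dependent component.
- **Flux-analyser traces** (OCR in pmol O₂/min, ECAR in mpH/min) through
  the standard injection sequence oligomycin → FCCP →
  rotenone/antimycin A.
- **Plate-reader tables** — a TMRM fluorescence plate normalised to the
  untreated control, and an erythrocyte haemolysis assay read as
  415 nm absorbance against a blank and a 1% Triton X-100 positive
  control.

## Methods at a glance

**Image pipeline.** Each grayscale image is denoised with a pixel-wise
adaptive Wiener filter (5×5 window): with local mean *m*, local variance
*v* and noise estimate *ν* (the mean of all local variances), the output
is *m* + max(*v* − *ν*, 0)/max(*v*, *ν*) · (*x* − *m*). Objects are
outlined by thresholding the 3×3 Sobel gradient magnitude at 4× its mean,
then dilation (orthogonal length-3 lines) closes the outlines, interior
holes are filled, a diamond erosion restores the boundary, and
sub-2-pixel objects are removed. Per-region means are computed on the
filtered image; the **bright-area ratio** is the fraction of segmented
pixels at or above half the maximum filtered intensity (the
hyperpolarised pool), and the **FCCP response** is
100 · (F_before − F_after)/F_before.

**Respirometry.** With stage levels taken as last-basal, min-oligomycin,
max-FCCP and min-rotenone/antimycin OCR, the partition is
non-mito = rot/AA floor, basal = last basal − floor, proton leak =
oligomycin − floor, ATP-linked = basal − leak, maximal = FCCP − floor,
spare = maximal − basal, coupling efficiency = ATP-linked/basal.
ATP rates: mito = ATP-linked · 2 O/O₂ · P/O (2.75 by default); the
glycolytic rate is the proton efflux (basal ECAR / buffer factor) minus
the respiration-derived share (CCF · basal), at one ATP per lactate.

**Plate assays.** Haemolysis % = 100 · (A − A_blank)/(A_Triton −
A_blank); TMRM plate potential = background-subtracted fluorescence as a
percentage of the untreated-control mean.

**Statistics.** Per-group mean ± SD, one-way ANOVA, Dunnett's
many-to-one comparison against the control (familywise-error
controlled), pooled or Welch t-tests, and the conventional significance
stars (\* p ≤ 0.05 … \*\*\*\* p ≤ 0.0001).

A synthetic-data module emulates all three instruments with known ground
truth (object masks, hyperpolarised fraction, stage levels, group
effects), so every pipeline stage is testable end to end without any
measured data.

## Worked example

```bash
python examples/segment_tmrm_image.py
```

```
objects generated : 10
regions segmented : 10
segmented area    : 3121 px (true object area 3447 px)
bright-area ratio : 0.299 (true hyperpolarised fraction 0.300)
largest region mean intensity: 150.0 a.u.
```

The pipeline recovers all 10 simulated mitochondria and measures a
bright-area (hyperpolarised) ratio of 0.299 against a generated truth of
0.300. The other examples cover the FCCP response
(`fccp_response.py`: recovers ~58% for a true 60% signal collapse — the
non-scaling background baseline accounts for the small gap), the mito
stress test (`mito_stress_test.py`: coupling efficiency 0.762 ± 0.024
against a truth of 0.750, glycolytic ATP fraction ~19% vs 20.4%), the
haemolysis assay (`haemolysis_assay.py`: a ~1% haemolysing treatment is
Dunnett-significant while an inert one is not) and a dose-response plate
with ANOVA + Dunnett (`group_comparison.py`).

A thin CLI mirrors the library for shell use:

```bash
mitoquant simulate image --out sim --seed 5
mitoquant segment sim/before.tif --out results
mitoquant fccp sim/before.tif sim/after.tif
mitoquant anova-dunnett values.csv --control untreated
```

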