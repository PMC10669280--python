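# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions.

## Image quantification

### Model

TMRM is a cationic dye whose mitochondrial accumulation increases with
the inner-membrane potential, so in a single-channel fluorescence image
the potential readouts are (i) the mean intensity of segmented
mitochondrial regions, (ii) the fraction of segmented area that is
"bright" (at or above half of the maximum filtered intensity) — the
hyperpolarised pool — and (iii) the fractional signal loss after the
uncoupler FCCP collapses the potential.

The segmentation follows the classical gradient-outline recipe with a
fixed stage order:

1. **Adaptive Wiener filter** (default 5×5 window). Output per pixel is
   `m + max(v − ν, 0)/max(v, ν) · (x − m)` with local mean `m`, local
   variance `v`, and noise estimate `ν` = mean of all local variances.
   Constant images are exact fixed points; flat noisy regions collapse
   to the local mean while structured regions pass through.
2. **Sobel gradient magnitude**, unnormalised 3×3 kernels (a vertical
   step of height `h` produces magnitude `4h` at the edge).
3. **Automatic threshold** at `scale × mean(gradient)`, default
   `scale = 4` — a standard heuristic for Sobel edge maps; the exact
   constant is an explicit configuration default, not a claim.
4. **Morphology**: dilation by horizontal + vertical length-3 lines
   (closes gaps in the gradient outline), 4-connected hole filling,
   diamond erosion, removal of 8-connected components below 2 px.
5. **Labelling** (8-connected) and per-region means on the *filtered*
   image, regions sorted by descending area.

### Why the default erosion radius is 3

The Sobel response of a step edge extends about two pixels beyond the
object boundary, and the gap-closing dilation adds one more, so the
filled outline overshoots the object footprint by roughly three pixels
on every side. A single radius-1 erosion therefore leaves a background
ring in every region: on a sharp 200-on-10 test square the region mean
drops to ~116 (vs ~197 with radius 3), and segmented areas inflate by
~50%, which biases the bright-area ratio downward by up to 0.2 at high
hyperpolarised fractions. The default diamond radius of 3 (equivalent to
three radius-1 passes) cancels that systematic overshoot; the element and
radius remain configurable.

Other conventions: reflective (edge-including) padding for all windows
and kernels; intensities processed in native units with no rescaling;
the half-max threshold for bright pixels uses the maximum of the
filtered image (the object the pipeline operates on); the FCCP response
of an image pair averages the filtered fluorescence over the
*pre-uncoupler* segmentation mask in both frames, so the same structures
are compared before and after the collapse. When nothing is segmented,
the result carries `n_regions = 0` and `bright_ratio = None` rather than
a silent NaN.

## Respirometry

Stage levels are picked by the vendor convention — last basal point,
minimum under oligomycin, maximum under FCCP, minimum under
rotenone/antimycin A — and partitioned as

    non_mito    = rot/AA minimum
    basal       = last basal − non_mito
    proton_leak = oligomycin minimum − non_mito
    atp_linked  = basal − proton_leak
    maximal     = FCCP maximum − non_mito
    spare       = maximal − basal
    coupling    = atp_linked / basal

`basal = atp_linked + proton_leak` and `spare = maximal − basal` hold
exactly by construction. A basal at or below the non-mitochondrial floor
is an error; negative ATP-linked or proton-leak values (possible with
noisy traces) are flagged in the result rather than raised.

ATP production rates use conversion constants that are methodology
conventions, not assay outputs, and are all overridable:

| constant | default | meaning |
|---|---|---|
| P/O ratio | 2.75 | ATP per O atom reduced |
| O atoms per O₂ | 2 | stoichiometry |
| buffer factor | 0.15 | mpH per (pmol H⁺/min) for the medium |
| CCF | 0.61 | pmol H⁺ per pmol O₂ of respiration (CO₂-derived acidification) |
| ATP per lactate | 1 | glycolytic stoichiometry |

`mito_atp = atp_linked × 2 × P/O`; the glycolysis-attributable proton
efflux is `basal_ecar / buffer_factor − CCF × basal`, clamped at zero
with a warning if negative, and converted one-to-one to ATP. Exact
numerical parity with any particular instrument software is not claimed;
the structure (respiration-corrected proton efflux) is the standard one.
Computation is per well first, group aggregation (mean ± SD, n) second.

## Plate assays

Haemolysis: `100 × (A − A_blank)/(A_Triton − A_blank)` after averaging
parallel wells of the same sample, so blanks read exactly 0% and the
Triton-lysed positive control exactly 100%; the formula is affine
invariant, so upstream blank-subtraction conventions are irrelevant.
TMRM plates: blank-mean subtraction (when blank wells exist), then
normalisation to the untreated-control mean, × 100.

## Statistics

One-way ANOVA (classical between/within decomposition via
`scipy.stats.f_oneway`, with explicit handling of zero-variance
degeneracies), two-sided pooled-variance t-tests (Welch optional), and
Dunnett's many-to-one procedure. Adjusted p-values come from the joint
multivariate-t distribution of the comparison statistics
(`scipy.stats.dunnett`, seeded); because that integration is numerical,
each adjusted p is clipped to be no smaller than its unadjusted pooled-t
p, which the joint distribution guarantees analytically. With one
treatment the procedure reduces to the pooled two-sided t-test (within
integration tolerance ~1e-3), and its familywise error under the null is
calibrated by simulation in the test suite. Stars follow
`* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001, **** p ≤ 0.0001`.

## Synthetic data

The generators emulate the three instruments only as far as the
quantification pipelines care:

- **Images** (default 256×256): ten non-overlapping rotated ellipses
  with semi-axes 10–24 × 4–8 px — rod-shaped mitochondrial profiles at
  super-resolution confocal sampling (~0.3–1 µm × 1–5 µm at ~60 nm/px) —
  at base intensity 100 over background 5, with a chosen fraction of
  object pixels at 3× base (the hyperpolarised pool), Poisson shot noise
  plus Gaussian read noise (σ = 4; SNR ≈ 9 at base intensity). The
  after-FCCP frame scales object signal toward background by
  (1 − d). Placement keeps a 6-px Chebyshev gap so the pipeline's
  dilation cannot merge objects; packing failures raise after bounded
  retries. Not emulated: the microscope PSF, out-of-focus light,
  intra-mitochondrial texture, photobleaching, or cell-to-cell
  variability — so passing recovery tests demonstrate correctness of the
  quantification chain, not robustness to every optical artefact.
- **Traces**: per-stage plateaus (defaults 100/40/180/20 pmol O₂/min,
  basal ECAR 20 mpH/min — a well with coupling efficiency 0.75 and a
  glycolytic ATP fraction ≈ 0.20) with i.i.d. Gaussian noise (σ = 2 OCR,
  0.5 ECAR) and three points per stage. Injection kinetics
  (exponential transitions) are not modelled; stage levels are the
  ground truth the analysis should recover.
- **Plates**: Gaussian readings around true group means with roles
  (blank, positive control, untreated control, sample) assigned.

All generators are bit-reproducible given their seed, and every truth
object is expressed in the same types the analysis emits, so recovery is
a direct comparison.

## Numerical choices and degenerate inputs

- Padding: scipy's `reflect` (edge-including symmetric) everywhere.
- All-zero gradients give threshold 0 and an empty segmentation (a
  flagged zero-region result, not an error).
- Region relabelling is stable under area ties (original label order).
- Zero within-group variance: equal means → F = 0/p = 1 (t = 0/p = 1);
  unequal means → flagged degenerate with p = 0.
- Bright-area ratio of an empty mask and FCCP response with
  non-positive pre-uncoupler signal are errors, not NaNs.

## Known limitations

- The gradient-outline segmentation needs objects a few pixels wide;
  sub-3-px structures are removed by design.
- The bright-area ratio is only interpretable once the bright pool is
  separated from the base level by the half-max threshold (bright
  multiplier > 2 under the default generator); below that every
  segmented pixel clears the threshold and the ratio saturates near 1.
- ATP-rate magnitudes depend linearly on the conversion constants above;
  comparisons across instruments require matching constants.
- No 3D/z-stack, multi-channel, or time-lapse tracking support.
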