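"""Segment a synthetic TMRM image and read off the hyperpolarised fraction.

Generates a confocal-like field of rod-shaped mitochondria in which 30% of
object pixels are hyperpolarised (3x brighter), runs the full pipeline
(adaptive Wiener denoise -> Sobel gradient -> threshold -> morphology ->
region statistics), and compares the measured bright-area ratio with the
generator's ground truth.
"""

from mitoquant import gen_mito_image, segment_mitochondria

before, after, truth = gen_mito_image(bright_fraction=0.3, seed=42)
result = segment_mitochondria(before)

print(f"objects generated : {truth.object_labels.max()}")
print(f"regions segmented : {result.n_regions}")
print(f"segmented area    : {result.segmented_area_px} px "
      f"(true object area {int(truth.object_mask.sum())} px)")
print(f"bright-area ratio : {result.bright_ratio:.3f} "
      f"(true hyperpolarised fraction {truth.realized_bright_fraction:.3f})")
print(f"largest region mean intensity: {result.region_means[0][1]:.1f} a.u.")

# The bright-area ratio is the fraction of segmented pixels at or above
# half the maximum filtered intensity -- the readout used to quantify
# mitochondrial hyperpolarisation; it should track the generated fraction.
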