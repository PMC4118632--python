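"""Color-normalize a degraded tile and segment it into three classes.

The tile is rendered with a stain shift, an illumination gradient and
pixel noise; normalization maps it back to the package reference, and
the three-class segmentation labels background / normal / abnormal
tissue.  Accuracy is scored as Dice overlap against the generator's
ground truth.
"""

from pulleyquant import PhantomConfig, generate_phantom, normalize_color, \
    segment_tissue
from pulleyquant.tissue_seg import dice_coefficient

phantom = generate_phantom(PhantomConfig(
    width_px=320, height_px=240, abnormal_fraction_target=0.2,
    nucleus_density=6.0,
    stain_shift=(1.1, 0.92, 1.05),          # eosin-heavy staining batch
    illumination_gradient_amplitude=0.08,   # uneven lamp field
    noise_sd=2.0, seed=1))

normalized = normalize_color(phantom.image)
mask = segment_tissue(normalized.image)

for code, name in ((0, "background"), (1, "normal tissue"),
                   (2, "abnormal tissue")):
    dice = dice_coefficient(mask, phantom.truth.label_mask, code)
    print(f"Dice {name:16s}: {dice:.3f}")
print("Dice near 1.0 means the color segmentation recovers the true")
print("tissue classes despite the staining/illumination degradation.")
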