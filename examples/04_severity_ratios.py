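"""Quantify one tile's severity: Abn-SR and Abn-NR vs ground truth.

Abn-SR = abnormal tissue area / total tissue area (background excluded);
Abn-NR = abnormal (round) nuclei / all nuclei.  Both increase with the
extent of chondroid metaplasia, i.e. with trigger-finger severity.
"""

from pulleyquant import PhantomConfig, analyze_image, generate_phantom

phantom = generate_phantom(PhantomConfig(
    width_px=320, height_px=240, abnormal_fraction_target=0.26,
    abnormal_nucleus_fraction=0.74, nucleus_density=6.0, seed=42))

result, mask, records = analyze_image(phantom.image, "demo_tile")

print(f"estimated Abn-SR: {result.abn_sr:.4f}   "
      f"(truth {phantom.truth.realized_abn_sr:.4f})")
print(f"estimated Abn-NR: {result.abn_nr:.4f}   "
      f"(truth {phantom.truth.realized_abn_nr:.4f})")
print(f"tissue pixels:    {result.tissue_px}, "
      f"abnormal pixels: {result.abnormal_px}")
print(f"nuclei:           {result.n_nuclei_normal} spindle, "
      f"{result.n_nuclei_abnormal} round")
print(f"suitable tile:    {result.is_suitable} "
      f"(tissue fraction {result.suitability:.2f})")
print("Estimates within a few 1e-3 of truth show the four-step pipeline")
print("recovering the tile's severity parameters.")
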