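# Methods

## Scope and model

`pulleyquant` quantifies chondroid (fibrocartilaginous) metaplasia in
H&E-stained A1-pulley tissue through two severity parameters and
reconstructs the statistics of a severity-correlation study design:
21 specimens in pathological grades L/M/H (5/8/8) and Froimson
clinical grades II/III/IV (8/6/7), each specimen imaged as 49
candidate tiles of which 10 survive suitability screening and random
selection. The specimen — not the tile — is the statistical unit;
all ANOVA and correlation statistics operate on specimen means.

The severity parameters are ratios, unitless in [0, 1]:

* **Abn-SR** (abnormal size ratio): area of basophilic chondromyxoid
  matrix over total tissue area, background excluded;
* **Abn-NR** (abnormal nucleus ratio): count of rounded
  chondrocyte-like nuclei over all detected nuclei.

Undefined ratios (a tile with no tissue, or no nuclei) propagate as
missing values and are excluded from specimen means with a logged
count; treating them as zero would bias severity downward.

## Synthetic phantom generator

The generator is first-class, tested code: it is the package's
replacement for unavailable patient imagery and defines the study
conditions for every validation claim.

**Geometry.** The canvas is partitioned by quantile-thresholding
band-passed smoothed Gaussian noise fields: background blobs first
(target fraction of the canvas), then chondromyxoid patches among the
remaining tissue (target = the tile's ground-truth Abn-SR; quantile
thresholding makes the realized fraction exact to pixel resolution,
well within the guaranteed ±0.02). The noise fields are band-passed
(their heavy-smooth component subtracted) so structures distribute
evenly and an undegraded tile genuinely has flat illumination.
Nuclei are non-overlapping ellipses placed by rejection sampling with
full containment in their tissue class and a 2 px clearance: spindles
(axis ratio 3–6) in normal tissue, round nuclei (axis ratio 1–1.4) in
abnormal patches; areas are drawn from 30–70 px². A bounded retry
budget (400 attempts per nucleus, preferring the small end of the
area range once crowded) ends in an explicit `GenerationError` rather
than silently violating any invariant.

**Appearance.** Flat stain colors with mild texture: pink eosin
matrix with sinusoidal collagen-bundle striping, blue-purple
basophilic patches with low-frequency mottle, near-white background,
dark hematoxylin nuclei. Degradation — per-channel multiplicative
stain shift in [0.7, 1.3], a linear illumination gradient of
amplitude ≤ 0.3 along a random direction, Gaussian pixel noise — is
applied after the ground truth is frozen, and the identity parameters
reproduce the input exactly. This is deliberately schematic: no
chromatin texture, vasculature, tissue folds, focus blur or JPEG
artifacts. Passing tests therefore show correctness of the
measurement logic under controlled color/illumination variation, not
performance on real slides.

**Cohorts.** Specimen-level true ratios are drawn from per-grade
normal distributions truncated to [0, 1]; the default calibration is
L: 0.14 ± 0.03 / 0.57 ± 0.07, M: 0.20 ± 0.01 / 0.64 ± 0.04,
H: 0.26 ± 0.01 / 0.74 ± 0.05 (Abn-SR/Abn-NR mean ± SD), with 5/8/8
subjects. Clinical grades follow the empirical conditional rows
(L→II; M→II w.p. 3/8 else III; H→III w.p. 1/8 else IV); an
exact-counts mode reproduces the 3×3 confusion table
[[5,0,0],[3,5,0],[0,1,7]] deterministically. Froimson grade I is
representable in the label types but never generated: mild cases are
treated conservatively and do not yield surgical specimens. Per-tile
targets are jittered around the specimen value with SD 0.02 (the
within-specimen, tile-to-tile variance is a free parameter of the
design; 0.02 keeps the 10-tile specimen mean within ±0.02 of truth at
the ~95% level, consistent with specimen-level SDs of 0.01–0.03).
Since Abn-NR targets far exceed Abn-SR targets, nuclei cluster in the
chondroid patches; a tile's nucleus-ratio target is capped by the
patch's random-sequential packing capacity (limit 0.35 of the patch
area given the expected nucleus footprint), which binds only in the
near-zero-SR tail and reflects the biology — chondrocyte-like cells
sit in chondroid matrix. About 20% of each specimen's candidate tiles
are built unsuitable (70% background, sparse nuclei) to exercise the
screening step. All randomness flows from one seeded generator per
call; equal config means bit-identical output.

## Color normalization

Illumination flattening divides L\* by a smooth illumination field,
rescaled to preserve the global mean. The field is the best-fit plane
through the Gaussian-smoothed luminance (σ = width/4): restricting to
a plane removes lamp/condenser gradients while leaving genuine tissue
structure alone, and a 6% relief deadzone (the fitted plane counts as
flat) makes the operation idempotent — a corrected image is not
re-corrected.

Statistics matching is Reinhard-style per-channel mean/SD transfer in
CIELAB, chosen over stain-vector deconvolution because the goal is a
stable color distribution for fixed thresholds, not stain unmixing,
and mean/SD transfer is deterministic and parameter-free. Two
refinements matter in practice: (1) statistics are computed over
stained foreground only (background = bright and unsaturated,
relative to the image's own bright end), because a tile that is
mostly empty background otherwise drags the tissue colors with it;
(2) background pixels are pinned to the reference white point by a
mean shift, keeping the white point stable across tiles of any
composition. The reference is derived once from the canonical
undegraded phantom (default config, seed 0) — with no deposited
images there is no patient-derived reference — and is serializable
to JSON. Constant-color inputs degenerate to a mean shift and are
flagged in the result metadata rather than raising.

## Tissue segmentation

Three steps, all deterministic and ground-truth-blind:

1. **Background**: luminance ≥ 185 (Rec. 709, 0–255) and saturation
   ≤ 0.15. After normalization the background sits near the reference
   white point, so fixed gates suffice.
2. **Stain polarity**: remaining matrix pixels scored by the
   basophilia index b = B − R (positive = basophilic). The split
   point is re-estimated per image by Otsu's method on the tissue b
   histogram because global statistics matching shifts the index with
   the tile's pink/blue composition; when the two putative classes
   are separated by < 50 units (near-unimodal histogram, e.g. an
   all-normal tile) the fixed threshold t_b = 0 is used instead.
   Setting `adaptive_polarity=False` restores a purely fixed cut.
3. **Cleanup**: nuclear-dark pixels (luminance < 95) are filled with
   the geometrically nearest matrix class — severity is a
   matrix-area ratio and nuclei are not subtracted from their region
   — and connected components smaller than 64 px are dissolved into
   their surroundings. The nearest-class fill uses one distance
   transform per class with a fixed label-priority tie-break, keeping
   the whole operation equivariant under image flips.

Suitability is a quantitative proxy for expert screening: a tile is
suitable when its tissue fraction is ≥ 0.5 and it shows ≥ 30 nuclei
(defaults for the full-size canvas; scaled configs lower the nucleus
minimum proportionally to tissue area). The score used for ranking is
the tissue fraction.

## Nucleus analysis

Candidates are tissue pixels below the dark threshold;
8-connected components with area in [20, 240] px are kept, oversized
components are split by watershed on the distance transform seeded at
local maxima, and descriptors come from second moments (Crofton
perimeter). Circularity 4πA/P² with Crofton perimeter stays in
(0, ~1] for rasterized ellipses; on the generator's shape ranges the
two classes separate cleanly: round nuclei (axis ratio ≤ 1.4)
rasterize to circularity ≳ 0.85, spindles (ratio ≥ 3) to ≲ 0.6.

Classification is two-threshold hysteresis on circularity:
≥ 0.75 ⇒ abnormal, ≤ 0.55 ⇒ normal, and in the ambiguous band the
axis ratio decides (≤ 2 ⇒ abnormal). The thresholds were calibrated
on rasterized ellipses of the generator's shape ranges. Nuclei are
classified wherever they sit; the tissue mask only restricts the
search region, since Abn-NR is defined purely by counts. Raising the
upper threshold can only move nuclei out of the forced-abnormal set,
so the abnormal count is monotone non-increasing in it — a tested
invariant.

## Selection and aggregation

Unsuitable tiles are discarded, then min(k, remaining) tiles are
drawn uniformly without replacement from a generator seeded per
specimen; short selections are recorded as warnings and zero suitable
tiles raise an error naming the specimen. Specimen severity is the
unweighted mean over selected tiles (no area weighting: the study
design reports per-subject means of per-tile parameters).

## Statistics

* ANOVA: standard between/within decomposition; the summary-statistics
  form uses SS_within = Σ(nᵢ−1)sᵢ² and is algebraically identical to
  the raw form (tested to 1e-10 relative). Zero within-variance with
  unequal means reports F = ∞, p = 0, flagged degenerate.
* LSD: unadjusted pairwise t-tests on the pooled ANOVA error variance
  with df = N − k; all pairs returned; two-sided p-values; no further
  multiplicity correction (that is the LSD rule).
* Cohen's kappa: unweighted, on the 3×3 pathological × clinical table
  with L↔II, M↔III, H↔IV aligned by position. Bands: poor < 0.40,
  fair to good in [0.40, 0.75), excellent ≥ 0.75 — the published band
  edges leave [0.74, 0.75) ambiguous; it is resolved as fair to good.
  Pe = 1 raises an explicit undefined-statistic error.
* ICC: two-way random effects, absolute agreement, single rater
  (ICC(2,1)) — the standard form for rater-agreement designs;
  verified against pingouin's ICC(A,1).
* Boxplots: quartiles by linear interpolation by default with a
  classic Tukey-hinge switch; whiskers at the furthest points within
  1.5 IQR of the quartiles, never retreating inside the box; points
  beyond the whiskers are outliers.
* Sample SDs use the n−1 denominator throughout.

## Problem sizes and numerical choices

The default phantom canvas is 640 × 480 px (a scaled stand-in for
2560 × 1920 acquisition tiles; all geometry is in pixels, so full
size is a config change). The test suite and the end-to-end study
runs use 320 × 240 or 256 × 192 canvases with 6–8 candidate tiles per
specimen and k = 4–5 selected, with the suitability nucleus minimum
scaled accordingly (12–15); these are the package's chosen desk-scale
study sizes. Tolerances on phantoms: per-class segmentation Dice
≥ 0.90, nucleus classification accuracy ≥ 0.95, per-tile recovery
|Abn-SR − truth| ≤ 0.05 and |Abn-NR − truth| ≤ 0.07 (measured
performance on undegraded tiles is far inside these bounds). CSV/JSON
outputs are written with fixed float formatting and sorted keys so
identical configs byte-reproduce every file.

## Known limitations

* The phantom's flat-color rendering makes color segmentation much
  easier than real H&E; Dice near 1.0 on phantoms says the logic is
  correct, not that real-slide Dice would be comparable.
* Reinhard matching is composition-sensitive by construction; the
  foreground masking, background pinning and adaptive polarity split
  mitigate but do not remove this. Tiles that are entirely abnormal
  (no pink at all) fall back to the fixed polarity threshold and can
  be misread; such tiles are outside the calibrated study range
  (specimen Abn-SR ≤ ~0.3).
* Published point p-values from the original rater data, the
  parameter correlation on real specimens, and the two inter-rater
  ICCs cannot be recomputed from summaries; the package reproduces
  them only as bounds or as properties of the simulated design.
* Hypervascularization, a third histological feature of diseased
  pulleys, is out of scope: the grading model covers matrix color and
  nucleus shape only.
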