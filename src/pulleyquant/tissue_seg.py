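"""Three-class tissue segmentation (pipeline step 2).

Assigns every pixel of a color-normalized tile to one of three codes:
0 background (empty, near-white), 1 normal tissue (eosinophilic pink
collagen), 2 abnormal tissue (basophilic blue-purple chondromyxoid
matrix).  The classification runs in three steps:

1. background: bright, unsaturated pixels;
2. stain polarity: remaining pixels scored by a basophilia index
   b = blue − red (positive = basophilic, negative = eosinophilic);
3. cleanup: nuclear-dark pixels are absorbed into the surrounding
   matrix class (severity ratios are matrix-area ratios, nuclei are not
   subtracted), and connected components smaller than ``min_region_px``
   are dissolved into their surroundings.

All steps are deterministic and never read phantom ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import LABEL_ABNORMAL, LABEL_BACKGROUND, LABEL_NORMAL

_UNASSIGNED = 255


@dataclass(frozen=True)
class SegParams:
    """Thresholds of the segmentation, calibrated on phantoms.

    ``background_luminance`` / ``background_saturation`` define step 1
    (Rec. 709 luminance on 0–255, saturation = (max−min)/max).
    ``basophilia_threshold`` splits eosinophilic from basophilic matrix
    on the b = B − R index.  With ``adaptive_polarity`` (default) the
    split point is re-estimated per image by Otsu's method on the
    tissue b histogram — global statistics matching shifts the b index
    with the pink/blue composition of the tile, so a fixed cut is
    brittle — and falls back to the fixed threshold whenever the two
    putative classes are separated by less than
    ``min_polarity_separation`` (a near-unimodal histogram).
    ``dark_luminance`` marks nuclear-stain pixels to be reassigned to
    the surrounding matrix.
    """

    background_luminance: float = 185.0
    background_saturation: float = 0.15
    basophilia_threshold: float = 0.0
    adaptive_polarity: bool = True
    min_polarity_separation: float = 50.0
    dark_luminance: float = 95.0
    min_region_px: int = 64


@dataclass(frozen=True)
class SuitabilityParams:
    """Quantitative proxy for the pathologists' image screening: a tile
    is suitable when it shows enough tissue and enough nuclei."""

    min_tissue_fraction: float = 0.5
    min_nuclei: int = 30


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 709 luma of an RGB image, float, same scale as the input."""
    rgb = np.asarray(image, dtype=np.float64)
    return 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]


def saturation(image: np.ndarray) -> np.ndarray:
    """HSV-style saturation (max−min)/max, zero for black pixels."""
    rgb = np.asarray(image, dtype=np.float64)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    return np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)


def _dissolve_small(labels: np.ndarray, code: int, min_px: int) -> None:
    """Mark connected components of ``code`` smaller than ``min_px`` as
    unassigned, in place.  8-connectivity (isotropic, flip-invariant)."""
    comp, n = ndimage.label(labels == code, structure=np.ones((3, 3), int))
    if n == 0:
        return
    sizes = np.bincount(comp.ravel())
    small = np.flatnonzero(sizes < min_px)
    small = small[small > 0]
    if small.size:
        labels[np.isin(comp, small)] = _UNASSIGNED


def _fill_unassigned(labels: np.ndarray) -> None:
    """Assign leftover pixels to the geometrically nearest class.

    Uses one Euclidean distance transform per class with a fixed
    label-priority tie-break (0 < 1 < 2), which keeps the operation
    symmetric under image flips.
    """
    un = labels == _UNASSIGNED
    if not un.any():
        return
    present = [c for c in (LABEL_BACKGROUND, LABEL_NORMAL, LABEL_ABNORMAL)
               if (labels == c).any()]
    if not present:
        labels[un] = LABEL_BACKGROUND
        return
    dists = np.stack([ndimage.distance_transform_edt(labels != c)
                      for c in present])
    labels[un] = np.asarray(present, dtype=labels.dtype)[
        np.argmin(dists, axis=0)][un]


def segment_tissue(normalized_image: np.ndarray,
                   params: SegParams | None = None) -> np.ndarray:
    """Segment a color-normalized RGB tile into a {0,1,2} label mask.

    Returns a uint8 array on the image's pixel grid; every pixel carries
    exactly one code.  An all-background result is valid (downstream
    ratio operations must handle empty tissue).
    """
    params = params or SegParams()
    image = np.asarray(normalized_image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    rgb = image.astype(np.float64)
    Y = luminance(rgb)
    S = saturation(rgb)

    labels = np.empty(Y.shape, dtype=np.uint8)
    background = (Y >= params.background_luminance) & \
                 (S <= params.background_saturation)
    dark = (~background) & (Y < params.dark_luminance)
    b_index = rgb[..., 2] - rgb[..., 0]
    t_b = params.basophilia_threshold
    matrix = ~(background | dark)
    if params.adaptive_polarity and np.count_nonzero(matrix) > 1:
        b_vals = b_index[matrix]
        if b_vals.min() < b_vals.max():
            t_candidate = float(threshold_otsu(b_vals))
            hi = b_vals[b_vals > t_candidate]
            lo = b_vals[b_vals <= t_candidate]
            if hi.size and lo.size and \
                    hi.mean() - lo.mean() >= params.min_polarity_separation:
                t_b = t_candidate
    baso = b_index > t_b

    labels[:] = LABEL_NORMAL
    labels[baso] = LABEL_ABNORMAL
    labels[background] = LABEL_BACKGROUND
    labels[dark] = _UNASSIGNED            # nuclear pixels: filled below

    _fill_unassigned(labels)
    for code in (LABEL_BACKGROUND, LABEL_NORMAL, LABEL_ABNORMAL):
        _dissolve_small(labels, code, params.min_region_px)
    _fill_unassigned(labels)
    return labels


def tissue_fraction(mask: np.ndarray) -> float:
    """Fraction of pixels that are tissue (codes 1 or 2)."""
    return float(np.count_nonzero(mask != LABEL_BACKGROUND)) / mask.size


def suitability_score(mask: np.ndarray, nucleus_count: int,
                      params: SuitabilityParams | None = None
                      ) -> tuple[float, bool]:
    """Score a tile's evidential value for pulley-tissue quantification.

    Returns ``(score, is_suitable)`` where the score is the tissue
    fraction (for ranking) and a tile is suitable iff the tissue
    fraction and the nucleus count both meet their minima.
    """
    params = params or SuitabilityParams()
    frac = tissue_fraction(mask)
    ok = frac >= params.min_tissue_fraction and \
        nucleus_count >= params.min_nuclei
    return frac, ok


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray,
                     code: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of one label code between two masks.

    Returns 1.0 when the code is absent from both masks.
    """
    a = mask_a == code
    b = mask_b == code
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


__all__ = [
    "SegParams", "SuitabilityParams", "dice_coefficient", "luminance",
    "saturation", "segment_tissue", "suitability_score", "tissue_fraction",
]
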