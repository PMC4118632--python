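"""Synthetic H&E-like A1-pulley tissue phantoms with exact ground truth.

A phantom emulates one microscopic tile of a trigger-finger pulley
specimen: eosinophilic pink collagen with rows of elongated
spindle-shaped fibroblast nuclei (normal tissue), patches of basophilic
blue-purple chondromyxoid matrix with rounded chondrocyte-like nuclei
(abnormal tissue, i.e. chondroid metaplasia), and near-white empty
background.  Every phantom carries a per-pixel label mask and the exact
list of generated nuclei, so the whole measurement pipeline can be
validated against known truth without any real slide.

Rendering is deliberately schematic — flat stain colors with mild
texture — not photorealistic histology.  Staining/illumination
variability is modelled separately by :func:`degrade_staining`, applied
after the ground truth is frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

from .exceptions import GenerationError

NORMAL = "normal"
ABNORMAL = "abnormal"

# label codes of the ground-truth / segmentation masks
LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_ABNORMAL = 2

RGB = tuple[float, float, float]

# free space kept around every placed nucleus so detected components
# stay unambiguous
NUCLEUS_CLEARANCE = 2.0


@dataclass(frozen=True)
class StainPalette:
    """Reference RGB triples (0-255) for the four rendered materials."""

    background: RGB = (245.0, 244.0, 242.0)
    eosin: RGB = (231.0, 113.0, 147.0)         # pink collagen matrix
    basophilic: RGB = (150.0, 112.0, 190.0)    # blue-purple chondromyxoid matrix
    nuclear: RGB = (72.0, 48.0, 110.0)         # hematoxylin-dark nuclei


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic tile.

    ``abnormal_fraction_target`` is the target share of *tissue* pixels
    (background excluded) rendered as chondromyxoid matrix — i.e. the
    ground-truth Abn-SR of the tile.  ``nucleus_density`` is nuclei per
    10^4 tissue pixels.  ``abnormal_nucleus_fraction`` optionally fixes
    the share of nuclei placed in abnormal regions (the ground-truth
    Abn-NR); when ``None`` nuclei are allocated proportionally to region
    area.  Degradation parameters (illumination gradient, per-channel
    stain shift, pixel noise) default to the identity so the default
    phantom is undegraded.
    """

    width_px: int = 640
    height_px: int = 480
    abnormal_fraction_target: float = 0.2
    nucleus_density: float = 5.0
    normal_axis_ratio_range: tuple[float, float] = (3.0, 6.0)
    abnormal_axis_ratio_range: tuple[float, float] = (1.0, 1.4)
    background_fraction_target: float = 0.15
    abnormal_nucleus_fraction: float | None = None
    nucleus_area_range: tuple[float, float] = (30.0, 70.0)
    stain_palette: StainPalette = field(default_factory=StainPalette)
    illumination_gradient_amplitude: float = 0.0
    stain_shift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if not 0.0 <= self.abnormal_fraction_target <= 1.0:
            raise ValueError("abnormal_fraction_target must lie in [0, 1]")
        if not 0.0 <= self.background_fraction_target <= 0.9:
            raise ValueError("background_fraction_target must lie in [0, 0.9]")
        if self.nucleus_density <= 0:
            raise ValueError("nucleus_density must be > 0")
        for lo, hi in (self.normal_axis_ratio_range,
                       self.abnormal_axis_ratio_range,
                       self.nucleus_area_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < low <= high")
        if self.normal_axis_ratio_range[0] < 1 or self.abnormal_axis_ratio_range[0] < 1:
            raise ValueError("axis ratios are major/minor and must be >= 1")
        if not 0.0 <= self.illumination_gradient_amplitude <= 0.3:
            raise ValueError("illumination_gradient_amplitude must lie in [0, 0.3]")
        for s in self.stain_shift:
            if not 0.7 <= s <= 1.3:
                raise ValueError("stain_shift components must lie in [0.7, 1.3]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.abnormal_nucleus_fraction is not None and not (
                0.0 <= self.abnormal_nucleus_fraction <= 1.0):
            raise ValueError("abnormal_nucleus_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NucleusTruth:
    """One generated nucleus: geometric parameters and true class."""

    centroid: tuple[float, float]      # (row, col)
    major_axis: float                  # full major axis length, px
    minor_axis: float                  # full minor axis length, px
    orientation: float                 # radians
    true_class: str                    # NORMAL | ABNORMAL


@dataclass
class GroundTruth:
    label_mask: np.ndarray             # uint8 HxW, codes {0, 1, 2}
    nuclei: list[NucleusTruth]
    realized_abn_sr: float
    realized_abn_nr: float

    def recompute_abn_sr(self) -> float:
        """Abnormal tissue area over total tissue area, from the mask."""
        n_norm = int(np.count_nonzero(self.label_mask == LABEL_NORMAL))
        n_abn = int(np.count_nonzero(self.label_mask == LABEL_ABNORMAL))
        if n_norm + n_abn == 0:
            return float("nan")
        return n_abn / (n_norm + n_abn)

    def recompute_abn_nr(self) -> float:
        """Abnormal nucleus count over total nucleus count."""
        if not self.nuclei:
            return float("nan")
        n_abn = sum(1 for n in self.nuclei if n.true_class == ABNORMAL)
        return n_abn / len(self.nuclei)


@dataclass
class Phantom:
    """A rendered tile (8-bit RGB) together with its ground truth."""

    image: np.ndarray                  # uint8 HxWx3
    truth: GroundTruth
    config: PhantomConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean unit-SD band-passed Gaussian noise field.

    The heavy-smooth component is subtracted so the field carries no
    near-DC power: generated structures then distribute evenly across
    the canvas and an undegraded phantom has genuinely flat
    illumination.
    """
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= gaussian_filter(f, sigma=3 * sigma, mode="reflect")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _partition_canvas(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    """Build the 3-class label mask by quantile-thresholding smooth noise.

    Background blobs are carved first; among the remaining tissue pixels
    the abnormal (chondromyxoid) patches are thresholded so the realized
    abnormal fraction matches the target to pixel resolution.
    """
    shape = (cfg.height_px, cfg.width_px)
    scale = min(shape)
    mask = np.full(shape, LABEL_NORMAL, dtype=np.uint8)

    if cfg.background_fraction_target > 0:
        f_bg = _smooth_field(rng, shape, sigma=scale / 8)
        thr = np.quantile(f_bg, 1.0 - cfg.background_fraction_target)
        mask[f_bg > thr] = LABEL_BACKGROUND
    else:
        # keep the stream aligned whether or not background is drawn
        _smooth_field(rng, shape, sigma=scale / 8)

    tissue = mask != LABEL_BACKGROUND
    if not tissue.any():
        raise GenerationError("background fraction left no tissue pixels")

    a = cfg.abnormal_fraction_target
    f_abn = _smooth_field(rng, shape, sigma=scale / 16)
    if a >= 1.0:
        mask[tissue] = LABEL_ABNORMAL
    elif a > 0.0:
        thr = np.quantile(f_abn[tissue], 1.0 - a)
        mask[tissue & (f_abn > thr)] = LABEL_ABNORMAL
    return mask


def _place_nuclei(rng: np.random.Generator, cfg: PhantomConfig,
                  mask: np.ndarray) -> list[NucleusTruth]:
    """Rejection-sample non-overlapping elliptical nuclei inside their
    tissue class.  Spindle (elongated) nuclei go in normal tissue,
    round nuclei in abnormal tissue; a 3 px clearance keeps detected
    components unambiguous."""
    tissue_px = int(np.count_nonzero(mask != LABEL_BACKGROUND))
    n_total = int(round(cfg.nucleus_density * tissue_px / 1e4))
    if n_total == 0:
        return []

    abn_px = int(np.count_nonzero(mask == LABEL_ABNORMAL))
    if cfg.abnormal_nucleus_fraction is not None:
        n_abn = int(round(n_total * cfg.abnormal_nucleus_fraction))
        if n_abn > 0 and abn_px == 0:
            raise GenerationError(
                "abnormal nuclei requested but no abnormal region exists")
    else:
        n_abn = int(round(n_total * abn_px / tissue_px))
    if abn_px == 0:
        n_abn = 0
    if np.count_nonzero(mask == LABEL_NORMAL) == 0:
        n_abn = n_total
    n_norm = n_total - n_abn

    occupied = np.zeros(mask.shape, dtype=bool)
    margin = NUCLEUS_CLEARANCE
    nuclei: list[NucleusTruth] = []
    h, w = mask.shape

    for true_class, count in ((ABNORMAL, n_abn), (NORMAL, n_norm)):
        label = LABEL_ABNORMAL if true_class == ABNORMAL else LABEL_NORMAL
        region = mask == label
        centers = np.argwhere(region)
        if count > 0 and centers.size == 0:
            raise GenerationError(f"no {true_class} region to place nuclei in")
        ratio_range = (cfg.abnormal_axis_ratio_range if true_class == ABNORMAL
                       else cfg.normal_axis_ratio_range)
        area_lo, area_hi = cfg.nucleus_area_range
        for _ in range(count):
            placed = False
            for _attempt in range(400):
                r0, c0 = centers[rng.integers(len(centers))]
                ratio = rng.uniform(*ratio_range)
                # when the region gets crowded, prefer the small end of
                # the configured area range before giving up
                hi = area_hi if _attempt < 200 else \
                    area_lo + 0.3 * (area_hi - area_lo)
                area = rng.uniform(area_lo, hi)
                b = math.sqrt(area / (math.pi * ratio))   # semi-minor
                a = ratio * b                             # semi-major
                theta = rng.uniform(0.0, math.pi)
                pad = a + margin + 1
                if not (pad <= r0 < h - pad and pad <= c0 < w - pad):
                    continue
                rr, cc = _draw_ellipse(r0, c0, b, a, rotation=theta)
                if rr.size == 0:
                    continue
                if not region[rr, cc].all() or occupied[rr, cc].any():
                    continue
                # reserve the ellipse plus clearance
                rr2, cc2 = _draw_ellipse(r0, c0, b + margin, a + margin,
                                         rotation=theta, shape=mask.shape)
                occupied[rr2, cc2] = True
                nuclei.append(NucleusTruth(
                    centroid=(float(r0), float(c0)),
                    major_axis=2.0 * a, minor_axis=2.0 * b,
                    orientation=theta, true_class=true_class))
                placed = True
                break
            if not placed:
                raise GenerationError(
                    "nucleus placement retry budget exhausted; "
                    "reduce nucleus_density or nucleus size")
    return nuclei


def _render(rng: np.random.Generator, cfg: PhantomConfig, mask: np.ndarray,
            nuclei: list[NucleusTruth]) -> np.ndarray:
    """Paint the float RGB canvas from the label mask and nucleus list."""
    h, w = mask.shape
    pal = cfg.stain_palette
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = pal.background

    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0.0, math.pi)
    phase = rng.uniform(0.0, 2 * math.pi)
    # parallel collagen-bundle striping of the normal matrix
    u = xx * math.cos(theta) + yy * math.sin(theta)
    stripes = 1.0 + 0.08 * np.sin(2 * math.pi * u / 14.0 + phase)
    mottle_n = 1.0 + 0.05 * _smooth_field(rng, (h, w), sigma=min(h, w) / 10)
    mottle_a = 1.0 + 0.06 * _smooth_field(rng, (h, w), sigma=min(h, w) / 12)

    normal = mask == LABEL_NORMAL
    abnormal = mask == LABEL_ABNORMAL
    canvas[normal] = np.asarray(pal.eosin) * (stripes * mottle_n)[normal, None]
    canvas[abnormal] = np.asarray(pal.basophilic) * mottle_a[abnormal, None]

    for nuc in nuclei:
        r0, c0 = nuc.centroid
        rr, cc = _draw_ellipse(r0, c0, nuc.minor_axis / 2.0,
                               nuc.major_axis / 2.0,
                               rotation=nuc.orientation, shape=mask.shape)
        canvas[rr, cc] = np.asarray(pal.nuclear) * rng.uniform(0.9, 1.1)
    return canvas


def _degrade_float(canvas: np.ndarray, stain_shift, amplitude: float,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    h, w = canvas.shape[:2]
    out = canvas.astype(np.float64, copy=True)
    if amplitude > 0:
        theta = rng.uniform(0.0, 2 * math.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        u = xx * math.cos(theta) + yy * math.sin(theta)
        span = u.max() - u.min()
        if span > 0:
            u = 2.0 * (u - u.min()) / span - 1.0   # in [-1, 1]
        out *= (1.0 + amplitude * u)[..., None]
    out *= np.asarray(stain_shift, dtype=np.float64)[None, None, :]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _to_uint8(canvas: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def degrade_staining(image: np.ndarray,
                     stain_shift: tuple[float, float, float],
                     illumination_gradient_amplitude: float,
                     seed: int,
                     noise_sd: float = 0.0) -> np.ndarray:
    """Apply stain/illumination variability to a rendered 8-bit image.

    Multiplies each channel by its shift factor, applies a linear
    illumination gradient along a seeded random direction, and adds
    Gaussian pixel noise; output is clipped back to [0, 255].  The
    identity parameters (shift = (1,1,1), amplitude 0, noise 0) return
    the input exactly.  Ground truth of a phantom is never touched.
    """
    for s in stain_shift:
        if not 0.7 <= s <= 1.3:
            raise ValueError("stain_shift components must lie in [0.7, 1.3]")
    if not 0.0 <= illumination_gradient_amplitude <= 0.3:
        raise ValueError("illumination_gradient_amplitude must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    out = _degrade_float(image.astype(np.float64), stain_shift,
                         illumination_gradient_amplitude, noise_sd, rng)
    return _to_uint8(out)


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate one seeded synthetic tile with exact ground truth.

    The realized abnormal area fraction is within ±0.02 of
    ``abnormal_fraction_target`` (quantile thresholding makes it exact
    to pixel resolution); identical config (including seed) yields a
    bit-identical phantom.

    Raises :class:`GenerationError` when the geometry is infeasible
    (nuclei cannot be placed without overlap within the retry budget).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mask = _partition_canvas(rng, config)
    nuclei = _place_nuclei(rng, config, mask)
    canvas = _render(rng, config, mask, nuclei)
    canvas = _degrade_float(canvas, config.stain_shift,
                            config.illumination_gradient_amplitude,
                            config.noise_sd, rng)
    image = _to_uint8(canvas)

    truth = GroundTruth(label_mask=mask, nuclei=nuclei,
                        realized_abn_sr=0.0, realized_abn_nr=0.0)
    truth.realized_abn_sr = truth.recompute_abn_sr()
    truth.realized_abn_nr = truth.recompute_abn_nr() if nuclei else 0.0
    if math.isnan(truth.realized_abn_sr):
        raise GenerationError("no tissue pixels in generated phantom")
    if abs(truth.realized_abn_sr - config.abnormal_fraction_target) > 0.02:
        raise GenerationError("realized abnormal fraction missed its target")
    return Phantom(image=image, truth=truth, config=config)


def canonical_phantom() -> Phantom:
    """The package's canonical undegraded phantom (default config, seed 0),
    used to derive the reference color statistics for normalization."""
    return generate_phantom(PhantomConfig())


__all__ = [
    "ABNORMAL", "NORMAL",
    "LABEL_ABNORMAL", "LABEL_BACKGROUND", "LABEL_NORMAL",
    "GroundTruth", "NucleusTruth", "Phantom", "PhantomConfig",
    "StainPalette", "canonical_phantom", "degrade_staining",
    "generate_phantom",
]
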