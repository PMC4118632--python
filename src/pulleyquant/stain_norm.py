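"""Color and illumination normalization of H&E tiles (pipeline step 1).

Staining batches and microscope illumination drift shift the colors of
H&E slides enough to destabilize fixed segmentation thresholds.  This
module flattens the illumination field and then matches per-channel
mean/SD statistics in CIELAB (Reinhard-style statistics transfer) to a
fixed package reference, so downstream thresholds see a stable color
distribution.

The reference statistics are derived once from the package's canonical
undegraded phantom; they can also be computed from any image and
round-tripped through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import lab2rgb, rgb2lab

REFERENCE_VERSION = 1
_EPS = 1e-6


@dataclass(frozen=True)
class ReferenceColorStats:
    """Target per-channel mean and SD in CIELAB (L*, a*, b*).

    ``means``/``sds`` describe the stained foreground; ``bg_means``,
    when present, is the target mean of empty slide background, which
    is normalized separately (a mean shift) so that tiles dominated by
    background keep a stable white point.
    """

    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    bg_means: tuple[float, float, float] | None = None
    version: int = REFERENCE_VERSION

    def __post_init__(self):
        if any(s <= 0 for s in self.sds):
            raise ValueError("reference SDs must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "means": list(self.means),
             "sds": list(self.sds),
             "bg_means": None if self.bg_means is None
             else list(self.bg_means)}, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceColorStats":
        d = json.loads(Path(path).read_text())
        bg = d.get("bg_means")
        return cls(means=tuple(d["means"]), sds=tuple(d["sds"]),
                   bg_means=None if bg is None else tuple(bg),
                   version=d.get("version", REFERENCE_VERSION))


@dataclass
class NormalizedImage:
    """Result of :func:`normalize_color`.

    ``degenerate_channels`` lists LAB channels whose input SD was zero
    (constant-color input); for those the remap degenerates to a mean
    shift and is flagged here rather than raising.
    """

    image: np.ndarray                    # uint8 HxWx3
    degenerate_channels: list[str] = field(default_factory=list)


def _flatten_illumination(lab: np.ndarray, smoothing_scale: float) -> np.ndarray:
    """Divide L* by a smooth illumination field, preserving the global mean.

    The field is the best-fit plane through the heavily smoothed
    luminance (Gaussian sigma ``smoothing_scale`` px, at least a quarter
    of the image width).  Restricting the field to a plane removes
    lamp/condenser gradients while leaving genuine tissue structure
    untouched, which keeps the operation close to idempotent.
    """
    L = lab[..., 0]
    smooth = gaussian_filter(L, sigma=smoothing_scale, mode="reflect")
    h, w = L.shape
    yy, xx = np.mgrid[0:h, 0:w]
    step = max(1, min(h, w) // 64)
    a = np.column_stack([
        xx[::step, ::step].ravel(), yy[::step, ::step].ravel(),
        np.ones(xx[::step, ::step].size)])
    coeff, *_ = np.linalg.lstsq(a, smooth[::step, ::step].ravel(), rcond=None)
    plane = coeff[0] * xx + coeff[1] * yy + coeff[2]
    plane = np.maximum(plane, _EPS)
    # deadzone: a relief under 6% counts as already flat, which makes
    # the flattening idempotent (a corrected image is not re-corrected)
    if (plane.max() - plane.min()) / plane.mean() < 0.06:
        return lab
    flat = L * (plane.mean() / plane)
    out = lab.copy()
    out[..., 0] = flat
    return out


def _foreground_mask(rgb: np.ndarray) -> np.ndarray:
    """Boolean mask of stained (non-background) pixels.

    Empty slide background is the brightest, least saturated material
    regardless of staining batch, so it is excluded from the statistics
    (matching mean/SD over a tile that is mostly background would drag
    the tissue colors with the background share).  Falls back to all
    pixels when nothing qualifies as foreground.
    """
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    y = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
    white = (sat < 0.2) & (y > 0.8 * np.percentile(y, 99))
    fg = ~white
    if not fg.any():
        return np.ones(fg.shape, dtype=bool)
    return fg


def compute_reference_stats(image: np.ndarray) -> ReferenceColorStats:
    """Per-channel LAB mean/SD of an image's stained (foreground)
    pixels after illumination flattening."""
    rgb = np.asarray(image, dtype=np.float64)
    lab = rgb2lab(rgb / 255.0)
    lab = _flatten_illumination(lab, smoothing_scale=image.shape[1] / 4.0)
    fg = _foreground_mask(rgb)
    means = tuple(float(lab[..., c][fg].mean()) for c in range(3))
    sds = tuple(float(max(lab[..., c][fg].std(), _EPS)) for c in range(3))
    bg = ~fg
    bg_means = tuple(float(lab[..., c][bg].mean()) for c in range(3)) \
        if bg.any() else None
    return ReferenceColorStats(means=means, sds=sds, bg_means=bg_means)


@lru_cache(maxsize=1)
def default_reference() -> ReferenceColorStats:
    """Reference statistics of the canonical undegraded phantom."""
    from .phantom import canonical_phantom
    return compute_reference_stats(canonical_phantom().image)


def normalize_color(image: np.ndarray,
                    ref: ReferenceColorStats | None = None) -> NormalizedImage:
    """Normalize an RGB tile to the reference color statistics.

    Two stages: (1) illumination flattening — L* divided by the
    best-fit plane through a Gaussian blur of itself at sigma =
    width/4, rescaled to preserve the global mean; (2) per-channel
    linear remap in LAB so the foreground (non-background) mean/SD
    equal the reference; the remap is applied to every pixel.
    Computation stays in floating point; clipping happens only at the
    final uint8 conversion.  Never reads ground truth.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a nonempty HxWx3 RGB image")
    if ref is None:
        ref = default_reference()

    rgbf = image.astype(np.float64)
    lab = rgb2lab(rgbf / 255.0)
    lab = _flatten_illumination(lab, smoothing_scale=image.shape[1] / 4.0)
    fg = _foreground_mask(rgbf)

    degenerate: list[str] = []
    out = np.empty_like(lab)
    for c, name in enumerate(("L", "a", "b")):
        ch = lab[..., c]
        mu, sd = ch[fg].mean(), ch[fg].std()
        if sd < _EPS:
            out[..., c] = ch - mu + ref.means[c]
            degenerate.append(name)
        else:
            out[..., c] = (ch - mu) / sd * ref.sds[c] + ref.means[c]

    bg = ~fg
    if bg.any() and ref.bg_means is not None:
        # empty background is pinned to the reference white point by a
        # mean shift (texture preserved), independent of tissue stats
        for c in range(3):
            ch = lab[..., c][bg]
            out[..., c][bg] = ch - ch.mean() + ref.bg_means[c]

    rgb = lab2rgb(out)  # clips internally to [0, 1]
    rgb8 = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return NormalizedImage(image=rgb8, degenerate_channels=degenerate)


__all__ = [
    "NormalizedImage", "ReferenceColorStats", "compute_reference_stats",
    "default_reference", "normalize_color",
]
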