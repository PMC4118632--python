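"""Nucleus detection and round-vs-spindle classification (pipeline step 3).

In normal pulley tissue the fibroblast nuclei between collagen bundles
are elongated and spindle-shaped; with chondroid metaplasia the nuclei
of cartilage-like cells become rounded.  Detection finds dark
(hematoxylin-stained) connected components inside the tissue mask;
classification applies a double-thresholding scheme on circularity
(4*pi*area/perimeter^2) with an axis-ratio tie-break in the ambiguous
band between the two thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .phantom import ABNORMAL, LABEL_BACKGROUND, NORMAL
from .tissue_seg import luminance

RESOLVED_LOW = "low_threshold"
RESOLVED_HIGH = "high_threshold"
RESOLVED_BAND = "band_rule"


@dataclass(frozen=True)
class NucleusParams:
    """Detection and classification thresholds.

    ``dark_luminance`` selects nuclear-stain candidate pixels within
    tissue.  Components outside [min_nucleus_area, max_nucleus_area] are
    dropped or watershed-split, respectively.  ``t_low``/``t_high`` are
    the circularity double thresholds; nuclei in the band are resolved
    by the ``band_axis_ratio`` rule (axis ratio <= 2 → round/abnormal).
    """

    dark_luminance: float = 95.0
    min_nucleus_area: int = 20
    max_nucleus_area: int = 240
    t_low: float = 0.55
    t_high: float = 0.75
    band_axis_ratio: float = 2.0


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus with its shape descriptors."""

    id: int
    centroid: tuple[float, float]       # (row, col), px
    area: float                         # px
    perimeter: float                    # Crofton perimeter, px
    major_axis: float
    minor_axis: float
    axis_ratio: float                   # major/minor, >= 1
    circularity: float                  # 4*pi*area/perimeter^2
    nucleus_class: str | None = None    # NORMAL | ABNORMAL
    resolved_by: str | None = None


def _split_large(candidates: np.ndarray, comp: np.ndarray,
                 large_ids: np.ndarray, max_area: int) -> np.ndarray:
    """Watershed-split components larger than ``max_area`` on the
    distance transform, seeded at local maxima."""
    out = comp.copy()
    next_id = int(comp.max()) + 1
    for cid in large_ids:
        region = comp == cid
        dist = ndimage.distance_transform_edt(region)
        peaks = peak_local_max(dist, min_distance=4, labels=region,
                               exclude_border=False)
        if len(peaks) < 2:
            continue
        markers = np.zeros_like(comp)
        for k, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = k
        ws = watershed(-dist, markers=markers, mask=region)
        for k in range(1, int(ws.max()) + 1):
            out[ws == k] = next_id
            next_id += 1
    return out


def detect_nuclei(normalized_image: np.ndarray, mask: np.ndarray,
                  params: NucleusParams | None = None) -> list[NucleusRecord]:
    """Detect unclassified nuclei in a normalized tile.

    Candidate pixels are tissue pixels darker than ``dark_luminance``;
    connected components are area-filtered, oversized components are
    split by distance-transform watershed, and shape descriptors are
    taken from second moments (skimage region properties, Crofton
    perimeter).  Deterministic; an empty list is a valid result.
    """
    params = params or NucleusParams()
    Y = luminance(normalized_image)
    candidates = (mask != LABEL_BACKGROUND) & (Y < params.dark_luminance)
    comp, n = ndimage.label(candidates, structure=np.ones((3, 3), int))
    if n == 0:
        return []

    sizes = np.bincount(comp.ravel())
    large = np.flatnonzero(sizes > params.max_nucleus_area)
    large = large[large > 0]
    if large.size:
        comp = _split_large(candidates, comp, large, params.max_nucleus_area)

    records: list[NucleusRecord] = []
    rid = 0
    for prop in regionprops(comp):
        if prop.area < params.min_nucleus_area or \
                prop.area > params.max_nucleus_area:
            continue
        perim = prop.perimeter_crofton
        if perim <= 0:
            continue
        minor = max(prop.axis_minor_length, 1e-6)
        rid += 1
        records.append(NucleusRecord(
            id=rid,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=float(prop.area),
            perimeter=float(perim),
            major_axis=float(prop.axis_major_length),
            minor_axis=float(minor),
            axis_ratio=float(prop.axis_major_length / minor),
            circularity=float(4.0 * math.pi * prop.area / perim**2)))
    return records


def classify_nucleus(rec: NucleusRecord, t_low: float = 0.55,
                     t_high: float = 0.75,
                     band_axis_ratio: float = 2.0) -> NucleusRecord:
    """Classify one nucleus by circularity double-thresholding.

    circularity >= t_high → abnormal (round); circularity <= t_low →
    normal (spindle); in the band, axis_ratio <= ``band_axis_ratio``
    resolves to abnormal, else normal.  Returns a new record with
    ``nucleus_class`` and ``resolved_by`` set.
    """
    if not t_low < t_high:
        raise ValueError("t_low must be < t_high")
    if rec.circularity >= t_high:
        cls, how = ABNORMAL, RESOLVED_HIGH
    elif rec.circularity <= t_low:
        cls, how = NORMAL, RESOLVED_LOW
    elif rec.axis_ratio <= band_axis_ratio:
        cls, how = ABNORMAL, RESOLVED_BAND
    else:
        cls, how = NORMAL, RESOLVED_BAND
    return _dc_replace(rec, nucleus_class=cls, resolved_by=how)


def classify_nuclei(records: list[NucleusRecord],
                    params: NucleusParams | None = None) -> list[NucleusRecord]:
    """Classify every record; order-independent by construction."""
    params = params or NucleusParams()
    return [classify_nucleus(r, params.t_low, params.t_high,
                             params.band_axis_ratio) for r in records]


__all__ = [
    "NucleusParams", "NucleusRecord", "RESOLVED_BAND", "RESOLVED_HIGH",
    "RESOLVED_LOW", "classify_nuclei", "classify_nucleus", "detect_nuclei",
]
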