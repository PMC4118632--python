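"""Severity parameters and specimen aggregation (pipeline step 4).

Two per-image severity parameters quantify chondroid metaplasia:

* Abn-SR — size ratio of the abnormal tissue region: abnormal-pixel
  area over total tissue area (normal + abnormal, background excluded);
* Abn-NR — number ratio of the abnormal nuclei: round-nucleus count
  over total nucleus count.

A specimen contributes many candidate tiles; unsuitable tiles are
discarded by the quantitative suitability proxy, ``k`` tiles (default
10 of 49) are selected uniformly at random, and the specimen-level
parameters are unweighted means over the selected tiles.  Undefined
ratios (no tissue, no nuclei) propagate as missing values and are
excluded from means rather than silently counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoSuitableImagesError, UndefinedStatisticError
from .nuclei import (ABNORMAL, NucleusParams, NucleusRecord, classify_nuclei,
                     detect_nuclei)
from .phantom import LABEL_ABNORMAL, LABEL_NORMAL
from .stain_norm import ReferenceColorStats, normalize_color
from .tissue_seg import (SegParams, SuitabilityParams, segment_tissue,
                         suitability_score)


@dataclass(frozen=True)
class PipelineParams:
    """Bundle of all per-image pipeline thresholds."""

    reference: ReferenceColorStats | None = None   # None = package default
    seg: SegParams = field(default_factory=SegParams)
    nuc: NucleusParams = field(default_factory=NucleusParams)
    suitability: SuitabilityParams = field(default_factory=SuitabilityParams)


@dataclass
class ImageResult:
    """Per-image quantification outcome."""

    image_id: str
    abn_sr: float | None
    abn_nr: float | None
    tissue_px: int
    abnormal_px: int
    n_nuclei_normal: int
    n_nuclei_abnormal: int
    suitability: float
    is_suitable: bool


@dataclass
class SpecimenResult:
    """Specimen-level severity: mean ratios over the selected images."""

    specimen_id: str
    pathological_grade: str | None
    clinical_grade: str | None
    selected_image_ids: list[str]
    mean_abn_sr: float
    mean_abn_nr: float
    n_images_used_sr: int
    n_images_used_nr: int
    warnings: list[str] = field(default_factory=list)


def compute_abn_sr(mask: np.ndarray) -> float | None:
    """Abnormal-area ratio of a tissue label mask; ``None`` (undefined,
    never 0) when the mask has no tissue pixels."""
    n_norm = int(np.count_nonzero(mask == LABEL_NORMAL))
    n_abn = int(np.count_nonzero(mask == LABEL_ABNORMAL))
    if n_norm + n_abn == 0:
        return None
    return n_abn / (n_norm + n_abn)


def compute_abn_nr(records: list[NucleusRecord]) -> float | None:
    """Abnormal-nucleus ratio of a classified nucleus list; ``None``
    when the list is empty."""
    if not records:
        return None
    for r in records:
        if r.nucleus_class is None:
            raise ValueError("nuclei must be classified before ratioing")
    n_abn = sum(1 for r in records if r.nucleus_class == ABNORMAL)
    return n_abn / len(records)


def analyze_image(image: np.ndarray, image_id: str = "image",
                  params: PipelineParams | None = None
                  ) -> tuple[ImageResult, np.ndarray, list[NucleusRecord]]:
    """Run the full four-step pipeline on one RGB tile.

    Returns the :class:`ImageResult` plus the intermediate label mask
    and classified nucleus list (for overlays and debugging).
    """
    params = params or PipelineParams()
    norm = normalize_color(image, params.reference)
    mask = segment_tissue(norm.image, params.seg)
    records = classify_nuclei(detect_nuclei(norm.image, mask, params.nuc),
                              params.nuc)
    abn_sr = compute_abn_sr(mask)
    abn_nr = compute_abn_nr(records)
    score, suitable = suitability_score(mask, len(records), params.suitability)
    n_abn = sum(1 for r in records if r.nucleus_class == ABNORMAL)
    result = ImageResult(
        image_id=image_id, abn_sr=abn_sr, abn_nr=abn_nr,
        tissue_px=int(np.count_nonzero(mask != 0)),
        abnormal_px=int(np.count_nonzero(mask == LABEL_ABNORMAL)),
        n_nuclei_normal=len(records) - n_abn, n_nuclei_abnormal=n_abn,
        suitability=score, is_suitable=suitable)
    return result, mask, records


def select_images(candidates: list[ImageResult], k: int,
                  seed: int) -> list[str]:
    """Select ``k`` image ids uniformly at random among suitable tiles.

    Unsuitable tiles are discarded first; sampling is without
    replacement from the remaining ids via a generator seeded with
    ``seed`` (deterministic per seed).  When fewer than ``k`` suitable
    tiles remain, all of them are returned and a warning is emitted.
    Zero suitable tiles raises :class:`NoSuitableImagesError`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    suitable = [c.image_id for c in candidates if c.is_suitable]
    if not suitable:
        sid = candidates[0].image_id if candidates else "<empty>"
        raise NoSuitableImagesError(sid)
    if len(suitable) <= k:
        if len(suitable) < k:
            warnings.warn(f"only {len(suitable)} suitable images for "
                          f"requested k={k}", stacklevel=2)
        return list(suitable)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(suitable), size=k, replace=False)
    return [suitable[i] for i in sorted(chosen)]


def summarize_specimen(specimen_id: str,
                       selected: list[ImageResult],
                       pathological_grade: str | None = None,
                       clinical_grade: str | None = None) -> SpecimenResult:
    """Aggregate selected image results into a specimen-level result.

    Unweighted arithmetic means over images with defined ratios;
    undefined ratios are excluded and logged.  Raises
    :class:`UndefinedStatisticError` when every ratio is undefined.
    """
    if not selected:
        raise ValueError("at least one selected image is required")
    srs = [r.abn_sr for r in selected if r.abn_sr is not None]
    nrs = [r.abn_nr for r in selected if r.abn_nr is not None]
    if not srs and not nrs:
        raise UndefinedStatisticError(
            f"specimen {specimen_id!r}: all ratios undefined")
    notes = []
    if len(srs) < len(selected):
        notes.append(f"{len(selected) - len(srs)} images with undefined Abn-SR")
    if len(nrs) < len(selected):
        notes.append(f"{len(selected) - len(nrs)} images with undefined Abn-NR")
    return SpecimenResult(
        specimen_id=specimen_id,
        pathological_grade=pathological_grade,
        clinical_grade=clinical_grade,
        selected_image_ids=[r.image_id for r in selected],
        mean_abn_sr=float(np.mean(srs)) if srs else float("nan"),
        mean_abn_nr=float(np.mean(nrs)) if nrs else float("nan"),
        n_images_used_sr=len(srs), n_images_used_nr=len(nrs),
        warnings=notes)


__all__ = [
    "ImageResult", "PipelineParams", "SpecimenResult", "analyze_image",
    "compute_abn_nr", "compute_abn_sr", "select_images", "summarize_specimen",
]
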