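"""Simulated specimen cohorts with a known grade structure.

A cohort emulates the study population: specimens carry a pathological
grade (L/M/H, extent of chondroid metaplasia) and a Froimson clinical
severity grade (II/III/IV), each specimen contributes a set of
candidate microscope tiles of which a fraction is unsuitable (mostly
background, few nuclei), and the specimen-level severity ratios Abn-SR
and Abn-NR are drawn from per-grade calibration distributions.

Candidate tiles are stored as phantom *configurations* (with their own
seeds) and rendered lazily, so generating many cohorts for statistical
checks is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .phantom import (NUCLEUS_CLEARANCE, Phantom, PhantomConfig,
                      generate_phantom)

# random-sequential packing limit assumed when capping how many round
# nuclei a chondroid patch can physically hold
_PACKING_LIMIT = 0.35

PATHOLOGICAL_GRADES = ("L", "M", "H")
CLINICAL_GRADES = ("II", "III", "IV")
ALL_CLINICAL_GRADES = ("I", "II", "III", "IV")   # grade I representable, never simulated


@dataclass(frozen=True)
class GradeCalibration:
    """Specimen-level mean/SD of the two severity ratios for one grade."""

    sr_mean: float
    sr_sd: float
    nr_mean: float
    nr_sd: float


# Per-grade calibration of the generator: specimen-level means and
# sample SDs of Abn-SR and Abn-NR for pathological grades L/M/H.
DEFAULT_GRADE_CALIBRATION: dict[str, GradeCalibration] = {
    "L": GradeCalibration(0.14, 0.03, 0.57, 0.07),
    "M": GradeCalibration(0.20, 0.01, 0.64, 0.04),
    "H": GradeCalibration(0.26, 0.01, 0.74, 0.05),
}

# Conditional distribution of the clinical grade given the pathological
# grade (empirical rows of the study's confusion structure).
DEFAULT_CLINICAL_ASSIGNMENT: dict[str, dict[str, float]] = {
    "L": {"II": 1.0},
    "M": {"II": 3 / 8, "III": 5 / 8},
    "H": {"III": 1 / 8, "IV": 7 / 8},
}

# Exact pathological x clinical counts used by exact-counts mode
# (rows L/M/H, columns II/III/IV).
DEFAULT_EXACT_COUNTS = ((5, 0, 0), (3, 5, 0), (0, 1, 7))


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a simulated cohort.

    Defaults mirror the study conditions: 5/8/8 specimens in grades
    L/M/H, 49 candidate tiles per specimen of which ~20% are unsuitable,
    10 tiles selected.  ``exact_counts`` assigns clinical grades so the
    3x3 contingency table equals ``exact_counts_table`` deterministically;
    otherwise grades are sampled from ``clinical_assignment``.
    ``phantom_template`` sets the canvas and rendering parameters shared
    by all candidate tiles; per-tile degradation is sampled from the
    ``stain_shift_range`` / ``illumination_range`` bounds.
    """

    calibration: dict[str, GradeCalibration] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_CALIBRATION))
    subjects_per_grade: tuple[int, int, int] = (5, 8, 8)
    clinical_assignment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in
                                 DEFAULT_CLINICAL_ASSIGNMENT.items()})
    exact_counts: bool = False
    exact_counts_table: tuple[tuple[int, int, int], ...] = DEFAULT_EXACT_COUNTS
    images_per_specimen_candidates: int = 49
    images_selected: int = 10
    unsuitable_fraction: float = 0.2
    image_jitter_sd: float = 0.02
    phantom_template: PhantomConfig = field(default_factory=PhantomConfig)
    background_fraction_range: tuple[float, float] = (0.05, 0.30)
    unsuitable_background_fraction: float = 0.70
    unsuitable_nucleus_density: float = 0.8
    stain_shift_range: tuple[float, float] = (0.95, 1.05)
    illumination_range: tuple[float, float] = (0.0, 0.08)
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for g, row in self.clinical_assignment.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"clinical_assignment row {g!r} must sum to 1")
            for c in row:
                if c not in ALL_CLINICAL_GRADES:
                    raise ValueError(f"unknown clinical grade {c!r}")
        for cal in self.calibration.values():
            if cal.sr_sd < 0 or cal.nr_sd < 0:
                raise ValueError("calibration SDs must be >= 0")
        if any(n < 0 for n in self.subjects_per_grade):
            raise ValueError("subjects_per_grade must be non-negative")
        if not 0.0 <= self.unsuitable_fraction < 1.0:
            raise ValueError("unsuitable_fraction must lie in [0, 1)")
        if self.images_selected < 1 or self.images_per_specimen_candidates < 1:
            raise ValueError("image counts must be >= 1")
        if self.exact_counts:
            for g, n, row in zip(PATHOLOGICAL_GRADES, self.subjects_per_grade,
                                 self.exact_counts_table):
                if sum(row) != n:
                    raise ValueError(
                        f"exact_counts_table row {g} must sum to {n}")


@dataclass(frozen=True)
class CandidateImage:
    """One candidate tile of a specimen: a phantom config plus its
    by-construction suitability flag.  Rendered on demand."""

    image_id: str
    config: PhantomConfig
    suitable_by_construction: bool

    def render(self) -> Phantom:
        return generate_phantom(self.config)


@dataclass
class SimulatedSpecimen:
    specimen_id: str
    pathological_grade: str
    clinical_grade: str
    true_abn_sr: float
    true_abn_nr: float
    candidates: list[CandidateImage]


@dataclass
class SimulatedCohort:
    specimens: list[SimulatedSpecimen]
    config: CohortConfig

    def contingency_counts(self) -> np.ndarray:
        """3x3 pathological (L/M/H) x clinical (II/III/IV) counts."""
        counts = np.zeros((3, 3), dtype=int)
        for s in self.specimens:
            i = PATHOLOGICAL_GRADES.index(s.pathological_grade)
            j = CLINICAL_GRADES.index(s.clinical_grade)
            counts[i, j] += 1
        return counts

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"specimen_id": s.specimen_id,
              "pathological_grade": s.pathological_grade,
              "clinical_grade": s.clinical_grade,
              "true_abn_sr": s.true_abn_sr,
              "true_abn_nr": s.true_abn_nr,
              "n_candidates": len(s.candidates)}
             for s in self.specimens])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = 0.0, hi: float = 1.0,
                      budget: int = 1000) -> float:
    if sd == 0:
        if not lo <= mean <= hi:
            raise GenerationError("degenerate draw outside bounds")
        return mean
    for _ in range(budget):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise GenerationError("truncated-normal rejection budget exhausted")


def _feasible_nucleus_fraction(template: PhantomConfig, img_sr: float,
                               img_nr: float) -> float:
    """Cap a tile's abnormal-nucleus target by what its chondroid area
    can physically hold.

    Round nuclei are placed without overlap fully inside abnormal
    patches, so a tile with almost no chondroid matrix cannot host a
    large share of the nuclei; the cap follows from the expected
    nucleus footprint and a random-sequential packing limit.  (This is
    also the biologically coherent reading: chondrocyte-like cells sit
    in the chondroid matrix.)
    """
    area = 0.5 * (template.nucleus_area_range[0]
                  + template.nucleus_area_range[1])
    radius = math.sqrt(area / math.pi)
    footprint = math.pi * (radius + NUCLEUS_CLEARANCE) ** 2
    nr_max = _PACKING_LIMIT * img_sr * 1e4 / \
        (template.nucleus_density * footprint)
    return min(img_nr, nr_max)


def _assign_clinical(rng: np.random.Generator, cfg: CohortConfig,
                     grade: str, index_in_grade: int) -> str:
    if cfg.exact_counts:
        row = cfg.exact_counts_table[PATHOLOGICAL_GRADES.index(grade)]
        cum = 0
        for j, n in enumerate(row):
            cum += n
            if index_in_grade < cum:
                return CLINICAL_GRADES[j]
        raise GenerationError("exact-counts row exhausted")
    row = cfg.clinical_assignment[grade]
    grades = sorted(row)
    probs = np.array([row[g] for g in grades])
    return str(rng.choice(grades, p=probs / probs.sum()))


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate one seeded cohort.

    Specimen-level true ratios are drawn from the per-grade calibration
    normals truncated to [0, 1]; per-tile targets are jittered around
    the specimen values; exactly
    ``round(unsuitable_fraction * candidates)`` tiles per specimen are
    built unsuitable (large background, sparse nuclei).  Identical
    config (including seed) reproduces the cohort exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    template = config.phantom_template
    specimens: list[SimulatedSpecimen] = []
    sid = 0

    for grade, n_subjects in zip(PATHOLOGICAL_GRADES, config.subjects_per_grade):
        cal = config.calibration[grade]
        for idx in range(n_subjects):
            sid += 1
            specimen_id = f"S{sid:02d}"
            clinical = _assign_clinical(rng, config, grade, idx)
            sr = _truncated_normal(rng, cal.sr_mean, cal.sr_sd)
            nr = _truncated_normal(rng, cal.nr_mean, cal.nr_sd)

            n_cand = config.images_per_specimen_candidates
            n_unsuitable = int(round(config.unsuitable_fraction * n_cand))
            unsuitable_pos = set(
                rng.permutation(n_cand)[:n_unsuitable].tolist())

            candidates: list[CandidateImage] = []
            for i in range(n_cand):
                img_sr = float(np.clip(rng.normal(sr, config.image_jitter_sd),
                                       0.0, 1.0))
                img_nr = float(np.clip(rng.normal(nr, config.image_jitter_sd),
                                       0.0, 1.0))
                img_nr = _feasible_nucleus_fraction(template, img_sr, img_nr)
                shift = tuple(rng.uniform(*config.stain_shift_range, size=3))
                illum = float(rng.uniform(*config.illumination_range))
                img_seed = int(rng.integers(0, 2**31 - 1))
                if i in unsuitable_pos:
                    pcfg = replace(
                        template,
                        abnormal_fraction_target=img_sr,
                        abnormal_nucleus_fraction=img_nr,
                        background_fraction_target=config.unsuitable_background_fraction,
                        nucleus_density=config.unsuitable_nucleus_density,
                        stain_shift=shift, illumination_gradient_amplitude=illum,
                        noise_sd=config.noise_sd, seed=img_seed)
                    suitable = False
                else:
                    bg = float(rng.uniform(*config.background_fraction_range))
                    pcfg = replace(
                        template,
                        abnormal_fraction_target=img_sr,
                        abnormal_nucleus_fraction=img_nr,
                        background_fraction_target=bg,
                        stain_shift=shift, illumination_gradient_amplitude=illum,
                        noise_sd=config.noise_sd, seed=img_seed)
                    suitable = True
                candidates.append(CandidateImage(
                    image_id=f"{specimen_id}_I{i:02d}", config=pcfg,
                    suitable_by_construction=suitable))

            specimens.append(SimulatedSpecimen(
                specimen_id=specimen_id, pathological_grade=grade,
                clinical_grade=clinical, true_abn_sr=sr, true_abn_nr=nr,
                candidates=candidates))

    return SimulatedCohort(specimens=specimens, config=config)


__all__ = [
    "ALL_CLINICAL_GRADES", "CLINICAL_GRADES", "PATHOLOGICAL_GRADES",
    "CandidateImage", "CohortConfig", "DEFAULT_CLINICAL_ASSIGNMENT",
    "DEFAULT_EXACT_COUNTS", "DEFAULT_GRADE_CALIBRATION", "GradeCalibration",
    "SimulatedCohort", "SimulatedSpecimen", "generate_cohort",
]
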