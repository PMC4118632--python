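"""Shared fixtures: a seeded suite of undegraded phantoms with their
pipeline outputs, and a small end-to-end simulated study."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pulleyquant import PipelineParams, analyze_image
from pulleyquant.cohort import CohortConfig
from pulleyquant.phantom import PhantomConfig, generate_phantom
from pulleyquant.study import StudyConfig, run_study
from pulleyquant.tissue_seg import SuitabilityParams

N_SUITE = 20

# desk-scale canvas used throughout the suite; geometry is in pixels so
# the full-size canvas is only a config change
SUITE_W, SUITE_H = 320, 240


def suite_config(i: int) -> PhantomConfig:
    return PhantomConfig(
        width_px=SUITE_W, height_px=SUITE_H,
        abnormal_fraction_target=0.1 + 0.04 * (i % 10),
        background_fraction_target=0.1 + 0.02 * (i % 5),
        nucleus_density=6.0,
        abnormal_nucleus_fraction=0.5 + 0.03 * (i % 8),
        seed=100 + i)


@pytest.fixture(scope="session")
def phantom_suite():
    """20 undegraded seeded phantoms with their full pipeline outputs:
    list of (phantom, image_result, predicted_mask, classified_records)."""
    out = []
    for i in range(N_SUITE):
        phantom = generate_phantom(suite_config(i))
        result, mask, records = analyze_image(phantom.image, f"suite_{i}")
        out.append((phantom, result, mask, records))
    return out


def match_detections(phantom, records, max_dist: float = 5.0):
    """Pair detections with ground-truth nuclei by nearest centroid.

    Returns (matched_flags, matched_truth) aligned with ``records``.
    """
    truth = phantom.truth.nuclei
    tree = cKDTree(np.array([n.centroid for n in truth]))
    dists, idx = tree.query(np.array([r.centroid for r in records]))
    flags = dists <= max_dist
    return flags, [truth[i] for i in idx]


@pytest.fixture(scope="session")
def study_cohort_config():
    return CohortConfig(
        images_per_specimen_candidates=6, images_selected=4,
        phantom_template=PhantomConfig(width_px=256, height_px=192,
                                       nucleus_density=6.0),
        seed=1)


@pytest.fixture(scope="session")
def study_report(study_cohort_config):
    """One end-to-end simulated study at desk scale (default grade
    calibration and confusion structure)."""
    cfg = StudyConfig(
        cohort=study_cohort_config,
        pipeline=PipelineParams(suitability=SuitabilityParams(
            min_tissue_fraction=0.5, min_nuclei=12)),
        seed=1)
    return run_study(cfg)
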