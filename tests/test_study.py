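"""Study orchestration: end-to-end simulate mode, directory mode,
reproducibility and internal consistency."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from pulleyquant.cohort import CohortConfig, generate_cohort
from pulleyquant.phantom import PhantomConfig, generate_phantom
from pulleyquant.severity import PipelineParams
from pulleyquant.study import StudyConfig, rater_icc, run_study
from pulleyquant.tissue_seg import SuitabilityParams

FAST_PIPELINE = PipelineParams(suitability=SuitabilityParams(
    min_tissue_fraction=0.5, min_nuclei=12))


def test_exact_counts_study_reproduces_contingency_and_kappa():
    """A cohort built with the study's exact confusion counts yields
    the printed 3x3 table and kappa = 0.717."""
    cfg = StudyConfig(
        cohort=CohortConfig(
            images_per_specimen_candidates=3, images_selected=2,
            exact_counts=True,
            phantom_template=PhantomConfig(width_px=192, height_px=144,
                                           nucleus_density=6.0),
            seed=2),
        pipeline=FAST_PIPELINE, seed=2)
    report = run_study(cfg)
    assert [list(r) for r in report.contingency.counts] == \
        [[5, 0, 0], [3, 5, 0], [0, 1, 7]]
    assert round(report.kappa, 3) == 0.717
    assert report.kappa_category == "fair to good"


def test_simulated_study_recovers_grade_structure(study_report,
                                                  study_cohort_config):
    """Grade-monotone means, significant ANOVA, and high correlation of
    pipeline estimates with generator truth."""
    per_spec = study_report.per_specimen
    means = per_spec.groupby("pathological_grade")["mean_abn_sr"].mean()
    assert means["L"] < means["M"] < means["H"]
    nr_means = per_spec.groupby("pathological_grade")["mean_abn_nr"].mean()
    assert nr_means["L"] < nr_means["M"] < nr_means["H"]

    anova = study_report.anova
    sr_row = anova[(anova.grouping == "pathological_grade")
                   & (anova.parameter == "mean_abn_sr")]
    assert float(sr_row.p_value.iloc[0]) < 0.05

    truth = generate_cohort(study_cohort_config).truth_frame()
    merged = truth.merge(per_spec, on="specimen_id")
    r = np.corrcoef(merged.true_abn_sr, merged.mean_abn_sr)[0, 1]
    assert r > 0.9


def test_severity_parameters_positively_correlated(study_report):
    per_spec = study_report.per_specimen
    r = np.corrcoef(per_spec.mean_abn_sr, per_spec.mean_abn_nr)[0, 1]
    assert r > 0.5


def test_grade_summary_consistent_with_per_specimen_rows(study_report):
    gs = study_report.grade_summary
    per_spec = study_report.per_specimen
    for _, row in gs[gs.grouping == "pathological_grade"].iterrows():
        vals = per_spec.loc[per_spec.pathological_grade == row.grade,
                            row.parameter]
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["n"] == len(vals)


def _write_specimen_dir(tmp_path, specimen_id, n_images=3):
    sdir = tmp_path / "images" / specimen_id
    sdir.mkdir(parents=True)
    for i in range(n_images):
        p = generate_phantom(PhantomConfig(
            width_px=192, height_px=144, nucleus_density=6.0,
            abnormal_fraction_target=0.2, seed=50 + i))
        Image.fromarray(p.image).save(sdir / f"img{i}.png")
    return tmp_path / "images"


def test_directory_mode_single_specimen(tmp_path):
    images_dir = _write_specimen_dir(tmp_path, "P01")
    labels = tmp_path / "labels.csv"
    labels.write_text("specimen_id,pathological_grade,clinical_grade\n"
                      "P01,M,III\n")
    cfg = StudyConfig(images_dir=str(images_dir), labels_csv=str(labels),
                      pipeline=FAST_PIPELINE, out_dir=str(tmp_path / "out"),
                      seed=0)
    report = run_study(cfg)
    assert len(report.per_specimen) == 1
    assert 0.1 <= report.per_specimen.mean_abn_sr.iloc[0] <= 0.3
    assert any("insufficient groups" in n for n in report.notes)
    assert (tmp_path / "out" / "per_specimen.csv").exists()


def test_directory_mode_rejects_bad_grade(tmp_path):
    images_dir = _write_specimen_dir(tmp_path, "P01", n_images=1)
    labels = tmp_path / "labels.csv"
    labels.write_text("specimen_id,pathological_grade,clinical_grade\n"
                      "P01,X,III\n")
    cfg = StudyConfig(images_dir=str(images_dir), labels_csv=str(labels),
                      pipeline=FAST_PIPELINE, seed=0)
    with pytest.raises(ValueError):
        run_study(cfg)


def test_rerun_byte_reproduces_outputs(tmp_path):
    cfg = CohortConfig(
        images_per_specimen_candidates=2, images_selected=2,
        subjects_per_grade=(1, 1, 1),
        unsuitable_fraction=0.0,
        phantom_template=PhantomConfig(width_px=192, height_px=144,
                                       nucleus_density=6.0),
        seed=4)
    outputs = []
    for run in ("a", "b"):
        out = tmp_path / run
        run_study(StudyConfig(cohort=cfg, pipeline=FAST_PIPELINE,
                              out_dir=str(out), seed=4))
        outputs.append({f.name: f.read_bytes()
                        for f in sorted(out.iterdir())})
    assert outputs[0] == outputs[1]


def test_config_validation():
    with pytest.raises(ValueError):
        StudyConfig().validate()
    with pytest.raises(ValueError):
        StudyConfig(cohort=CohortConfig(), images_dir="x").validate()
    with pytest.raises(ValueError):
        StudyConfig(images_dir="x").validate()


def test_rater_icc_on_encoded_grades():
    grades = np.array([[2, 2], [3, 3], [4, 4], [2, 3], [3, 3], [4, 4]],
                      dtype=float)
    assert 0.5 < rater_icc(grades) <= 1.0


def test_manifest_records_seed_and_config(study_report):
    assert study_report.manifest["seed"] == 1
    assert study_report.manifest["mode"] == "simulate"
    assert study_report.manifest["cohort_config"]["seed"] == 1
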