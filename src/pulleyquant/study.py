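"""End-to-end study orchestration.

Runs the full severity-correlation study on either a simulated cohort
or a directory of per-specimen image tiles: per-image quantification
(normalize → segment → nuclei → ratios), suitability screening and
random tile selection, specimen aggregation, and the result surface of
the study — grade-wise means ± SD for both grading systems, one-way
ANOVA with LSD post-hoc comparisons per parameter per grouping, the
pathological x clinical contingency table with percentages and Cohen's
kappa, boxplot summaries, and an optional inter-rater ICC.

The specimen (not the image) is the statistical unit: ANOVA operates on
specimen means.  Re-running an identical config reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .cohort import (CLINICAL_GRADES, PATHOLOGICAL_GRADES, CohortConfig,
                     SimulatedCohort, generate_cohort)
from .exceptions import NoSuitableImagesError, PulleyQuantError, \
    UndefinedStatisticError
from .severity import (ImageResult, PipelineParams, SpecimenResult,
                       analyze_image, select_images, summarize_specimen)
from .stats import (ContingencyTable, GroupSummary, anova_from_summary,
                    boxplot_summary, cohens_kappa, contingency_percentages,
                    icc_inter_rater, lsd_pairwise)

log = logging.getLogger("pulleyquant.study")

VALID_PATHOLOGICAL = set(PATHOLOGICAL_GRADES)
VALID_CLINICAL = {"I", "II", "III", "IV"}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run.

    Exactly one input mode is active: ``cohort`` (simulate mode) or
    ``images_dir`` + ``labels_csv`` (directory mode, one subdirectory of
    PNG/TIFF tiles per specimen).  ``images_selected`` tiles are kept
    per specimen after suitability screening.  All randomness descends
    from ``seed``.
    """

    cohort: CohortConfig | None = None
    images_dir: str | None = None
    labels_csv: str | None = None
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    images_selected: int | None = None     # None = cohort default / all
    out_dir: str | None = None
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        simulate = self.cohort is not None
        directory = self.images_dir is not None
        if simulate == directory:
            raise ValueError("exactly one of cohort / images_dir must be set")
        if directory and self.labels_csv is None:
            raise ValueError("directory mode requires labels_csv")


@dataclass
class StudyReport:
    per_image: pd.DataFrame
    per_specimen: pd.DataFrame
    grade_summary: pd.DataFrame
    anova: pd.DataFrame
    lsd: pd.DataFrame
    boxplots: pd.DataFrame
    contingency: ContingencyTable | None
    kappa: float | None
    kappa_category: str | None
    icc: float | None
    notes: list[str]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write every table plus a JSON report/manifest to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = {"index": False, "float_format": "%.6f"}
        self.per_image.to_csv(out / "per_image.csv", **kw)
        self.per_specimen.to_csv(out / "per_specimen.csv", **kw)
        self.grade_summary.to_csv(out / "grade_summary.csv", **kw)
        self.anova.to_csv(out / "anova.csv", **kw)
        self.lsd.to_csv(out / "lsd_pairwise.csv", **kw)
        self.boxplots.to_csv(out / "boxplot_summaries.csv", **kw)
        report = {
            "kappa": self.kappa, "kappa_category": self.kappa_category,
            "icc": self.icc, "notes": self.notes,
        }
        if self.contingency is not None:
            pct = contingency_percentages(self.contingency)
            report["contingency"] = {
                "rows": list(self.contingency.row_labels),
                "cols": list(self.contingency.col_labels),
                "counts": [list(map(int, r)) for r in self.contingency.counts],
                "row_percentages": [
                    [None if np.isnan(v) else float(v) for v in row]
                    for row in pct["row_percentages"]],
                "row_marginal_percentages":
                    [float(v) for v in pct["row_marginal_percentages"]],
                "col_marginal_percentages":
                    [float(v) for v in pct["col_marginal_percentages"]],
            }
            pd.DataFrame(np.asarray(self.contingency.counts),
                         index=list(self.contingency.row_labels),
                         columns=list(self.contingency.col_labels)
                         ).to_csv(out / "contingency.csv")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str))


def _specimen_inputs_simulated(cohort: SimulatedCohort):
    for s in cohort.specimens:
        yield (s.specimen_id, s.pathological_grade, s.clinical_grade,
               [(c.image_id, c.render().image) for c in s.candidates])


def _specimen_inputs_directory(images_dir: str, labels_csv: str):
    labels = pd.read_csv(labels_csv, dtype=str)
    required = {"specimen_id", "pathological_grade", "clinical_grade"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    root = Path(images_dir)
    for _, row in labels.iterrows():
        sid = row["specimen_id"]
        pg, cg = row["pathological_grade"], row["clinical_grade"]
        if pg not in VALID_PATHOLOGICAL:
            raise ValueError(f"specimen {sid}: invalid pathological grade {pg!r}")
        if cg not in VALID_CLINICAL:
            raise ValueError(f"specimen {sid}: invalid clinical grade {cg!r}")
        sdir = root / sid
        paths = sorted(list(sdir.glob("*.png")) + list(sdir.glob("*.tif"))
                       + list(sdir.glob("*.tiff")))
        if not paths:
            raise FileNotFoundError(f"no images found for specimen {sid}")
        yield (sid, pg, cg,
               [(p.stem, np.asarray(Image.open(p).convert("RGB")))
                for p in paths])


def _grade_rows(per_specimen: pd.DataFrame, grouping: str, param: str,
                order: tuple[str, ...]) -> list[GroupSummary]:
    rows = []
    for g in order:
        vals = per_specimen.loc[per_specimen[grouping] == g, param].dropna()
        if len(vals):
            rows.append(GroupSummary(label=g, n=len(vals),
                                     mean=float(vals.mean()),
                                     sd=float(vals.std(ddof=1))
                                     if len(vals) > 1 else 0.0))
    return rows


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the study defined by ``config`` and return its report.

    Per-specimen failures (no suitable tiles, undefined ratios) are
    recorded as notes; the run raises only when every specimen fails.
    Writes the report to ``config.out_dir`` when set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    notes: list[str] = []

    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
        inputs = _specimen_inputs_simulated(cohort)
        k = config.images_selected or config.cohort.images_selected
    else:
        cohort = None
        inputs = _specimen_inputs_directory(config.images_dir,
                                            config.labels_csv)
        k = config.images_selected

    image_rows: list[dict] = []
    specimen_results: list[SpecimenResult] = []
    for sid, pg, cg, tiles in inputs:
        sel_seed = int(rng.integers(0, 2**31 - 1))
        results: list[ImageResult] = []
        for image_id, image in tiles:
            res, _, _ = analyze_image(image, image_id, config.pipeline)
            results.append(res)
        try:
            if k is None:
                chosen = [r.image_id for r in results if r.is_suitable]
                if not chosen:
                    raise NoSuitableImagesError(sid)
            else:
                chosen = select_images(results, k, sel_seed)
            selected = [r for r in results if r.image_id in set(chosen)]
            spec = summarize_specimen(sid, selected, pg, cg)
        except (NoSuitableImagesError, UndefinedStatisticError) as exc:
            notes.append(f"specimen {sid} failed: {exc}")
            log.warning("specimen %s failed: %s", sid, exc)
            chosen = []
            spec = None
        chosen_set = set(chosen)
        for r in results:
            image_rows.append({
                "specimen_id": sid, "image_id": r.image_id,
                "abn_sr": r.abn_sr, "abn_nr": r.abn_nr,
                "tissue_px": r.tissue_px, "abnormal_px": r.abnormal_px,
                "n_nuclei_normal": r.n_nuclei_normal,
                "n_nuclei_abnormal": r.n_nuclei_abnormal,
                "suitability": r.suitability, "is_suitable": r.is_suitable,
                "selected": r.image_id in chosen_set})
        if spec is not None:
            specimen_results.append(spec)
            notes.extend(f"specimen {sid}: {w}" for w in spec.warnings)

    if not specimen_results:
        raise PulleyQuantError("every specimen failed; no study results")

    per_image = pd.DataFrame(image_rows)
    per_specimen = pd.DataFrame(
        [{"specimen_id": s.specimen_id,
          "pathological_grade": s.pathological_grade,
          "clinical_grade": s.clinical_grade,
          "mean_abn_sr": s.mean_abn_sr, "mean_abn_nr": s.mean_abn_nr,
          "n_images_used_sr": s.n_images_used_sr,
          "n_images_used_nr": s.n_images_used_nr}
         for s in specimen_results])

    # grade I specimens are reported but excluded from the II-IV comparisons
    grade1 = per_specimen["clinical_grade"] == "I"
    if grade1.any():
        notes.append(f"{int(grade1.sum())} grade-I specimens excluded from "
                     "clinical comparisons")

    summary_rows, anova_rows, lsd_rows, box_rows = [], [], [], []
    for grouping, order in (("pathological_grade", PATHOLOGICAL_GRADES),
                            ("clinical_grade", CLINICAL_GRADES)):
        frame = per_specimen[~grade1] if grouping == "clinical_grade" \
            else per_specimen
        for param in ("mean_abn_sr", "mean_abn_nr"):
            groups = _grade_rows(frame, grouping, param, order)
            for g in groups:
                summary_rows.append({"grouping": grouping, "parameter": param,
                                     "grade": g.label, "n": g.n,
                                     "mean": g.mean, "sd": g.sd})
                vals = frame.loc[frame[grouping] == g.label, param].dropna()
                bs = boxplot_summary(vals.to_numpy())
                box_rows.append({
                    "grouping": grouping, "parameter": param,
                    "grade": g.label, "q1": bs.q1, "median": bs.median,
                    "q3": bs.q3, "whisker_low": bs.whisker_low,
                    "whisker_high": bs.whisker_high,
                    "n_outliers": len(bs.outliers)})
            eligible = [g for g in groups if g.n >= 2]
            if len(eligible) < 2:
                notes.append(f"{grouping}/{param}: insufficient groups "
                             "for ANOVA")
                continue
            res = anova_from_summary(eligible)
            anova_rows.append({"grouping": grouping, "parameter": param,
                               "f_statistic": res.f_statistic,
                               "df_between": res.df_between,
                               "df_within": res.df_within,
                               "p_value": res.p_value, "mse": res.mse})
            if res.mse > 0:
                for pr in lsd_pairwise(eligible, res.mse, res.df_within):
                    lsd_rows.append({
                        "grouping": grouping, "parameter": param,
                        "pair": f"{pr.label_a}-{pr.label_b}",
                        "mean_difference": pr.mean_difference,
                        "t_statistic": pr.t_statistic, "df": pr.df,
                        "p_value": pr.p_value})

    contingency = kappa = kcat = None
    agree = per_specimen[~grade1]
    counts = np.zeros((3, 3), dtype=int)
    for _, row in agree.iterrows():
        if row["pathological_grade"] in VALID_PATHOLOGICAL and \
                row["clinical_grade"] in CLINICAL_GRADES:
            i = PATHOLOGICAL_GRADES.index(row["pathological_grade"])
            j = CLINICAL_GRADES.index(row["clinical_grade"])
            counts[i, j] += 1
    if counts.sum() > 0:
        contingency = ContingencyTable(
            counts=tuple(tuple(int(v) for v in r) for r in counts),
            row_labels=PATHOLOGICAL_GRADES, col_labels=CLINICAL_GRADES)
        try:
            kres = cohens_kappa(contingency)
            kappa, kcat = kres.kappa, kres.category
        except UndefinedStatisticError as exc:
            notes.append(f"kappa undefined: {exc}")

    icc = None
    notes.append("inter-rater ICC requires a subjects x raters matrix; "
                 "not available for this run" )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "images_selected": k,
        "mode": "simulate" if config.cohort is not None else "directory",
        "cohort_config": dataclasses.asdict(config.cohort)
        if config.cohort is not None else None,
        "notes": notes,
    }
    report = StudyReport(
        per_image=per_image, per_specimen=per_specimen,
        grade_summary=pd.DataFrame(summary_rows),
        anova=pd.DataFrame(anova_rows), lsd=pd.DataFrame(lsd_rows),
        boxplots=pd.DataFrame(box_rows), contingency=contingency,
        kappa=kappa, kappa_category=kcat, icc=icc, notes=notes,
        manifest=manifest)

    if config.out_dir:
        report.write(config.out_dir)
        if config.make_plots:
            _write_boxplot_figures(per_specimen[~grade1], per_specimen,
                                   Path(config.out_dir))
    return report


def rater_icc(ratings: np.ndarray) -> float:
    """Convenience wrapper: ICC(2,1) of a subjects x raters matrix of
    numerically encoded grades (e.g. II/III/IV → 2/3/4)."""
    return icc_inter_rater(ratings).icc


def _write_boxplot_figures(clin_frame: pd.DataFrame,
                           path_frame: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for grouping, order, frame in (
            ("pathological_grade", PATHOLOGICAL_GRADES, path_frame),
            ("clinical_grade", CLINICAL_GRADES, clin_frame)):
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for ax, param, title in zip(axes, ("mean_abn_sr", "mean_abn_nr"),
                                    ("Abn-SR", "Abn-NR")):
            data = [frame.loc[frame[grouping] == g, param].dropna()
                    for g in order]
            ax.boxplot(data, tick_labels=list(order))
            ax.set_title(title)
            ax.set_xlabel(grouping.replace("_", " "))
        fig.tight_layout()
        fig.savefig(out / f"boxplot_{grouping}.png", dpi=120)
        plt.close(fig)


__all__ = ["StudyConfig", "StudyReport", "rater_icc", "run_study"]
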