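"""End-to-end orchestration: habitats -> features -> selection -> SVM -> stats.

The train/validation design mirrors a two-center study: the validation
cohort is strictly held out — voxel-feature standardization, the k-means
habitat model, the selection cascade and the SVM are all fitted on training
subjects only and then applied, frozen, to validation subjects.

For each requested habitat count k the pipeline produces an
:class:`~habrad.stats.EvaluationReport`; across k it reports the pairwise
DeLong p-value matrix and the silhouette profile, and flags the k with the
highest validation AUC (silhouette is reported alongside, not folded into
the choice).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .catalog import ExtractionConfig, build_catalog, build_feature_table
from .habitats import assign_habitats, fit_habitats, silhouette
from .imaging import correct_bias_field
from .phantom import PhantomSubject
from .selection import SelectionConfig, run_cascade
from .stats import (EvaluationReport, confusion_metrics, decision_curve,
                    delong_test, roc_auc)
from .svm import SVMConfig, grid_search, predict_proba
from .voxel_features import (VoxelFeatureConfig, assemble_voxel_matrix,
                             compute_feature_maps)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    k_list: tuple[int, ...] = tuple(range(1, 11))
    voxel: VoxelFeatureConfig = dc_field(default_factory=VoxelFeatureConfig)
    extraction: ExtractionConfig = dc_field(default_factory=ExtractionConfig)
    selection: SelectionConfig = dc_field(default_factory=SelectionConfig)
    svm: SVMConfig = dc_field(default_factory=SVMConfig)
    bias_correction_order: int = 2   # 0 disables the correction
    silhouette_cap: int = 10_000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if any(k < 1 or k > 10 for k in self.k_list):
            raise ValueError("k values must lie in 1..10")


@dataclass
class SubjectFeatures:
    """Per-subject cache of corrected volumes and the voxel matrix."""

    subject: PhantomSubject
    matrix: np.ndarray
    coords: np.ndarray


def prepare_subjects(subjects: list[PhantomSubject],
                     config: PipelineConfig) -> list[SubjectFeatures]:
    """Bias-correct both contrasts and compute the 38-column voxel matrix."""
    out = []
    for subj in subjects:
        t1, t2 = subj.t1w, subj.t2w
        if config.bias_correction_order > 0:
            t1, _ = correct_bias_field(t1, subj.voi_mask,
                                       config.bias_correction_order)
            t2, _ = correct_bias_field(t2, subj.voi_mask,
                                       config.bias_correction_order)
        subj = PhantomSubject(subj.subject_id, t1, t2, subj.voi_mask,
                              subj.truth)
        m1 = compute_feature_maps(t1, subj.voi_mask, config.voxel)
        m2 = compute_feature_maps(t2, subj.voi_mask, config.voxel)
        matrix, coords = assemble_voxel_matrix(m1, m2, subj.voi_mask)
        out.append(SubjectFeatures(subj, matrix, coords))
    return out


def run_for_k(train: list[SubjectFeatures], validation: list[SubjectFeatures],
              k: int, config: PipelineConfig) -> EvaluationReport:
    """One full modelling round at a fixed habitat count."""
    pooled = np.vstack([sf.matrix for sf in train])
    model = fit_habitats(pooled, k, seed=config.seed)
    sil = None
    if k >= 2:
        Z = model.transform(pooled)
        pooled_labels = np.concatenate([
            assign_habitats(model, sf.matrix, sf.coords,
                            sf.subject.voi_mask.shape).labels[
                tuple(sf.coords.T)]
            for sf in train])
        sil = silhouette(Z, pooled_labels, config.silhouette_cap, config.seed)

    maps = {}
    for sf in train + validation:
        maps[sf.subject.subject_id] = assign_habitats(
            model, sf.matrix, sf.coords, sf.subject.voi_mask.shape,
            sf.subject.subject_id)

    catalog = build_catalog(config.extraction)
    table_train = build_feature_table([sf.subject for sf in train], maps,
                                      catalog, config.extraction)
    table_val = build_feature_table([sf.subject for sf in validation], maps,
                                    catalog, config.extraction)
    y_train = np.array([sf.subject.truth.class_label for sf in train])
    y_val = np.array([sf.subject.truth.class_label for sf in validation])

    trace = run_cascade(table_train.values, y_train, config.selection)
    survivors = trace.lasso_survivors
    if not survivors:
        # penalty wiped everything out: fall back to the mRMR set so a
        # model can still be reported
        logger.warning("k=%d: LASSO retained no features; using mRMR set", k)
        survivors = trace.mrmr_survivors
    Xtr = table_train.values[survivors]
    Xva = table_val.values[survivors]
    # validation NaNs are imputed with training medians
    med = Xtr.median()
    Xtr = Xtr.fillna(med)
    Xva = Xva.fillna(med)

    trained = grid_search(Xtr, y_train, config.svm)
    p_train = predict_proba(trained, Xtr)
    p_val = predict_proba(trained, Xva)

    report = EvaluationReport(
        k=k,
        train_roc=roc_auc(p_train, y_train),
        validation_roc=roc_auc(p_val, y_val),
        train_confusion=confusion_metrics((p_train >= 0.5).astype(int),
                                          y_train),
        validation_confusion=confusion_metrics((p_val >= 0.5).astype(int),
                                               y_val),
        validation_dca=decision_curve(p_val, y_val),
        silhouette=sil,
        extras={
            "chosen_svm": trained.config,
            "n_selected_features": len(survivors),
            "selected_features": list(survivors),
            "train_scores": p_train.tolist(),
            "validation_scores": p_val.tolist(),
        },
    )
    return report


def run_pipeline(train_subjects: list[PhantomSubject],
                 validation_subjects: list[PhantomSubject],
                 config: PipelineConfig | None = None) -> dict:
    """Run every k in ``config.k_list``; return the comparison summary."""
    config = config or PipelineConfig()
    train = prepare_subjects(train_subjects, config)
    validation = prepare_subjects(validation_subjects, config)

    reports: dict[int, EvaluationReport] = {}
    for k in config.k_list:
        logger.info("pipeline: running k=%d", k)
        reports[k] = run_for_k(train, validation, k, config)

    ks = list(config.k_list)
    y_val = np.array([s.truth.class_label for s in validation_subjects])
    delong_p = np.ones((len(ks), len(ks)))
    for i, ka in enumerate(ks):
        for j, kb in enumerate(ks):
            if j <= i:
                continue
            _, _, p = delong_test(reports[ka].extras["validation_scores"],
                                  reports[kb].extras["validation_scores"],
                                  y_val)
            delong_p[i, j] = delong_p[j, i] = p

    val_aucs = {k: reports[k].validation_roc.auc for k in ks}
    best_k = max(ks, key=lambda k: (val_aucs[k], -k))
    silhouettes = {k: reports[k].silhouette for k in ks}
    result = {
        "seed": config.seed,
        "k_list": ks,
        "reports": {k: r.to_dict() for k, r in reports.items()},
        "validation_auc": val_aucs,
        "silhouette": silhouettes,
        "delong_p_matrix": delong_p.tolist(),
        "best_k_by_validation_auc": best_k,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "pipeline_report.json").write_text(
            json.dumps(result, indent=1, sort_keys=True))
    return result


def leakage_audit(train_subjects, validation_subjects, k: int,
                  config: PipelineConfig) -> bool:
    """True when permuting validation labels changes no trained artifact."""
    train = prepare_subjects(train_subjects, config)
    validation = prepare_subjects(validation_subjects, config)
    r1 = run_for_k(train, validation, k, config)
    flipped = []
    for s in validation_subjects:
        t = s.truth
        flipped.append(PhantomSubject(
            s.subject_id, s.t1w, s.t2w, s.voi_mask,
            type(t)(t.habitat_label_volume, 1 - t.class_label, t.bias_field)))
    validation2 = prepare_subjects(flipped, config)
    r2 = run_for_k(train, validation2, k, config)
    same_model = r1.extras["chosen_svm"] == r2.extras["chosen_svm"]
    same_features = (r1.extras["selected_features"]
                     == r2.extras["selected_features"])
    same_scores = np.allclose(r1.extras["validation_scores"],
                              r2.extras["validation_scores"])
    return bool(same_model and same_features and same_scores)
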