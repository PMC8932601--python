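"""End-to-end orchestration: simulate -> preprocess -> label -> features ->
channel/band/feature selection -> classify, with persisted artifacts and a
hash-stamped run manifest.

The default flow mirrors the source analysis: selection stages run once on the
full dataset and the chosen features are then cross-validated (optimistic for
generalization; documented). Passing ``nested=True`` instead refits channel,
band and feature selection inside every training fold of the final
cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .evaluation import (ClassifierConfig, confusion_matrix, compute_metrics,
                         fit_predict_cv, loio_plan, loso_plan, make_classifier)
from .labeling import LabelSet, expand_trial_labels, label_recordings
from .preprocessing import (ArtifactConfig, concat_epochs, design_bandpass_fir,
                            apply_fir, reject_artifact_epochs, segment_epochs)
from .spectral import PAIRS, build_feature_table, parse_feature_name
from .stats_select import channel_power_summary, select_channels
from .subset_select import AccuracyRFE, BandSubsetSelector
from .synth import GeneratorConfig, generate_dataset

log = logging.getLogger("anxeeg")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults reproduce the study's settings."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter_low_hz: float = 4.0
    filter_high_hz: float = 45.0
    filter_order: int = 15
    filter_window: str = "hanning"
    epoch_seconds: float = 1.0
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    schemes: tuple[str, ...] = ("SAM", "HAM-A")
    granularities: tuple[int, ...] = (2, 4)
    classifiers: tuple[str, ...] = ("knn", "dt", "rf", "mlp", "svm")
    channel_alpha: float = 0.05
    band_n_repeats: int = 3
    band_cv: int = 5
    selection_rf_trees: int = 100
    rfe_cv: int = 5
    cv_mode: str = "loso"           # "loio" or "loso"
    nested: bool = False
    rf_n_trees: int = 500
    seed: int = 0
    outdir: str = "anxeeg_run"
    persist_recordings: bool = False

    def to_yaml(self, path: Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        gen = d.pop("generator", {})
        art = d.pop("artifact", {})
        rates = gen.pop("artifact_rates", None) if isinstance(gen, dict) else None
        from .synth import ArtifactRates
        gcfg = GeneratorConfig(**gen) if isinstance(gen, dict) else GeneratorConfig()
        if rates:
            gcfg.artifact_rates = ArtifactRates(**rates)
        if isinstance(gcfg.channels, list):
            gcfg.channels = tuple(gcfg.channels)
        if isinstance(gcfg.effect_channels, list):
            gcfg.effect_channels = tuple(gcfg.effect_channels)
        if isinstance(gcfg.effect_bands, list):
            gcfg.effect_bands = tuple(gcfg.effect_bands)
        if isinstance(gcfg.class_prevalence, list):
            gcfg.class_prevalence = tuple(gcfg.class_prevalence)
        for key in ("schemes", "granularities", "classifiers"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(generator=gcfg, artifact=ArtifactConfig(**art), **d)


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256

    def record(self, stage: str, paths: list[Path]) -> None:
        entry = {"stage": stage, "outputs": []}
        for p in paths:
            digest = dio.sha256_file(p)
            entry["outputs"].append({"path": str(p), "sha256": digest})
            self.outputs[str(p)] = digest
        self.stages.append(entry)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"stages": self.stages, "outputs": self.outputs}, indent=1))


def _restrict_pairs(selected_channels):
    return [(l, r) for l, r in PAIRS if l in selected_channels and r in selected_channels]


def _evaluate_cell(features: pd.DataFrame, labels: np.ndarray, subject_ids,
                   cfg: PipelineConfig, kind: str):
    clf_cfg = ClassifierConfig(kind=kind, rf_n_trees=cfg.rf_n_trees,
                               seed=cfg.seed)
    plan = (loio_plan(len(labels)) if cfg.cv_mode == "loio"
            else loso_plan(subject_ids))
    preds = fit_predict_cv(features, labels, clf_cfg, plan)
    classes = tuple(sorted(set(labels.tolist())))
    cm = confusion_matrix(labels, preds, classes)
    report = compute_metrics(cm, feature_vector_length=features.shape[1])
    return cm, report


def _select_features_for(features: pd.DataFrame, labels: np.ndarray,
                         cfg: PipelineConfig, seed: int):
    """Band subset search followed by accuracy-RFE; returns the reduced table
    plus the selection evidence."""
    from sklearn.ensemble import RandomForestClassifier
    est = RandomForestClassifier(n_estimators=cfg.selection_rf_trees,
                                 max_depth=32, random_state=seed)
    bsel = BandSubsetSelector(estimator=est, n_repeats=cfg.band_n_repeats,
                              cv=cfg.band_cv, random_state=seed)
    bsel.fit(features, labels)
    banded = bsel.transform(features)
    rfe = AccuracyRFE(estimator=est, cv=cfg.rfe_cv, random_state=seed)
    rfe.fit(banded, labels)
    final = rfe.transform(banded)
    evidence = {
        "band_scores": {"+".join(k): v for k, v in bsel.scores_.items()},
        "best_bands": list(bsel.best_subset_),
        "rfe_selected": list(rfe.selected_),
        "rfe_trajectory": [[r, a] for r, a in rfe.trajectory_],
    }
    return final, evidence


def _nested_predictions(features: pd.DataFrame, labels: np.ndarray, plan,
                        cfg: PipelineConfig, kind: str) -> np.ndarray:
    """Refit band + feature selection inside every training fold."""
    preds = np.empty(len(labels), dtype=labels.dtype)
    for k, test_idx in enumerate(plan.folds):
        mask = np.ones(len(labels), dtype=bool)
        mask[test_idx] = False
        sub, _ = _select_features_for(features.iloc[mask],
                                      labels[mask], cfg, cfg.seed + k)
        cols = list(sub.columns)
        clf_cfg = ClassifierConfig(kind=kind, rf_n_trees=cfg.rf_n_trees,
                                   seed=cfg.seed)
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.base import clone
        model = Pipeline([("scale", StandardScaler()),
                          ("clf", clone(make_classifier(clf_cfg)))])
        model.fit(features.loc[mask, cols], labels[mask])
        preds[test_idx] = model.predict(features.iloc[test_idx][cols])
    return preds


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and persist artifacts under ``config.outdir``.

    Returns a manifest with a sha256 digest for every written file; two runs
    with the same config and seed produce identical digests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()

    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    manifest.record("config", [cfg_path])

    # 1. simulate
    log.info("simulate: %d subjects x %d trials", config.generator.n_subjects,
             config.generator.n_trials)
    recordings = generate_dataset(config.generator)
    if config.persist_recordings:
        ds_manifest = dio.write_dataset(recordings, outdir / "recordings")
        manifest.record("simulate", [ds_manifest])

    # 2. preprocess: filter, segment, optional EMG rejection
    spec = design_bandpass_fir(config.filter_low_hz, config.filter_high_hz,
                               config.filter_order, config.filter_window,
                               config.generator.fs)
    epochs = concat_epochs([
        segment_epochs(apply_fir(r, spec), config.epoch_seconds)
        for r in recordings])
    epochs = reject_artifact_epochs(epochs, config.artifact)
    log.info("preprocess: %d epochs of %.0f ms", epochs.n_epochs,
             1000 * config.epoch_seconds)

    # 3. channel selection on broadband power (per scheme x granularity)
    power = channel_power_summary(epochs)
    subject_ids = epochs.subject_ids()

    report: dict = {}
    label_rows = []
    for scheme in config.schemes:
        for gran in config.granularities:
            trial_labels = label_recordings(recordings, scheme, gran)
            label_rows += [{"subject_id": s, "trial_id": t, "scheme": scheme,
                            "granularity": gran, "class": c}
                           for (s, t), c in sorted(trial_labels.items())]
            labels = np.asarray(expand_trial_labels(
                trial_labels, provenance=epochs.provenance,
                scheme=scheme, granularity=gran).labels)
            keep = labels != "Unlabelled"
            y = labels[keep]
            cell_key = f"{scheme}_{gran}"
            results = select_channels(power[keep], y, epochs.channels,
                                      alpha=config.channel_alpha)
            selected = [r.channel for r in results if r.significant]
            if len(selected) < 2:   # degenerate selection: keep all channels
                selected = list(epochs.channels)
            log.info("%s: selected channels %s", cell_key, selected)

            features = build_feature_table(epochs, channels=selected,
                                           pairs=_restrict_pairs(selected))
            features = features.loc[keep].reset_index(drop=True)
            subs = subject_ids[keep]

            cell: dict = {
                "channel_tests": [asdict(r) for r in results],
                "selected_channels": selected,
                "class_counts": {c: int((y == c).sum()) for c in set(y.tolist())},
                "classifiers": {},
            }
            if not config.nested:
                final, evidence = _select_features_for(features, y, config,
                                                       config.seed)
                cell["selection"] = evidence
                for kind in config.classifiers:
                    cm, rep = _evaluate_cell(final, y, subs, config, kind)
                    cell["classifiers"][kind] = {
                        "confusion_matrix": cm.counts.tolist(),
                        "classes": list(cm.classes),
                        "metrics": rep.to_dict(),
                    }
            else:
                plan = (loio_plan(len(y)) if config.cv_mode == "loio"
                        else loso_plan(subs))
                for kind in config.classifiers:
                    preds = _nested_predictions(features, y, plan, config, kind)
                    classes = tuple(sorted(set(y.tolist())))
                    cm = confusion_matrix(y, preds, classes)
                    rep = compute_metrics(cm,
                                          feature_vector_length=features.shape[1])
                    cell["classifiers"][kind] = {
                        "confusion_matrix": cm.counts.tolist(),
                        "classes": list(cm.classes),
                        "metrics": rep.to_dict(),
                    }
            report[cell_key] = cell

    labels_path = outdir / "labels.csv"
    dio.write_labels_csv(label_rows, labels_path)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest.record("label", [labels_path])
    manifest.record("report", [report_path])
    manifest.write(outdir / "run_manifest.json")
    return manifest
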