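"""Config-driven pipelines wiring the modules into the four experiments:
three quality regressions (colour e, firmness, SSC) and the maturity
classification, on synthetic or user-supplied data.

Every run writes its intermediates (split CSV, selection JSON, model JSON,
evaluation CSV) plus a manifest with the seed and a hash of the resolved
configuration, so outputs are regenerable from (config, seed) alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import accuracy_report, classify, confusion, fit_classifier
from .errors import DomainError
from .models import evaluate, fit
from .preprocess import kennard_stone_split, snv, spxy_split
from .selection import cars_select, ga_select, spa_select
from .synthetic import (
    DEFAULT_STAGE_PROPORTIONS,
    SynthSpectraParams,
    simulate_quality_table,
    simulate_spectra,
)

logger = logging.getLogger(__name__)

_SELECTORS = {"CARS": cars_select, "GA": ga_select, "SPA": spa_select}


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    target: str = "colour_e"
    n_samples: int = 200
    stage_proportions: tuple = DEFAULT_STAGE_PROPORTIONS
    apply_snv: bool = True
    selection_method: str = "CARS"
    selection_config: dict = dataclasses.field(default_factory=dict)
    model_family: str = "MLR"
    model_hyperparams: dict = dataclasses.field(default_factory=dict)
    split_method: str = "SPXY"
    cal_fraction: float = 0.75
    classify_cal_fraction: float = 2.0 / 3.0
    synth_params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    output_dir: str = "hsifruit_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_proportions"] = list(self.stage_proportions)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, out: Path, stage_files: dict) -> None:
    manifest = {
        "package": "hsifruit",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "outputs": stage_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _synthetic_data(config: PipelineConfig):
    params = SynthSpectraParams(**config.synth_params)
    table = simulate_quality_table(
        config.n_samples, tuple(config.stage_proportions), seed=config.seed
    )
    matrix = simulate_spectra(table, params, seed=config.seed + 1)
    return table, matrix, params


def run_quality_pipeline(config: PipelineConfig):
    """extract -> SNV -> SPXY split -> select -> fit -> evaluate, with artifacts.

    Returns ``(selection_result, regression_model, evaluation_report)``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, matrix, params = _synthetic_data(config)
    logger.info("quality pipeline: target=%s n=%d bands=%d",
                config.target, matrix.n_samples, matrix.values.shape[1])

    work = snv(matrix) if config.apply_snv else matrix
    y = table.column(config.target)

    split = spxy_split(work.values, y, config.cal_fraction)
    Xc, yc = work.values[split.cal_indices], y[split.cal_indices]
    Xp, yp = work.values[split.pred_indices], y[split.pred_indices]

    sel_fn = _SELECTORS[config.selection_method]
    sel_cfg = dict(config.selection_config)
    if config.selection_method in ("CARS", "GA"):
        sel_cfg.setdefault("random_state", config.seed)
    selection = sel_fn(Xc, yc, sel_cfg, grid=matrix.grid)
    logger.info("selected %d/%d bands with %s",
                selection.n_selected, matrix.values.shape[1], selection.method)

    model = fit(
        config.model_family, Xc, yc,
        band_indices=selection.selected_band_indices,
        hyperparams=config.model_hyperparams,
        seed=config.seed,
        preprocessing_tag=work.preprocessing_tag,
        wavelengths=selection.selected_wavelengths,
    )
    report = evaluate(yc, model.predict(Xc), yp, model.predict(Xp))

    table.to_csv(out / "quality_table.csv")
    split.to_csv(out / "split.csv", sample_ids=work.sample_ids)
    selection.to_json(out / "selection.json")
    model.to_json(out / "model.json")
    pd.DataFrame([report.to_row()]).to_csv(out / "evaluation.csv", index=False)
    _write_manifest(config, out, {
        "quality_table": "quality_table.csv", "split": "split.csv",
        "selection": "selection.json", "model": "model.json",
        "evaluation": "evaluation.csv",
    })
    return selection, model, report


def run_maturity_pipeline(config: PipelineConfig):
    """KS 2:1 stratified split, fit PLS-DA/SKNN/SVM, emit accuracy table.

    Returns ``(models, reports)`` keyed by family.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, matrix, params = _synthetic_data(config)
    labels = np.array([s.value for s in table.stages])
    if len(set(labels)) < 3:
        raise DomainError("maturity pipeline needs all three stages present")

    work = snv(matrix) if config.apply_snv else matrix
    split = kennard_stone_split(
        work.values, config.classify_cal_fraction, stratify_labels=labels
    )
    Xc, yc = work.values[split.cal_indices], labels[split.cal_indices]
    Xp, yp = work.values[split.pred_indices], labels[split.pred_indices]

    models, reports, rows = {}, {}, []
    for family in ("PLSDA", "SKNN", "SVM"):
        model = fit_classifier(family, Xc, yc, seed=config.seed)
        cm_cal = confusion(yc, classify(model, Xc), set_name="cal")
        cm_pred = confusion(yp, classify(model, Xp), set_name="pred")
        rep = accuracy_report(cm_cal, cm_pred)
        models[family], reports[family] = model, rep
        rows.append({"Model": family, **rep.to_row()})
        cm_pred.to_frame().to_csv(out / f"confusion_pred_{family}.csv")
        cm_cal.to_frame().to_csv(out / f"confusion_cal_{family}.csv")
        logger.info("%s: cal %.2f%% pred %.2f%% total %.2f%%",
                    family, rep.acc_cal, rep.acc_pred, rep.acc_total)

    pd.DataFrame(rows).to_csv(out / "maturity_accuracy.csv", index=False)
    split.to_csv(out / "split.csv", sample_ids=work.sample_ids)
    table.to_csv(out / "quality_table.csv")
    _write_manifest(config, out, {
        "quality_table": "quality_table.csv", "split": "split.csv",
        "accuracy": "maturity_accuracy.csv",
    })
    return models, reports
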