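"""Config-driven orchestration of the full analysis.

``run_pipeline`` executes simulate -> preprocess -> features -> select ->
train -> evaluate and writes every stage artifact under one directory. A
single master seed deterministically derives all stage seeds, and each JSON/
CSV output embeds the configuration hash and package version, so a rerun
with the same config and seed reproduces byte-identical text outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import ModelSpec, TrainedModel, cross_validate, default_model_specs, train
from .evaluation import SplitPlan, evaluate_holdout
from .feature_select import NCAConfig, fit_selection
from .preprocess import EpochSpec, EpochTable, FilterSpec, IICP_THRESHOLD_MMHG, preprocess_subject
from .protocol_sim import ProtocolConfig, SpectralProfile, generate_cohort, write_cohort
from .qeeg_features import BandDefinition, FEATURE_REGISTRY, extract_feature_table

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

logger = logging.getLogger("qeegicp")


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; maps 1:1 to a flat YAML file."""

    protocol: ProtocolConfig = ProtocolConfig()
    profile: SpectralProfile = SpectralProfile()
    filter_spec: FilterSpec = FilterSpec()
    epoch_spec: EpochSpec = EpochSpec()
    bands: BandDefinition = BandDefinition()
    nca: NCAConfig = NCAConfig()
    feature_bank: tuple[str, ...] = FEATURE_REGISTRY
    iicp_threshold: float = IICP_THRESHOLD_MMHG
    n_validation_subjects: int = 9
    n_selected: int = 10
    alpha: float = 0.05
    cv_folds: int = 5
    n_boot: int = 1000
    svm_max_train: int | None = 8000
    seed: int = 42
    write_cohort_files: bool = True

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        return {f.name: encode(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "protocol": ProtocolConfig,
            "filter_spec": FilterSpec,
            "epoch_spec": EpochSpec,
            "nca": NCAConfig,
        }
        for key, value in raw.items():
            if key in nested:
                if isinstance(value, dict):
                    value = {
                        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                    }
                    kwargs[key] = nested[key](**value)
                else:
                    raise ValueError(f"{key} must be a mapping")
            elif key == "profile":
                if value == "flat":
                    kwargs[key] = SpectralProfile.flat()
                elif isinstance(value, dict):
                    kwargs[key] = SpectralProfile(
                        **{k: np.array(v) if k == "band_weights" else
                           tuple(v) if isinstance(v, list) else v
                           for k, v in value.items()}
                    )
                else:
                    raise ValueError("profile must be a mapping or 'flat'")
            elif key == "bands":
                rows = value["bands"] if isinstance(value, dict) else value
                kwargs[key] = BandDefinition(tuple(tuple(b) for b in rows))
            elif key == "feature_bank":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) derived from the master seed."""
    names = ("cohort", "nca", "models", "cv", "bootstrap")
    state = np.random.SeedSequence(master_seed).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, state)}


def _write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _csv_with_header(frame: pd.DataFrame, path: Path, meta: dict) -> None:
    header = "# " + json.dumps(meta, sort_keys=True) + "\n"
    _write_text(path, header + frame.to_csv(index=False))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; returns a manifest of artifact paths and key results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    meta = {"config_hash": config.config_hash(), "version": __version__}
    t0 = time.perf_counter()

    config.to_yaml(outdir / "config.yaml")

    # --- simulate -----------------------------------------------------------
    cohort = generate_cohort(config.protocol, config.profile, seeds["cohort"])
    if config.write_cohort_files:
        write_cohort(cohort, outdir / "cohort")
    logger.info("simulate: %d subjects in %.1fs", len(cohort), time.perf_counter() - t0)

    # --- preprocess + features ---------------------------------------------
    t1 = time.perf_counter()
    frames = []
    epoch_meta = []
    for rec in cohort:
        table = preprocess_subject(rec, config.filter_spec, config.epoch_spec,
                                   threshold=config.iicp_threshold)
        frames.append(
            extract_feature_table(table, config.bands, config.feature_bank)
        )
        em = table.frame[["subject_id", "start_s", "phase", "mean_icp", "iicp_label"]].copy()
        em["source_file"] = f"cohort/{rec.subject_id}.edf"
        em["start_index"] = (em["start_s"] * rec.eeg_fs).round().astype(int)
        epoch_meta.append(em)
    features = pd.concat(frames, ignore_index=True)
    _csv_with_header(pd.concat(epoch_meta, ignore_index=True),
                     outdir / "epoch_table.csv", meta)
    _csv_with_header(features, outdir / "feature_table.csv", meta)
    logger.info("features: %d epochs x %d features in %.1fs",
                len(features), len(config.feature_bank), time.perf_counter() - t1)

    # --- split + select -----------------------------------------------------
    t1 = time.perf_counter()
    plan = SplitPlan.by_cohort_order(
        features["subject_id"], n_validation=config.n_validation_subjects
    )
    deriv = features[features["subject_id"].isin(plan.derivation)]
    nca_cfg = dataclasses.replace(config.nca, seed=seeds["nca"])
    norm_params, selection = fit_selection(
        deriv, config.feature_bank, cfg=nca_cfg,
        k=config.n_selected, alpha=config.alpha,
    )
    _write_text(outdir / "selection.json",
                selection.to_json(config_echo={**meta, "nca": dataclasses.asdict(nca_cfg)}))
    logger.info("select: %s in %.1fs", list(selection.selected), time.perf_counter() - t1)

    # --- train + cross-validate --------------------------------------------
    t1 = time.perf_counter()
    Xd = norm_params.transform(deriv)[list(selection.selected)]
    yd = deriv["iicp_label"].to_numpy()
    gd = deriv["subject_id"].to_numpy()
    models: list[TrainedModel] = []
    for spec in default_model_specs(seed=seeds["models"], svm_max_train=config.svm_max_train):
        model = train(spec, Xd, yd, subjects=gd)
        models.append(model)
        _write_text(
            outdir / "models" / f"{spec.algorithm}.json",
            json.dumps({**meta, "spec": dataclasses.asdict(spec),
                        "features": list(selection.selected)}, indent=2, sort_keys=True),
        )
        if config.cv_folds >= 2:
            cv = cross_validate(spec, Xd, yd, gd, k=config.cv_folds, seed=seeds["cv"])
            _csv_with_header(cv, outdir / "cv" / f"{spec.algorithm}_cv.csv", meta)
    logger.info("train: %d models in %.1fs", len(models), time.perf_counter() - t1)

    # --- evaluate -----------------------------------------------------------
    t1 = time.perf_counter()
    reports, comparison = evaluate_holdout(
        models, features, plan, norm_params, selection,
        n_boot=config.n_boot, seed=seeds["bootstrap"],
    )
    for name, report in reports.items():
        _write_text(outdir / "eval" / f"{name}_report.json", report.to_json(metadata=meta))
        _csv_with_header(
            pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}),
            outdir / "eval" / f"{name}_roc.csv", meta,
        )
        _csv_with_header(
            pd.DataFrame(
                [{"": "pred_0", "true_0": report.tn, "true_1": report.fn},
                 {"": "pred_1", "true_0": report.fp, "true_1": report.tp}]
            ),
            outdir / "eval" / f"{name}_confusion.csv", meta,
        )
    _csv_with_header(comparison, outdir / "eval" / "comparison.csv", meta)
    logger.info("evaluate: %d epochs in %.1fs",
                reports[models[0].spec.algorithm].n_epochs, time.perf_counter() - t1)

    return {
        "outdir": str(outdir),
        "config_hash": meta["config_hash"],
        "n_subjects": len(cohort),
        "n_epochs": len(features),
        "selected": list(selection.selected),
        "plan": plan,
        "reports": reports,
        "comparison": comparison,
    }
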