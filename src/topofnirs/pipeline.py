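"""End-to-end orchestration: simulate → preprocess → features → train → …

:func:`run_pipeline` executes the stages named in a single YAML/dict
config, writes every stage's artifact under an output directory, and
returns a :class:`RunManifest` tracing outputs to config hashes, seeds
and wall-clock times.  Identical config + seed reproduces identical
artifact hashes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path


from . import io
from .ablation import AblationSpec, run_ablation
from .data import concatenate_epoch_sets
from .graph import FeatureConfig, epoch_set_features
from .model import ModelConfig
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import SimConfig, simulate_dataset
from .train import (
    TrainConfig,
    crossvalidate_loso,
    crossvalidate_subjects,
    feature_group_stats,
    make_subject_folds,
    prepare_inputs,
)

STAGES = ("simulate", "preprocess", "features", "train", "loso", "ablate", "stats")


class DependencyError(RuntimeError):
    """A stage's required input artifact is missing."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages_run: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> sha256
    wall_clock_s: dict[str, float] = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": io.config_hash(self.config),
            "seed": self.seed,
            "stages_run": self.stages_run,
            "artifacts": self.artifacts,
            "wall_clock_s": self.wall_clock_s,
            "results": self.results,
        }


def _cfg(section: dict | None, cls):
    return cls(**(section or {}))


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the stages listed in ``config["stages"]`` in canonical order.

    ``config`` is a dict or a path to a YAML file with optional sections
    ``simulate``, ``preprocess``, ``features``, ``model``, ``train``,
    ``ablate`` and a ``stages`` list.  ``seed`` overrides the simulation
    and training seeds.  Artifacts (HDF5 epochs, CSV tables, JSON
    reports) land in ``out_dir``; the manifest is written there too.
    """
    if not isinstance(config, dict):
        config = io.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or ["simulate", "preprocess", "features", "train"]
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    if seed is None:
        seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)

    recordings = None
    epoch_set = None
    inputs = None

    def _record(stage, t0, **artifacts):
        manifest.stages_run.append(stage)
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
        for name, path in artifacts.items():
            manifest.artifacts[name] = io.file_sha256(path)

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()

        if stage == "simulate":
            sim_cfg = _cfg(config.get("simulate"), SimConfig)
            sim_cfg.seed = seed
            dataset = simulate_dataset(sim_cfg)
            recordings = dataset.recordings
            paths = {}
            for rec in recordings:
                p = out / f"recording_subject{rec.subject_id}.h5"
                io.save_recording(p, rec)
                paths[p.name] = p
            _record(stage, t0, **paths)

        elif stage == "preprocess":
            if recordings is None:
                src = config.get("input_recordings")
                if not src:
                    raise DependencyError(
                        "preprocess needs simulated recordings or input_recordings"
                    )
                recordings = [io.load_recording(p) for p in src]
            pre_cfg = _cfg(config.get("preprocess"), PreprocessConfig)
            epoch_set = concatenate_epoch_sets(
                [preprocess_recording(r, pre_cfg) for r in recordings]
            )
            p = out / "epochs.h5"
            io.save_epoch_set(p, epoch_set, io.config_hash(config))
            _record(stage, t0, **{p.name: p})

        elif stage == "features":
            if epoch_set is None:
                raise DependencyError("features needs the epochs artifact")
            feat_cfg = _cfg(config.get("features"), FeatureConfig)
            pair_feats, f3, eff = epoch_set_features(epoch_set, feat_cfg)
            p = out / "features.csv"
            io.write_feature_table(
                p, pair_feats, eff, epoch_set.labels, epoch_set.subject_ids
            )
            inputs = prepare_inputs(epoch_set, feat_cfg)
            _record(stage, t0, **{p.name: p})

        elif stage in ("train", "loso"):
            if epoch_set is None:
                raise DependencyError(f"{stage} needs the epochs artifact")
            if inputs is None:
                inputs = prepare_inputs(
                    epoch_set, _cfg(config.get("features"), FeatureConfig)
                )
            model_cfg = _cfg(config.get("model"), ModelConfig)
            train_cfg = _cfg(config.get("train"), TrainConfig)
            train_cfg.seed = seed
            if stage == "train":
                folds = make_subject_folds(epoch_set, train_cfg.n_folds, seed)
                report = crossvalidate_subjects(inputs, folds, model_cfg, train_cfg)
            else:
                report = crossvalidate_loso(inputs, model_cfg, train_cfg)
            p = out / f"{stage}_report.json"
            agg = report.aggregate()
            io.write_json(p, {
                "aggregate": agg,
                "folds": [
                    {k: f[k] for k in ("tag", "n_test", "accuracy", "kappa",
                                       "macro_auc")}
                    for f in report.folds
                ],
            })
            pcsv = out / f"{stage}_folds.csv"
            report.to_frame().to_csv(pcsv, index=False)
            manifest.results[stage] = agg
            _record(stage, t0, **{p.name: p, pcsv.name: pcsv})

        elif stage == "ablate":
            if epoch_set is None:
                raise DependencyError("ablate needs the epochs artifact")
            ab = config.get("ablate") or {}
            spec = AblationSpec(
                variants=tuple(ab.get("variants", ("full",))),
                threshold_grid=tuple(ab["threshold_grid"]) if ab.get("threshold_grid") else None,
                window_grid=tuple(map(tuple, ab["window_grid"])) if ab.get("window_grid") else None,
                fusion_strategies=tuple(ab["fusion_strategies"]) if ab.get("fusion_strategies") else None,
                seeds=tuple(ab.get("seeds", (seed,))),
                train_accuracy=bool(ab.get("train_accuracy", False)),
            )
            table = run_ablation(
                spec, epoch_set,
                _cfg(config.get("features"), FeatureConfig),
                _cfg(config.get("model"), ModelConfig),
                _cfg(config.get("train"), TrainConfig),
                recordings=recordings,
                pre_cfg=_cfg(config.get("preprocess"), PreprocessConfig),
            )
            p = out / "ablation.csv"
            table.to_csv(p, index=False)
            manifest.results["ablate"] = table.to_dict(orient="records")
            _record(stage, t0, **{p.name: p})

        elif stage == "stats":
            if epoch_set is None:
                raise DependencyError("stats needs the epochs artifact")
            if inputs is None:
                inputs = prepare_inputs(
                    epoch_set, _cfg(config.get("features"), FeatureConfig)
                )
            table = feature_group_stats(inputs.pair_feats, inputs.labels)
            p = out / "feature_stats.csv"
            table.to_csv(p, index=False)
            n_sig = int(table["significant"].sum())
            manifest.results["stats"] = {"n_significant": n_sig,
                                         "n_tests": len(table)}
            _record(stage, t0, **{p.name: p})

    io.write_json(out / "manifest.json", manifest.to_dict())
    return manifest
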