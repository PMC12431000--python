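"""Ablation harnesses: module variants, threshold/window sweeps, fusion.

Four experiment families probe where the decoding signal lives:

* module ablation — removing the graph-feature block, fixing the pair
  attention to uniform, or replacing the Bi-LSTM with mean pooling;
* a sweep of the global connection threshold, reporting the average
  functional-connectivity efficiency (AE, in percent) and optionally
  accuracy at each threshold;
* a sweep over epoch length and sliding-window length, re-segmenting the
  recordings per grid point;
* feature-fusion strategies applied to the blocks of ``f3`` before
  concatenation (plain, per-block z-score, per-block min–max, fixed
  per-block weights).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .data import EpochSet, HemodynamicRecording, concatenate_epoch_sets
from .graph import FeatureConfig, average_efficiency
from .model import ModelConfig, VARIANTS
from .preprocess import PreprocessConfig, preprocess_recording
from .train import (
    ModelInputs,
    TrainConfig,
    confusion_matrix,
    accuracy,
    prepare_inputs,
    train_model,
)


class AblationConfigError(ValueError):
    pass


@dataclass
class AblationSpec:
    """Which ablation axes to run; empty/None axes are skipped."""

    variants: tuple[str, ...] = ("full",)
    threshold_grid: tuple[float, ...] | None = None
    window_grid: tuple[tuple[float, float], ...] | None = None  # (epoch_s, L_s)
    fusion_strategies: tuple[str, ...] | None = None
    seeds: tuple[int, ...] = (0,)
    train_accuracy: bool = True  # also train/evaluate where applicable

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise AblationConfigError(f"unknown variant {v!r}")
        if self.fusion_strategies:
            for s in self.fusion_strategies:
                if s not in FUSION_STRATEGIES:
                    raise AblationConfigError(f"unknown fusion strategy {s!r}")
        if not self.variants and not self.threshold_grid and not self.window_grid \
                and not self.fusion_strategies:
            raise AblationConfigError("ablation spec selects nothing to run")


FUSION_STRATEGIES = ("concat", "zscore_concat", "minmax_concat", "fixed_weighted")


def f3_block_slices(n_pairs: int, n_timepoints: int) -> dict[str, slice]:
    c_t = 2 * n_pairs * n_timepoints
    return {
        "f1": slice(0, c_t),
        "f2": slice(c_t, c_t + 3 * n_pairs),
        "e": slice(c_t + 3 * n_pairs, c_t + 3 * n_pairs + 1),
    }


def apply_fusion(
    f3: np.ndarray,
    strategy: str,
    blocks: dict[str, slice],
    fit_idx: np.ndarray | None = None,
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Rescale the blocks of ``f3`` before concatenation.

    Normalization statistics are fit on ``fit_idx`` rows (train split) and
    applied to all rows.  ``fixed_weighted`` multiplies each block by a
    constant weight (all 1.0 reproduces plain concatenation exactly).
    """
    if strategy not in FUSION_STRATEGIES:
        raise AblationConfigError(f"unknown fusion strategy {strategy!r}")
    if strategy == "concat":
        return f3.copy()
    out = f3.copy()
    fit = f3 if fit_idx is None else f3[fit_idx]
    for name, sl in blocks.items():
        block_fit = fit[:, sl]
        if strategy == "zscore_concat":
            mu = block_fit.mean(axis=0)
            sd = block_fit.std(axis=0)
            sd[sd == 0] = 1.0
            out[:, sl] = (f3[:, sl] - mu) / sd
        elif strategy == "minmax_concat":
            lo = block_fit.min(axis=0)
            hi = block_fit.max(axis=0)
            span = hi - lo
            span[span == 0] = 1.0
            out[:, sl] = (f3[:, sl] - lo) / span
        else:  # fixed_weighted
            w = 1.0 if weights is None else weights.get(name, 1.0)
            out[:, sl] = f3[:, sl] * w
    return out


def _single_split_accuracy(
    inputs: ModelInputs,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    variant: str,
    seed: int,
    test_fraction: float = 0.3,
) -> float:
    """Accuracy (%) of one stratified train/test split under ``seed``."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(inputs.labels):
        idx = np.flatnonzero(inputs.labels == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    train_idx, test_idx = np.array(sorted(train_idx)), np.array(sorted(test_idx))
    cfg = _dc_replace(train_cfg, seed=seed)
    model, _ = train_model(inputs, train_idx, model_cfg, cfg, variant)
    test = inputs.take(test_idx)
    preds = model.predict(test.pair_signals, test.pair_feats, test.f3)
    return accuracy(confusion_matrix(test.labels, preds, inputs.n_classes))


def module_ablation(
    inputs: ModelInputs,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    variants: tuple[str, ...],
    seeds: tuple[int, ...],
) -> pd.DataFrame:
    """Accuracy per (variant, seed) on one stratified holdout split."""
    rows = []
    for variant in variants:
        for seed in seeds:
            acc = _single_split_accuracy(inputs, model_cfg, train_cfg, variant, seed)
            rows.append({"experiment": "module", "variant": variant,
                         "seed": seed, "accuracy": acc})
    return pd.DataFrame(rows)


def threshold_sweep(
    ep: EpochSet,
    feat_cfg: FeatureConfig,
    thresholds: tuple[float, ...],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seeds: tuple[int, ...] = (0,),
    train_accuracy: bool = False,
) -> pd.DataFrame:
    """AE (%) — and optionally accuracy — per global connection threshold."""
    rows = []
    for thr in thresholds:
        cfg = _dc_replace(feat_cfg, adjacency_threshold=thr)
        ae = average_efficiency(ep, cfg)
        row = {"experiment": "threshold", "threshold": thr, "average_efficiency": ae}
        if train_accuracy:
            inputs = prepare_inputs(ep, cfg)
            accs = [
                _single_split_accuracy(inputs, model_cfg, train_cfg, "full", s)
                for s in seeds
            ]
            row["accuracy"] = float(np.mean(accs))
        rows.append(row)
    return pd.DataFrame(rows)


def window_sweep(
    recordings: list[HemodynamicRecording],
    pre_cfg: PreprocessConfig,
    feat_cfg: FeatureConfig,
    grid: tuple[tuple[float, float], ...],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seeds: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Re-segment per (epoch length, window length) and evaluate accuracy."""
    rows = []
    for epoch_s, window_s in grid:
        p_cfg = _dc_replace(pre_cfg, epoch_length_s=epoch_s)
        f_cfg = _dc_replace(feat_cfg, window_length_s=window_s)
        ep = concatenate_epoch_sets(
            [preprocess_recording(r, p_cfg) for r in recordings]
        )
        inputs = prepare_inputs(ep, f_cfg)
        accs = [
            _single_split_accuracy(inputs, model_cfg, train_cfg, "full", s)
            for s in seeds
        ]
        rows.append({
            "experiment": "window", "epoch_length_s": epoch_s,
            "window_length_s": window_s, "n_epochs": ep.n_epochs,
            "accuracy": float(np.mean(accs)),
        })
    return pd.DataFrame(rows)


def fusion_sweep(
    inputs: ModelInputs,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    strategies: tuple[str, ...],
    seeds: tuple[int, ...] = (0,),
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Accuracy per fusion strategy applied to the blocks of f3."""
    n_pairs = inputs.pair_signals.shape[1]
    n_time = inputs.pair_signals.shape[2]
    blocks = f3_block_slices(n_pairs, n_time)
    rows = []
    for strategy in strategies:
        accs = []
        for seed in seeds:
            f3 = apply_fusion(inputs.f3, strategy, blocks, weights=weights)
            mod_inputs = ModelInputs(
                inputs.pair_signals, inputs.pair_feats, f3,
                inputs.labels, inputs.subject_ids,
            )
            accs.append(
                _single_split_accuracy(mod_inputs, model_cfg, train_cfg, "full", seed)
            )
        rows.append({"experiment": "fusion", "strategy": strategy,
                     "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)


def run_ablation(
    spec: AblationSpec,
    ep: EpochSet,
    feat_cfg: FeatureConfig,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    recordings: list[HemodynamicRecording] | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Run the requested ablation families and stack their result tables."""
    frames = []
    inputs = None
    if spec.variants and len(spec.variants) > 0:
        inputs = prepare_inputs(ep, feat_cfg)
        frames.append(
            module_ablation(inputs, model_cfg, train_cfg, spec.variants, spec.seeds)
        )
    if spec.threshold_grid:
        frames.append(
            threshold_sweep(
                ep, feat_cfg, spec.threshold_grid, model_cfg, train_cfg,
                spec.seeds, train_accuracy=spec.train_accuracy,
            )
        )
    if spec.window_grid:
        if recordings is None or pre_cfg is None:
            raise AblationConfigError(
                "window sweep needs the source recordings and a preprocess config"
            )
        frames.append(
            window_sweep(recordings, pre_cfg, feat_cfg, spec.window_grid,
                         model_cfg, train_cfg, spec.seeds)
        )
    if spec.fusion_strategies:
        if inputs is None:
            inputs = prepare_inputs(ep, feat_cfg)
        frames.append(
            fusion_sweep(inputs, model_cfg, train_cfg, spec.fusion_strategies,
                         spec.seeds)
        )
    return pd.concat(frames, ignore_index=True)
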