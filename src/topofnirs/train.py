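"""Training loop, cross-validation protocols, and evaluation metrics.

Two protocols are provided: subject-specific stratified k-fold
cross-validation (folds drawn within each subject) and
leave-one-subject-out (LOSO) cross-validation for cross-subject
generalization.  Metrics are accuracy, Cohen's kappa (generalized to K
classes from the confusion-matrix marginals), and one-vs-rest ROC/AUC
with macro averaging; the AUC of the threshold sweep equals the
Mann–Whitney pair-counting statistic with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .autodiff import Tensor
from .data import EpochSet
from .graph import FeatureConfig, epoch_set_features
from .model import GraphTemporalNet, ModelConfig, cross_entropy, pairs_from_epochs


class FoldError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Optimization settings: Adam with a plateau scheduler on validation
    accuracy, no early stopping (the best-validation checkpoint is kept)."""

    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 5
    max_epochs: int = 200
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    min_lr: float = 1e-5
    val_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be ≥ 1")


@dataclass
class ModelInputs:
    """Model-ready arrays derived from an EpochSet."""

    pair_signals: np.ndarray  # (N, Cp, T, 2)
    pair_feats: np.ndarray  # (N, Cp, 3)
    f3: np.ndarray  # (N, D)
    labels: np.ndarray
    subject_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def take(self, idx) -> "ModelInputs":
        idx = np.asarray(idx)
        return ModelInputs(
            self.pair_signals[idx], self.pair_feats[idx], self.f3[idx],
            self.labels[idx], self.subject_ids[idx],
        )


def prepare_inputs(ep: EpochSet, feat_cfg: FeatureConfig | None = None) -> ModelInputs:
    """Compute graph features and arrange an EpochSet for the model."""
    feat_cfg = feat_cfg or FeatureConfig()
    pair_feats, f3, _ = epoch_set_features(ep, feat_cfg)
    return ModelInputs(
        pair_signals=pairs_from_epochs(ep.epochs, ep.pair_rows()),
        pair_feats=pair_feats,
        f3=f3,
        labels=ep.labels.copy(),
        subject_ids=ep.subject_ids.copy(),
    )


# ---------------------------------------------------------------------------
# cross-validation folds


def _stratified_kfold(labels: np.ndarray, k: int, rng: np.random.Generator):
    """Indices of k stratified folds over ``labels`` (local indices)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def make_subject_folds(
    ep: EpochSet, k: int = 5, seed: int = 0
) -> dict[int, list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified k-fold splits within each subject.

    Returns ``{subject: [(train_idx, val_idx), ...]}`` with global epoch
    indices; folds are disjoint, exhaustive, and deterministic under the
    seed.  Raises :class:`FoldError` if any subject has fewer than ``k``
    epochs of some class.
    """
    out: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for subject in np.unique(ep.subject_ids):
        sub_idx = np.flatnonzero(ep.subject_ids == subject)
        labels = ep.labels[sub_idx]
        counts = np.bincount(labels)
        if counts[counts > 0].min() < k:
            raise FoldError(
                f"subject {subject} has a class with fewer than {k} epochs"
            )
        rng = np.random.default_rng([seed, int(subject)])
        folds = _stratified_kfold(labels, k, rng)
        pairs = []
        for f in range(k):
            val = sub_idx[folds[f]]
            train = np.setdiff1d(sub_idx, val)
            pairs.append((train, val))
        out[int(subject)] = pairs
    return out


def make_loso_folds(ep: EpochSet) -> list[tuple[np.ndarray, int]]:
    """Leave-one-subject-out folds: (training subject array, test subject)."""
    subjects = np.unique(ep.subject_ids)
    if len(subjects) < 2:
        raise FoldError("LOSO needs at least two subjects")
    return [
        (np.setdiff1d(subjects, [s]), int(s)) for s in subjects
    ]


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    k = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    """Overall prediction correctness in percent: 100 · trace / total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(confusion)) / float(total)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e) / (1 − p_e).

    The chance agreement p_e sums the products of row and column
    marginals over classes.  When p_e = 1 (all mass in one cell) kappa is
    defined as 0.
    """
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(confusion) / n
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / n**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _binary_roc(scores: np.ndarray, positive: np.ndarray):
    """Threshold-swept ROC for one class; ties grouped; AUC by trapezoid."""
    order = np.argsort(-scores, kind="stable")
    scores, positive = scores[order], positive[order]
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    tps, fps = [0], [0]
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tps.append(tps[-1] + int(positive[i:j].sum()))
        fps.append(fps[-1] + (j - i) - int(positive[i:j].sum()))
        i = j
    tpr = np.array(tps) / n_pos
    fpr = np.array(fps) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """One-vs-rest ROC points and AUC per class, plus the macro average.

    ``scores`` is (N, K) class scores (probabilities or logits); a class
    without both positives and negatives is skipped and flagged.  The
    trapezoid AUC over the tie-grouped sweep equals
    P(score⁺ > score⁻) + ½·P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    result: dict = {"per_class": {}, "skipped": []}
    aucs = []
    for k in range(scores.shape[1]):
        positive = labels == k
        if positive.all() or not positive.any():
            result["skipped"].append(k)
            continue
        fpr, tpr, auc = _binary_roc(scores[:, k], positive)
        result["per_class"][k] = {"fpr": fpr, "tpr": tpr, "auc": auc}
        aucs.append(auc)
    result["macro_auc"] = float(np.mean(aucs)) if aucs else float("nan")
    return result


@dataclass
class EvalReport:
    """Per-fold metrics and their aggregate for one evaluation protocol."""

    folds: list[dict] = field(default_factory=list)

    def add_fold(self, y_true, y_pred, scores, n_classes: int, tag=None) -> dict:
        cm = confusion_matrix(y_true, y_pred, n_classes)
        roc = roc_auc(scores, y_true)
        fold = {
            "tag": tag,
            "n_test": len(y_true),
            "accuracy": accuracy(cm),
            "kappa": cohen_kappa(cm),
            "confusion": cm,
            "confusion_normalized": cm / np.maximum(cm.sum(axis=1, keepdims=True), 1),
            "macro_auc": roc["macro_auc"],
            "roc": roc,
        }
        self.folds.append(fold)
        return fold

    def aggregate(self) -> dict:
        acc = np.array([f["accuracy"] for f in self.folds])
        kap = np.array([f["kappa"] for f in self.folds])
        auc = np.array([f["macro_auc"] for f in self.folds])
        return {
            "n_folds": len(self.folds),
            "accuracy_mean": float(acc.mean()),
            "accuracy_std": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            "kappa_mean": float(kap.mean()),
            "auc_mean": float(np.nanmean(auc)) if len(auc) else float("nan"),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: f[k] for k in ("tag", "n_test", "accuracy", "kappa", "macro_auc")}
                for f in self.folds
            ]
        )


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay (classic Adam-L2)."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class PlateauScheduler:
    """Multiply the optimizer lr by ``factor`` after ``patience`` epochs
    without improvement of the monitored quantity (higher is better)."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-5):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = -np.inf
        self.stale = 0

    def step(self, metric: float) -> None:
        if metric > self.best:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.stale = 0


def _stratified_holdout(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """(train_idx, val_idx) local split, at least one sample per class in
    the validation part when possible."""
    if fraction <= 0:
        return np.arange(len(labels)), np.array([], dtype=int)
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * len(idx)))) if len(idx) > 1 else 0
        val.extend(idx[:n_val].tolist())
        train.extend(idx[n_val:].tolist())
    return np.array(sorted(train)), np.array(sorted(val))


def train_model(
    inputs: ModelInputs,
    train_idx: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    variant: str = "full",
) -> tuple[GraphTemporalNet, dict]:
    """Train one model on ``inputs[train_idx]``; fully seeded.

    An inner stratified ``val_fraction`` split of the training indices
    drives the plateau scheduler and the best-checkpoint selection; the
    history records per-epoch training loss, validation accuracy and lr.
    """
    rng = np.random.default_rng(train_cfg.seed)
    sub = inputs.take(train_idx)
    tr_loc, va_loc = _stratified_holdout(sub.labels, train_cfg.val_fraction, rng)
    if len(va_loc) == 0:
        tr_loc = np.arange(sub.n)
        va_loc = tr_loc
    tr, va = sub.take(tr_loc), sub.take(va_loc)

    model = GraphTemporalNet(
        n_pairs=inputs.pair_signals.shape[1],
        n_timepoints=inputs.pair_signals.shape[2],
        feature_dim=inputs.f3.shape[1],
        config=model_cfg,
        seed=train_cfg.seed,
        variant=variant,
    )
    opt = Adam(model.parameters(), train_cfg.lr, train_cfg.weight_decay)
    sched = PlateauScheduler(
        opt, train_cfg.scheduler_factor, train_cfg.scheduler_patience,
        train_cfg.min_lr,
    )
    history = {"train_loss": [], "val_accuracy": [], "lr": []}
    best_acc, best_state = -1.0, model.state_dict()

    for _epoch in range(train_cfg.max_epochs):
        order = rng.permutation(tr.n)
        losses = []
        for start in range(0, tr.n, train_cfg.batch_size):
            batch = order[start : start + train_cfg.batch_size]
            b = tr.take(batch)
            logits = model.forward(
                b.pair_signals, b.pair_feats, b.f3, train=True, rng=rng
            )
            loss = cross_entropy(logits, b.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}; lr={opt.lr}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        preds = model.predict(va.pair_signals, va.pair_feats, va.f3)
        val_acc = float(np.mean(preds == va.labels))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
        sched.step(val_acc)

    model.load_state_dict(best_state)
    history["best_val_accuracy"] = best_acc
    return model, history


def crossvalidate_subjects(
    inputs: ModelInputs,
    folds: dict[int, list[tuple[np.ndarray, np.ndarray]]],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    variant: str = "full",
) -> EvalReport:
    """Subject-specific k-fold evaluation; one model per (subject, fold)."""
    report = EvalReport()
    n_classes = inputs.n_classes
    for subject, subject_folds in folds.items():
        for fold_i, (train_idx, val_idx) in enumerate(subject_folds):
            cfg = _dc_replace(train_cfg, seed=train_cfg.seed + 1000 * subject + fold_i)
            model, _ = train_model(inputs, train_idx, model_cfg, cfg, variant)
            test = inputs.take(val_idx)
            scores = model.predict_proba(test.pair_signals, test.pair_feats, test.f3)
            report.add_fold(
                test.labels, scores.argmax(axis=1), scores, n_classes,
                tag=f"subject{subject}_fold{fold_i}",
            )
    return report


def crossvalidate_loso(
    inputs: ModelInputs,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    variant: str = "full",
) -> EvalReport:
    """Leave-one-subject-out evaluation; train subjects never overlap test."""
    subjects = np.unique(inputs.subject_ids)
    if len(subjects) < 2:
        raise FoldError("LOSO needs at least two subjects")
    report = EvalReport()
    for test_subject in subjects:
        train_idx = np.flatnonzero(inputs.subject_ids != test_subject)
        test_idx = np.flatnonzero(inputs.subject_ids == test_subject)
        assert not np.intersect1d(train_idx, test_idx).size
        cfg = _dc_replace(train_cfg, seed=train_cfg.seed + int(test_subject))
        model, _ = train_model(inputs, train_idx, model_cfg, cfg, variant)
        test = inputs.take(test_idx)
        scores = model.predict_proba(test.pair_signals, test.pair_feats, test.f3)
        report.add_fold(
            test.labels, scores.argmax(axis=1), scores, inputs.n_classes,
            tag=f"loso_subject{int(test_subject)}",
        )
    return report


# ---------------------------------------------------------------------------
# interpretability statistics


FEATURE_NAMES = ("strength", "density", "rfsmd")


def feature_group_stats(
    pair_feats: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-pair, per-feature group comparison of the graph features.

    With two groups a two-sided Welch t test is used; with three or more,
    a one-way ANOVA.  Returns a tidy frame with group means/SDs, the test
    statistic, the p value and a significance flag at ``alpha``
    (optionally Benjamini–Hochberg adjusted across all pair × feature
    tests).  Zero within-group variance in every group is flagged as an
    exact tie (statistic 0, p = 1).
    """
    pair_feats = np.asarray(pair_feats, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 epochs")

    rows = []
    for pair in range(pair_feats.shape[1]):
        for fi, fname in enumerate(FEATURE_NAMES):
            samples = [pair_feats[labels == g, pair, fi] for g in groups]
            tie = all(s.std() == 0 for s in samples)
            if tie and all(s.mean() == samples[0].mean() for s in samples):
                stat, p = 0.0, 1.0
            elif len(groups) == 2:
                stat, p = sstats.ttest_ind(samples[0], samples[1], equal_var=False)
            else:
                stat, p = sstats.f_oneway(*samples)
            row = {
                "pair": pair,
                "feature": fname,
                "statistic": float(stat),
                "p_value": float(p),
                "exact_tie": bool(tie),
            }
            for g, s in zip(groups, samples):
                row[f"mean_{g}"] = float(s.mean())
                row[f"sd_{g}"] = float(s.std(ddof=1))
            rows.append(row)
    frame = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        frame["p_adjusted"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        frame["significant"] = frame["p_adjusted"] < alpha
    else:
        frame["significant"] = frame["p_value"] < alpha
    return frame
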