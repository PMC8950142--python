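"""Pretraining, leave-subjects-out fine-tuning and repeated two-fold evaluation.

The evaluation design mirrors a user-independent decoding study: classifiers
are trained on pooled control-subject trials, with the oldest control subject
and the AD subject held out entirely as test subjects.  Trial-level two-fold
cross-validation repeated five times (random stratified re-partitions of the
pooled training trials, the two folds alternating as train/validation) yields
a distribution of validation / control / AD accuracies and macro one-vs-rest
AUCs.  Classifiers can be warm-started from weights pretrained on VAE-
generated synthetic epochs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import nn
from .architectures import ClassifierModel, ModelSpec, build_model
from .preprocess import EpochSet


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stopping_epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.early_stopping_epochs) < 1:
            raise ValueError("epochs, batch size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class PretrainConfig:
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-5
    patience: int = 50
    train_frac: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch size and patience must be positive")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class SplitPlan:
    """Subject-level hold-out: who trains, who is tested."""

    training_subjects: list
    test_subjects: list
    validation_fraction: float = 0.25

    def __post_init__(self):
        overlap = set(self.training_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects in both training and test: {overlap}")


def leave_subjects_out_plan(epoch_sets, groups) -> SplitPlan:
    """Controls train; the oldest control and the AD subject are test-only."""
    train, test = [], []
    for ep in epoch_sets:
        g = groups[ep.subject_id]
        (test if g in ("control_oldest", "ad") else train).append(ep.subject_id)
    return SplitPlan(training_subjects=train, test_subjects=test)


def one_hot(labels, n_classes: int) -> np.ndarray:
    """Rows with a single 1 at each label's class index."""
    idx = np.asarray([getattr(l, "index", l) for l in labels], dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_classes):
        bad = idx[(idx < 0) | (idx >= n_classes)][0]
        raise ValueError(f"label index {bad} outside [0, {n_classes})")
    out = np.zeros((len(idx), n_classes), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def pool_epoch_sets(epoch_sets) -> EpochSet:
    """Concatenate per-subject epoch sets, tracking each trial's subject."""
    if not epoch_sets:
        raise ValueError("no epoch sets to pool")
    first = epoch_sets[0]
    for ep in epoch_sets[1:]:
        if ep.channel_names != first.channel_names:
            raise ValueError("cannot pool epoch sets with different channels")
    data = np.concatenate([ep.data for ep in epoch_sets], axis=0)
    labels = [l for ep in epoch_sets for l in ep.labels]
    subjects = [ep.subject_id for ep in epoch_sets for _ in range(ep.n_trials)]
    pooled = EpochSet(data=data, labels=labels, time_axis=first.time_axis,
                      channel_names=first.channel_names, subject_id="pooled",
                      fs=first.fs, normalized=first.normalized)
    pooled.trial_subjects = subjects
    return pooled


def pretrain(model: ClassifierModel, synthetic_sets, cfg: PretrainConfig):
    """Train on VAE-generated samples with a shuffled 70/30 split.

    ``synthetic_sets`` maps each of the four classes to a SyntheticSampleSet
    (or is a list of four).  The held-out 30% serves as both the validation
    monitor and the final test set; metrics are recorded on the model.
    """
    sets = list(synthetic_sets.values()) if isinstance(synthetic_sets, dict) \
        else list(synthetic_sets)
    if len(sets) != model.spec.N:
        raise ValueError(
            f"expected {model.spec.N} synthetic classes, got {len(sets)}"
        )
    X = np.concatenate([s.data for s in sets], axis=0)
    y = np.concatenate([
        np.full(len(s.data), s.class_label.index, dtype=int) for s in sets
    ])
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    X, y = X[order], y[order]
    n_train = int(np.floor(len(X) * cfg.train_frac))
    Xtr, ytr = X[:n_train], one_hot(y[:n_train], model.spec.N)
    Xte, yte = X[n_train:], one_hot(y[n_train:], model.spec.N)
    t0 = time.time()
    hist = nn.fit(model.net, Xtr[:, None], ytr, X_val=Xte[:, None], y_val=yte,
                  epochs=cfg.epochs, batch_size=cfg.batch_size,
                  lr=cfg.learning_rate, patience=cfg.patience, rng=rng)
    test_loss, test_acc = nn.evaluate_loss_acc(model.net, Xte[:, None], yte)
    model.history = hist
    model.pretrain_metrics = {
        "run_time_s": time.time() - t0,
        "test_acc": test_acc, "test_loss": test_loss,
        "val_acc": hist["val_acc"][hist["best_epoch"]],
        "val_loss": hist["val_loss"][hist["best_epoch"]],
        "n_train": int(n_train), "n_test": int(len(X) - n_train),
    }
    return model


def finetune(model: ClassifierModel, init_state, train_ep, val_ep,
             cfg: TrainConfig, reset_bn_stats: bool = True):
    """Early-stopped training on real epochs, optionally warm-started.

    When warm-starting from pretrained weights, batch-norm *running
    statistics* are reset to (0, 1) by default: they describe the synthetic
    pretraining distribution, whose per-feature variances differ strongly
    from noisy real epochs, and carrying them over makes the transferred
    model confidently wrong at the start of fine-tuning.
    """
    if init_state is not None:
        model.net.set_state(init_state)
        if reset_bn_stats:
            for layer in model.net.layers:
                if isinstance(layer, nn.BatchNorm):
                    layer.run_mean = np.zeros_like(layer.run_mean)
                    layer.run_var = np.ones_like(layer.run_var)
    ytr = one_hot(train_ep.labels, model.spec.N)
    yva = one_hot(val_ep.labels, model.spec.N)
    rng = np.random.default_rng(cfg.seed)
    hist = nn.fit(model.net, train_ep.data[:, None], ytr,
                  X_val=val_ep.data[:, None], y_val=yva,
                  epochs=cfg.epochs, batch_size=cfg.batch_size,
                  lr=cfg.learning_rate, patience=cfg.early_stopping_epochs,
                  rng=rng)
    model.history = hist
    return model


@dataclass
class EvalResult:
    accuracy: float
    auc: float
    confusion: np.ndarray       # rows = true classes
    roc_curves: dict            # class index -> (fpr, tpr)
    n_trials: int


def evaluate(model: ClassifierModel, test_ep: EpochSet) -> EvalResult:
    """Accuracy, macro one-vs-rest AUC, per-class ROC and confusion matrix."""
    if test_ep.n_trials == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(test_ep.data)
    y = test_ep.class_indices()
    return scores_report(y, proba, model.spec.N)


def scores_report(y_true, proba, n_classes) -> EvalResult:
    """Metrics from true class indices and predicted class probabilities."""
    y_true = np.asarray(y_true)
    pred = proba.argmax(axis=1)  # ties -> lowest class index
    acc = float(np.mean(pred == y_true))
    aucs, rocs = [], {}
    for c in range(n_classes):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, proba[:, c]))
            fpr, tpr, _ = roc_curve(pos, proba[:, c])
            rocs[c] = (fpr, tpr)
    auc = float(np.mean(aucs)) if aucs else np.nan
    cm = _sk_confusion(y_true, pred, labels=np.arange(n_classes))
    return EvalResult(accuracy=acc, auc=auc, confusion=cm, roc_curves=rocs,
                      n_trials=len(y_true))


@dataclass
class ConfusionSummary:
    cross_view_confusion_mass: float
    within_view_confusion_mass: float
    no_confusion: bool = False


def confusion_view_split(confusion, classes) -> ConfusionSummary:
    """Partition off-diagonal confusion into cross-view vs within-view mass.

    ``classes`` supplies the view attribute per class index.  A matrix with
    no off-diagonal mass is flagged, with both fractions reported as 0.
    """
    cm = np.asarray(confusion, dtype=float)
    views = [c.view for c in classes]
    cross = within = 0.0
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            if i == j:
                continue
            if views[i] != views[j]:
                cross += cm[i, j]
            else:
                within += cm[i, j]
    total = cross + within
    if total == 0:
        return ConfusionSummary(0.0, 0.0, no_confusion=True)
    return ConfusionSummary(cross / total, within / total)


def grand_average(ep: EpochSet, classes=None) -> dict:
    """Per-class mean waveform (channels x time) across trials."""
    labels = np.asarray([l for l in ep.labels])
    wanted = classes if classes is not None else sorted(
        set(ep.labels), key=lambda c: c.index)
    out = {}
    for cls in wanted:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"no trials for class {cls.category!r}")
        out[cls] = ep.data[mask].mean(axis=0)
    return out


def trough_latency(waveform_1d, time_axis, window=(0.1, 0.25)) -> float:
    """Latency (s) of the most negative sample inside a search window."""
    t = np.asarray(time_axis)
    m = (t >= window[0]) & (t <= window[1])
    seg = np.asarray(waveform_1d)[m]
    return float(t[m][seg.argmin()])


@dataclass
class EvalReport:
    """Per-run records and summary of a repeated two-fold evaluation."""

    runs: pd.DataFrame
    confusions: dict            # (repeat, fold, subject_kind) -> matrix
    histories: list
    classes: tuple

    def summary(self) -> pd.DataFrame:
        cols = [c for c in self.runs.columns
                if c.endswith("_acc") or c.endswith("_auc")]
        return self.runs[cols].mean().to_frame("mean").T


def _audit_no_leakage(train_subjects, test_ids):
    leaked = set(train_subjects) & set(test_ids)
    if leaked:
        raise RuntimeError(f"subject leakage into training fold: {leaked}")


def repeated_two_fold(pooled: EpochSet, test_sets: dict, spec: ModelSpec,
                      cfg: TrainConfig, repeats: int = 5, k: int = 2,
                      init_state=None, seed: int = 0) -> EvalReport:
    """Repeat k-fold (default 2-fold, 5 times) over pooled training trials.

    Each repeat draws a fresh stratified partition; each fold in turn trains
    the classifier (optionally warm-started from ``init_state``) and is
    validated on the complementary fold, then evaluated on each held-out
    test subject.  ``test_sets`` maps a subject kind (e.g. ``"control"``,
    ``"alzheimer"``) to its EpochSet; a subject-leakage audit runs on every
    fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = pooled.class_indices()
    trial_subjects = getattr(pooled, "trial_subjects",
                             [pooled.subject_id] * pooled.n_trials)
    test_ids = [ep.subject_id for ep in test_sets.values()]
    rows = []
    confusions = {}
    histories = []
    ss = np.random.SeedSequence(seed)
    for rep, rep_seed in enumerate(ss.spawn(repeats)):
        rs = np.random.default_rng(rep_seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rs.integers(2 ** 31)))
        for fold, (ia, ib) in enumerate(skf.split(pooled.data, y)):
            tr_idx, va_idx = ib, ia  # train on the complement of the fold
            _audit_no_leakage([trial_subjects[i] for i in tr_idx], test_ids)
            _audit_no_leakage([trial_subjects[i] for i in va_idx], test_ids)
            model_seed = int(rs.integers(2 ** 31))
            model = build_model(spec, seed=model_seed)
            train_ep = replace(pooled, data=pooled.data[tr_idx],
                               labels=[pooled.labels[i] for i in tr_idx])
            val_ep = replace(pooled, data=pooled.data[va_idx],
                             labels=[pooled.labels[i] for i in va_idx])
            run_cfg = replace(cfg, seed=int(rs.integers(2 ** 31)))
            finetune(model, init_state, train_ep, val_ep, run_cfg)
            histories.append(model.history)
            row = {"repeat": rep, "fold": fold, "model_seed": model_seed}
            res = evaluate(model, val_ep)
            row["validation_acc"] = res.accuracy
            row["validation_auc"] = res.auc
            confusions[(rep, fold, "validation")] = res.confusion
            for kind, ep in test_sets.items():
                res = evaluate(model, ep)
                row[f"{kind}_acc"] = res.accuracy
                row[f"{kind}_auc"] = res.auc
                confusions[(rep, fold, kind)] = res.confusion
            rows.append(row)
    classes = tuple(sorted(set(pooled.labels), key=lambda c: c.index))
    return EvalReport(runs=pd.DataFrame(rows), confusions=confusions,
                      histories=histories, classes=classes)
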