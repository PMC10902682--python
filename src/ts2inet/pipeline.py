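"""End-to-end orchestration: transform, train, evaluate, compare.

Evaluation reports accuracy, macro recall/F1, a confusion matrix, per-class
accuracies, and micro-averaged ROC and PR curves (one-vs-rest indicator and
score pairs pooled across classes). Cross-validation is stratified k-fold
(k = 10 by default). Run vectors of per-fold accuracies are compared by
first checking normality of each vector with a Kolmogorov–Smirnov test
against a normal with that vector's estimated mean and standard deviation
(accept normality at P > .05), then a two-sided pooled-variance two-sample
t-test (significant difference at P < .05).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .s2i import transform_dataset
from .signal_io import ImageDataset, SignalDataset, split_dataset
from .model import ModelConfig, TrainedModel, build_model, predict, train

__all__ = [
    "EvalReport",
    "RunVector",
    "ComparisonResult",
    "evaluate",
    "cross_validate",
    "compare_runs",
    "strategy_comparison",
    "run_ablation",
    "train_once",
]

ALPHA = 0.05  # decision threshold for both the KS normality and t tests


@dataclass
class EvalReport:
    """Metrics of one evaluation pass."""

    accuracy: float
    recall_macro: float
    f1_macro: float
    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    roc_points: np.ndarray  # (n, 2) of (fpr, tpr), micro-averaged
    pr_points: np.ndarray  # (n, 2) of (recall, precision), micro-averaged

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "roc": self.roc_points.tolist(),
            "pr": self.pr_points.tolist(),
        }


@dataclass
class RunVector:
    """Per-fold (or per-repeat) accuracies of one method."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("run-vector accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class ComparisonResult:
    """KS-normality p-values, t-test p-value and the significance verdict."""

    ks_p_a: float
    ks_p_b: float
    normal_a: bool
    normal_b: bool
    t_stat: float
    t_p: float
    significant: bool
    mean_diff: float


def evaluate(true_labels: np.ndarray, pred_labels: np.ndarray,
             scores: np.ndarray, n_classes: int | None = None) -> EvalReport:
    """Compute the full metric set from labels and probability scores.

    Macro recall/F1 average over classes present in the truth; ROC and PR
    are micro-averaged by flattening the one-vs-rest indicator matrix
    against the score matrix.
    """
    y, p = np.asarray(true_labels, int), np.asarray(pred_labels, int)
    scores = np.asarray(scores, dtype=float)
    if not (len(y) == len(p) == len(scores)):
        raise ValueError("true_labels, pred_labels and scores must have equal length")
    k = n_classes or scores.shape[1]
    labels = np.arange(k)
    acc = float(_skm.accuracy_score(y, p))
    present = np.unique(y)
    rec = float(_skm.recall_score(y, p, labels=present, average="macro", zero_division=0))
    f1 = float(_skm.f1_score(y, p, labels=present, average="macro", zero_division=0))
    conf = _skm.confusion_matrix(y, p, labels=labels)
    row = conf.sum(axis=1)
    per_class = np.divide(np.diag(conf), row, out=np.zeros(k, dtype=float), where=row > 0)
    onehot = np.eye(k)[y].ravel()
    flat = scores.ravel()
    fpr, tpr, _ = _skm.roc_curve(onehot, flat)
    prec, recall, _ = _skm.precision_recall_curve(onehot, flat)
    return EvalReport(
        accuracy=acc,
        recall_macro=rec,
        f1_macro=f1,
        confusion=conf,
        per_class_accuracy=per_class,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, prec]),
    )


def _carve_validation(train_images: ImageDataset, seed: int,
                      frac: float = 0.125) -> tuple[ImageDataset, ImageDataset]:
    """Split an image stack into train/val, stratified, >= 1 per class in val."""
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for c in np.unique(train_images.labels):
        idx = np.flatnonzero(train_images.labels == c)
        take = max(1, int(round(frac * idx.size)))
        val_idx.extend(rng.permutation(idx)[:take])
    val_mask = np.zeros(len(train_images), dtype=bool)
    val_mask[val_idx] = True

    def pick(mask: np.ndarray) -> ImageDataset:
        return ImageDataset(
            images=train_images.images[mask],
            labels=train_images.labels[mask],
            strategy=train_images.strategy,
            image_size=train_images.image_size,
            class_names=train_images.class_names,
        )

    return pick(~val_mask), pick(val_mask)


def train_once(
    train_images: ImageDataset,
    test_images: ImageDataset,
    config: ModelConfig,
) -> tuple[TrainedModel, EvalReport]:
    """Train one model (with an internal stratified validation carve-out)
    and evaluate it on the held-out test images."""
    cfg = replace(config, n_classes=len(train_images.class_names))
    model = build_model(cfg, train_images.image_size, train_images.class_names)
    tr, val = _carve_validation(train_images, seed=cfg.seed)
    model = train(model, tr, val, cfg)
    probs, preds = predict(model, test_images)
    report = evaluate(test_images.labels, preds, probs, n_classes=cfg.n_classes)
    return model, report


def cross_validate(
    ds: SignalDataset,
    strategy: str,
    model_config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    image_size: int = 64,
    **transform_params,
) -> tuple[RunVector, list[EvalReport]]:
    """Stratified k-fold cross-validation of transform -> train -> evaluate."""
    labels = ds.label_indices()
    counts = np.bincount(labels)
    if counts.min() < k:
        small = ds.classes[int(counts.argmin())]
        raise ValueError(f"class {small!r} has fewer than k={k} records")
    images = transform_dataset(ds, strategy, l=image_size, **transform_params)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(ds)), labels)):
        def pick(idx: np.ndarray) -> ImageDataset:
            return ImageDataset(images.images[idx], images.labels[idx],
                                images.strategy, images.image_size, images.class_names)
        cfg = replace(model_config, seed=model_config.seed + fold)
        _, report = train_once(pick(tr_idx), pick(te_idx), cfg)
        reports.append(report)
    vec = RunVector(np.array([r.accuracy for r in reports]), label=strategy)
    return vec, reports


def compare_runs(a: RunVector, b: RunVector) -> ComparisonResult:
    """KS normality check on each run vector, then a pooled-variance
    two-sample t-test between them (both thresholds at .05)."""
    va, vb = a.values, b.values
    if va.size < 2 or vb.size < 2:
        raise ValueError("run vectors must have length >= 2")
    if va.std(ddof=1) == 0 or vb.std(ddof=1) == 0:
        raise ValueError("degenerate run vector: zero variance")
    ks_a = _sps.kstest(va, "norm", args=(va.mean(), va.std(ddof=1))).pvalue
    ks_b = _sps.kstest(vb, "norm", args=(vb.mean(), vb.std(ddof=1))).pvalue
    t = _sps.ttest_ind(va, vb, equal_var=True)
    return ComparisonResult(
        ks_p_a=float(ks_a),
        ks_p_b=float(ks_b),
        normal_a=bool(ks_a > ALPHA),
        normal_b=bool(ks_b > ALPHA),
        t_stat=float(t.statistic),
        t_p=float(t.pvalue),
        significant=bool(t.pvalue < ALPHA),
        mean_diff=float(va.mean() - vb.mean()),
    )


def _shared_split(ds: SignalDataset, seed: int) -> tuple[SignalDataset, SignalDataset]:
    tr, val, te = split_dataset(ds, (0.7, 0.1, 0.2), seed=seed)
    merged = SignalDataset(list(tr.records) + list(val.records))
    merged.classes = list(ds.classes)
    return merged, te


def strategy_comparison(
    ds: SignalDataset,
    strategies: tuple[str, ...] = ("RP", "MTF", "GASF", "GADF"),
    model_config: ModelConfig | None = None,
    seed: int = 0,
    image_size: int = 64,
    **transform_params,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Train the same model on the same split under each transformation
    strategy; only the transform varies, isolating its effect. Returns a
    strategy x (accuracy, recall, f1) table plus the full reports."""
    allowed = {"RP", "MTF", "GASF", "GADF"}
    strategies = tuple(s.upper() for s in strategies)
    if not set(strategies) <= allowed:
        raise ValueError(f"strategies must be a subset of {sorted(allowed)}")
    cfg = model_config or ModelConfig()
    train_sig, test_sig = _shared_split(ds, seed)
    rows, reports = [], {}
    for strat in strategies:
        tr = transform_dataset(train_sig, strat, l=image_size, **transform_params)
        te = transform_dataset(test_sig, strat, l=image_size, **transform_params)
        _, rep = train_once(tr, te, replace(cfg, seed=seed))
        reports[strat] = rep
        rows.append({"strategy": strat, "accuracy": rep.accuracy,
                     "recall": rep.recall_macro, "f1": rep.f1_macro})
    return pd.DataFrame(rows).set_index("strategy"), reports


def run_ablation(
    ds: SignalDataset,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    strategy: str = "GADF",
    image_size: int = 64,
    **transform_params,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Transformer vs the 4-conv CNN on identical data, transform and seed.

    Returns a two-row table (index: 'transformer', 'cnn') of
    accuracy/recall/f1 plus the full reports."""
    cfg = model_config or ModelConfig()
    train_sig, test_sig = _shared_split(ds, seed)
    tr = transform_dataset(train_sig, strategy, l=image_size, **transform_params)
    te = transform_dataset(test_sig, strategy, l=image_size, **transform_params)
    rows, reports = [], {}
    for arch in ("transformer", "cnn"):
        _, rep = train_once(tr, te, replace(cfg, arch=arch, seed=seed))
        reports[arch] = rep
        rows.append({"arch": arch, "transformer_module": arch == "transformer",
                     "accuracy": rep.accuracy, "recall": rep.recall_macro,
                     "f1": rep.f1_macro})
    return pd.DataFrame(rows).set_index("arch"), reports
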