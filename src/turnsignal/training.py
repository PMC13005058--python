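"""Participant-stratified cross-validation, training loop, and metrics.

Evaluation must generalize to unseen drivers, so folds are split at the
participant level: within-class seeded shuffles followed by round-robin
assignment give each test fold a class ratio matching the cohort's, and no
participant ever appears on both sides of a fold.  Training uses decoupled
weight decay (AdamW), cosine-annealed learning rate, weighted cross-entropy,
and mini-batches of 32; metrics are the imbalance-aware set (accuracy,
balanced accuracy, ROC AUC, precision, recall, F1) averaged across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .nn import ModelSpec, Tensor, build_model, cross_entropy, predict_proba
from .tensorize import SeriesTensor


@dataclass(frozen=True)
class TrainConfig:
    """Unified training configuration shared by all experiments."""

    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    class_weights: bool = True
    normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    auc: float | None
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc, "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


@dataclass
class FoldSplit:
    folds: list[tuple[set, set]]  # (train participant set, test participant set)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(participants: list[str], labels: dict[str, str] | list[str],
               k: int = 7, seed: int = 0) -> FoldSplit:
    """Participant-level stratified k-fold assignment.

    Participants are shuffled within class (seeded) and dealt round-robin into
    k folds, so every test fold's class ratio matches the overall ratio within
    rounding and test sets partition the cohort.
    """
    participants = list(participants)
    if isinstance(labels, dict):
        lab = [labels[p] for p in participants]
    else:
        lab = list(labels)
    if len(participants) < k:
        raise ValueError(f"need >= {k} participants for {k} folds")
    classes = sorted(set(lab))
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_sets: list[set] = [set() for _ in range(k)]
    for cls in classes:
        members = [p for p, l in zip(participants, lab) if l == cls]
        rng.shuffle(members)
        for i, p in enumerate(members):
            test_sets[i % k].add(p)
    allp = set(participants)
    folds = [(allp - ts, ts) for ts in test_sets if ts]
    return FoldSplit(folds)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights: w_c = n_total / (2 * n_c)."""
    labels = np.asarray(labels)
    counts = np.array([(labels == c).sum() for c in (0, 1)], dtype=float)
    if (counts == 0).any():
        raise ValueError("both classes must be present in the training set")
    return labels.shape[0] / (2.0 * counts)


@dataclass
class ChannelScaler:
    """Per-channel standard scaling fitted on training data only."""

    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, data: np.ndarray) -> "ChannelScaler":
        self.mean = data.mean(axis=(0, 2))
        std = data.std(axis=(0, 2))
        if (std == 0).any():
            import warnings

            warnings.warn("zero-variance channel; using unit divisor", stacklevel=2)
            std = np.where(std == 0, 1.0, std)
        self.std = std
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (data - self.mean[None, :, None]) / self.std[None, :, None]


def fit_scaler(train_data: np.ndarray) -> ChannelScaler:
    return ChannelScaler().fit(train_data)


def cosine_lr(base_lr: float, epoch: int, t_max: int) -> float:
    """Cosine annealing from base_lr to 0 over t_max epochs."""
    return 0.5 * base_lr * (1.0 + math.cos(math.pi * epoch / t_max))


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_model(spec: ModelSpec, data, labels: np.ndarray,
                config: TrainConfig):
    """Train a classifier; returns (model, per-epoch mean loss history).

    ``data`` is an N x C x L array or a pair of such arrays for dual models.
    Deterministic for a fixed config seed (init, batch order, dropout all flow
    from it).  NaN loss aborts with a diagnostic.
    """
    labels = np.asarray(labels, dtype=np.int64)
    dual = isinstance(data, tuple)
    n = data[0].shape[0] if dual else data.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    model = build_model(spec, seed=config.seed)
    w = class_weights(labels) if config.class_weights else None
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    to32 = lambda a: np.ascontiguousarray(a, dtype=np.float32)  # noqa: E731
    if dual:
        data = (to32(data[0]), to32(data[1]))
    else:
        data = to32(data)
    history: list[float] = []
    model.train()
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(config.lr, epoch, config.epochs)
        losses = []
        for idx in _batches(n, config.batch_size, rng):
            xb = (data[0][idx], data[1][idx]) if dual else data[idx]
            model.zero_grad()
            loss = cross_entropy(model(xb), labels[idx], w)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return model, history


def evaluate(model, data, labels: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Imbalance-aware metrics for a trained classifier on a test set.

    AUC uses the positive-class probability rank statistic and is recorded as
    ``None`` when the test labels contain a single class.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty test set")
    proba = predict_proba(model, data)
    return metrics_from_probabilities(labels, proba[:, 1], threshold)


def metrics_from_probabilities(labels: np.ndarray, p_pos: np.ndarray,
                               threshold: float = 0.5) -> MetricsReport:
    labels = np.asarray(labels, dtype=np.int64)
    pred = (np.asarray(p_pos) >= threshold).astype(np.int64)
    tn, fp, fn, tp = skm.confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    auc = None
    if len(np.unique(labels)) == 2:
        auc = float(skm.roc_auc_score(labels, p_pos))
    return MetricsReport(
        accuracy=float(skm.accuracy_score(labels, pred)),
        balanced_accuracy=float(skm.balanced_accuracy_score(labels, pred)),
        auc=auc,
        precision=float(skm.precision_score(labels, pred, zero_division=0)),
        recall=float(skm.recall_score(labels, pred, zero_division=0)),
        f1=float(skm.f1_score(labels, pred, zero_division=0)),
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
    )


@dataclass
class FoldResult:
    fold: int
    report: MetricsReport
    test_participants: set
    p_pos: np.ndarray  # positive-class probability per test row
    labels: np.ndarray
    participant_ids: np.ndarray
    trip_ids: np.ndarray


def _mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    aucs = [r.auc for r in reports if r.auc is not None]
    mean = lambda vals: float(np.mean(vals)) if vals else float("nan")  # noqa: E731
    return MetricsReport(
        accuracy=mean([r.accuracy for r in reports]),
        balanced_accuracy=mean([r.balanced_accuracy for r in reports]),
        auc=mean(aucs) if aucs else None,
        precision=mean([r.precision for r in reports]),
        recall=mean([r.recall for r in reports]),
        f1=mean([r.f1 for r in reports]),
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports),
    )


def cross_validate(
    spec: ModelSpec,
    tensor: SeriesTensor | tuple[SeriesTensor, SeriesTensor],
    config: TrainConfig,
    folds: FoldSplit,
    threshold: float = 0.5,
) -> tuple[MetricsReport, list[FoldResult]]:
    """Cross-validate a model over participant folds.

    For late-fusion pairs pass ``(trip_tensor, turn_tensor)`` with aligned
    rows.  Per fold: fit the optional scaler on training rows only, train,
    and evaluate on the held-out participants' trips; the averaged report is
    the unweighted mean of per-fold metrics (AUC averaged over folds where it
    is defined).
    """
    pair = isinstance(tensor, tuple)
    primary = tensor[0] if pair else tensor
    results: list[FoldResult] = []
    for i, (train_p, test_p) in enumerate(folds):
        tr = np.flatnonzero(np.isin(primary.participant_ids, list(train_p)))
        te = np.flatnonzero(np.isin(primary.participant_ids, list(test_p)))
        if len(tr) == 0 or len(te) == 0:
            continue
        assert not (set(primary.participant_ids[tr]) & set(primary.participant_ids[te]))
        if pair:
            xs_tr, xs_te = [], []
            for t in tensor:
                xtr, xte = t.data[tr], t.data[te]
                if config.normalize:
                    sc = fit_scaler(xtr)
                    xtr, xte = sc.transform(xtr), sc.transform(xte)
                xs_tr.append(xtr)
                xs_te.append(xte)
            x_train, x_test = tuple(xs_tr), tuple(xs_te)
        else:
            x_train, x_test = tensor.data[tr], tensor.data[te]
            if config.normalize:
                sc = fit_scaler(x_train)
                x_train, x_test = sc.transform(x_train), sc.transform(x_test)
        y_train, y_test = primary.labels[tr], primary.labels[te]
        fold_cfg = replace(config, seed=config.seed + i)
        model, _ = train_model(spec, x_train, y_train, fold_cfg)
        proba = predict_proba(model, x_test)
        report = metrics_from_probabilities(y_test, proba[:, 1], threshold)
        results.append(FoldResult(
            fold=i, report=report, test_participants=set(test_p),
            p_pos=proba[:, 1], labels=y_test,
            participant_ids=primary.participant_ids[te],
            trip_ids=primary.trip_ids[te],
        ))
    if not results:
        raise ValueError("no usable folds")
    return _mean_reports([r.report for r in results]), results


def results_frame(mean_report: MetricsReport, experiment: str, model: str,
                  config: TrainConfig) -> pd.DataFrame:
    """One tidy results row in the standard reporting column set."""
    d = mean_report.as_dict()
    return pd.DataFrame([{
        "experiment": experiment, "model": model,
        "normalize": config.normalize, "class_weights": config.class_weights,
        "accuracy": d["accuracy"], "balanced_accuracy": d["balanced_accuracy"],
        "auc": d["auc"], "precision": d["precision"], "recall": d["recall"],
        "f1": d["f1"],
    }])
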