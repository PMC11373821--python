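"""Training, scoring, evaluation metrics and the cross-validation protocol.

Training minimizes cross-entropy with Adam (default learning rate 0.003,
batch size 1024 auto-reduced to the dataset size) and early-stops on the AUC
of a held-out validation slice of the training data.  Evaluation reports the
confusion-table metrics (TPR, FPR, ACC, Sen, F1, MCC) at a 0.5 threshold
plus the rank-based ROC AUC; any metric with a zero denominator is reported
as 0 and flagged rather than raising, so sweeps over tiny folds survive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from ._autodiff import Tensor
from ._layers import Adam
from .encoders import EmbeddingModel, EncodingConfig, encode_dataset, train_doc2vec
from .network import Model, ModelConfig, assemble_model
from .sequence_io import (
    LabeledDataset, SequenceError, SplitSpec, kfold_indices,
    split_train_test, standardize_length,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.003
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_scores(cls, labels, scores, threshold: float = 0.5) -> "ConfusionCounts":
        labels = np.asarray(labels)
        pred = np.asarray(scores) >= threshold
        return cls(
            tp=int(np.sum(pred & (labels == 1))),
            fp=int(np.sum(pred & (labels == 0))),
            tn=int(np.sum(~pred & (labels == 0))),
            fn=int(np.sum(~pred & (labels == 1))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """AUC plus the confusion-table metrics at a fixed threshold.

    ``undefined`` names the metrics whose denominator was zero (they are
    reported as 0).
    """

    auc: float
    acc: float
    sen: float
    tpr: float
    fpr: float
    f1: float
    mcc: float
    threshold: float
    counts: ConfusionCounts
    undefined: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc, "ACC": self.acc, "Sen": self.sen, "TPR": self.tpr,
            "FPR": self.fpr, "F1": self.f1, "MCC": self.mcc,
            "threshold": self.threshold,
        }


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Threshold the scores and compute the full metric report."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size == 0:
        raise ValueError("labels and scores must be nonempty and equal-length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")

    c = ConfusionCounts.from_scores(labels, scores, threshold)
    undefined = set()

    def safe(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    tpr = safe(c.tp, c.tp + c.fn, "TPR")
    fpr = safe(c.fp, c.fp + c.tn, "FPR")
    acc = safe(c.tp + c.tn, c.total, "ACC")
    sen = safe(c.tp, c.tp + c.fn, "Sen")
    f1 = safe(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = safe(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC")
    if len(np.unique(labels)) < 2:
        undefined.add("AUC")
        auc = 0.0
    else:
        auc = float(roc_auc_score(labels, scores))
    return MetricReport(auc, acc, sen, tpr, fpr, f1, mcc, threshold, c,
                        frozenset(undefined))


def roc_points(labels, scores) -> np.ndarray:
    """(FPR, TPR, threshold) rows of the ROC curve, for export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _encode(ds: LabeledDataset, embedding: EmbeddingModel, length: int) -> np.ndarray:
    cfg = embedding.training_config
    seqs = [standardize_length(s, length) for s in ds.sequences]
    return encode_dataset(seqs, embedding, cfg)


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    from ._layers import log_softmax

    B = len(y)
    onehot = np.zeros((B, logits.shape[1]))
    onehot[np.arange(B), y] = 1.0
    return -(log_softmax(logits) * Tensor(onehot)).sum() * (1.0 / B)


def train(model: Model, train_ds: LabeledDataset, embedding: EmbeddingModel,
          tcfg: TrainConfig) -> dict:
    """Fit the model in place; returns the per-epoch history.

    A stratified ``val_fraction`` slice of the training data is held out for
    early stopping on validation AUC; the best-epoch weights are restored at
    the end.  History keys: ``loss`` (mean batch cross-entropy per epoch) and
    ``val_auc``.
    """
    labels = np.asarray(train_ds.labels)
    if len(np.unique(labels)) < 2:
        raise SequenceError("training set contains a single class")

    fit_ds, val_ds = split_train_test(
        train_ds, SplitSpec(test_fraction=tcfg.val_fraction, seed=tcfg.seed)
    )
    x_fit = _encode(fit_ds, embedding, model.input_length)
    y_fit = np.asarray(fit_ds.labels)
    x_val = _encode(val_ds, embedding, model.input_length)
    y_val = np.asarray(val_ds.labels)

    batch = min(tcfg.batch_size, len(fit_ds))
    rng = np.random.default_rng(tcfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=tcfg.learning_rate)

    history = {"loss": [], "val_auc": []}
    best_auc, best_state, since_best = -np.inf, None, 0
    for epoch in range(tcfg.max_epochs):
        model.set_training(True)
        order = rng.permutation(len(y_fit))
        losses = []
        for lo in range(0, len(order), batch):
            sel = order[lo : lo + batch]
            logits = model.logits(x_fit[sel])
            loss = _cross_entropy(logits, y_fit[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = model.predict_proba(x_val)
        val_auc = (
            float(roc_auc_score(y_val, val_scores))
            if len(np.unique(y_val)) > 1 else float("nan")
        )
        history["loss"].append(float(np.mean(losses)))
        history["val_auc"].append(val_auc)
        logger.info("epoch %d: loss %.4f, val AUC %.4f",
                    epoch + 1, history["loss"][-1], val_auc)
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc = val_auc
            best_state = [p.data.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break
    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
    model.set_training(False)
    return history


def predict(model: Model, ds: LabeledDataset, embedding: EmbeddingModel,
            batch_size: int = 256) -> np.ndarray:
    """Positive-class probability per sequence, order preserved."""
    if len(ds) == 0:
        return np.empty(0)
    x = _encode(ds, embedding, model.input_length)
    return np.concatenate([
        model.predict_proba(x[lo : lo + batch_size])
        for lo in range(0, len(x), batch_size)
    ])


def evaluate(model: Model, ds: LabeledDataset, embedding: EmbeddingModel,
             threshold: float = 0.5) -> MetricReport:
    return compute_metrics(ds.labels, predict(model, ds, embedding), threshold)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    mean: dict
    std: dict


def cross_validate(ds: LabeledDataset, mcfg: ModelConfig, tcfg: TrainConfig,
                   spec: SplitSpec, encoding: EncodingConfig,
                   input_length: int = 101) -> CVResult:
    """K-fold cross-validation with a fresh model and embedding per fold.

    The embedding is retrained on each fold's training portion only, so no
    token statistics leak from the validation fold.
    """
    if len(ds) < spec.n_folds * 2:
        raise SequenceError(
            f"need at least {spec.n_folds * 2} samples for {spec.n_folds} folds"
        )
    reports = []
    for fold, (tr, va) in enumerate(kfold_indices(len(ds), spec)):
        try:
            tr_ds, va_ds = ds.subset(tr), ds.subset(va)
            from dataclasses import replace

            emb = train_doc2vec(
                tr_ds.sequences, replace(encoding, seed=encoding.seed + fold)
            )
            model = assemble_model(mcfg, encoding, input_length,
                                   seed=tcfg.seed + fold)
            train(model, tr_ds, emb, tcfg)
            scores = predict(model, va_ds, emb)
            rep = compute_metrics(va_ds.labels, scores)
            if "AUC" in rep.undefined:
                logger.warning("fold %d: single-class validation fold, AUC undefined",
                               fold)
            reports.append(rep)
        except SequenceError as e:
            raise SequenceError(f"fold {fold}: {e}") from e
    keys = ("AUC", "ACC", "Sen", "TPR", "FPR", "F1", "MCC")
    table = {k: np.array([r.as_dict()[k] for r in reports]) for k in keys}
    return CVResult(
        fold_reports=reports,
        mean={k: float(v.mean()) for k, v in table.items()},
        std={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in table.items()},
    )


def generalizability_split(datasets: list[LabeledDataset], train_names: list[str],
                           test_names: list[str]) -> tuple[LabeledDataset, LabeledDataset]:
    """Pool named datasets into one training and one held-out testing set."""
    if not train_names or not test_names:
        raise ValueError("both name lists must be nonempty")
    overlap = set(train_names) & set(test_names)
    if overlap:
        raise ValueError(f"names in both groups: {sorted(overlap)}")
    by_name = {d.name: d for d in datasets}
    unknown = (set(train_names) | set(test_names)) - set(by_name)
    if unknown:
        raise ValueError(f"unknown dataset names: {sorted(unknown)}")

    def pool(names, tag):
        seqs, labels = [], []
        for n in names:
            seqs.extend(by_name[n].sequences)
            labels.extend(by_name[n].labels)
        return LabeledDataset(seqs, labels, name=tag)

    return pool(train_names, "train_pool"), pool(test_names, "test_pool")
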