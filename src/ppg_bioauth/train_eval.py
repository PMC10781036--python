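"""Training loop, loss, metric suite, and cross-validation protocols.

Evaluation follows the one-vs-rest convention: per-class TP/FP/TN/FN
counts give sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision,
recall, F1 (harmonic mean of precision and recall) and per-class
accuracy, macro-averaged over classes; ROC AUC is computed one-vs-rest
per class from the softmax scores and macro-averaged.

Splits are stratified by class and grouped by recording, so segments cut
from the same record never appear on both sides of a split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from . import nn
from .nn import Tensor
from .nn.autograd import log_softmax, softmax
from .model import HybridModel, ModelConfig, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "LabeledBatch", "Dataset", "EvalReport",
    "cross_entropy_loss", "train", "evaluate", "confusion_counts", "metrics",
    "roc_auc", "kfold_cv", "cross_dataset_validation",
    "split_train_val_test", "fit", "identification_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"          # "adam" | "sgdm"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 10
    early_stop_patience: int = 5
    loss: str = "cross_entropy"      # "cross_entropy" | "mse"
    k_folds: int = 5
    inner_val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.inner_val_fraction < 1):
            raise ValueError("inner_val_fraction must be in (0, 1)")
        if self.optimizer not in ("adam", "sgdm"):
            raise ValueError(f"unknown optimizer '{self.optimizer}'")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError(f"unknown loss '{self.loss}'")


@dataclass
class LabeledBatch:
    """Images with one-hot labels."""

    images: np.ndarray               # (m, side, side)
    y_true: np.ndarray               # (m, n_classes), one-hot rows

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.y_true = np.asarray(self.y_true)
        if self.y_true.ndim != 2 or self.images.shape[0] != self.y_true.shape[0]:
            raise ValueError("images and y_true must share the leading dimension")
        rows = self.y_true.sum(axis=1)
        if not (np.all(rows == 1) and np.isin(self.y_true, (0, 1)).all()):
            raise ValueError("y_true rows must be one-hot")


@dataclass
class Dataset:
    """Scalogram images with integer labels and record-level groups."""

    images: np.ndarray               # (n, side, side)
    labels: np.ndarray               # (n,) integer class labels
    groups: np.ndarray | None = None # (n,) record ids for leakage-free splits

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.groups is None:
            self.groups = np.arange(self.labels.size)
        self.groups = np.asarray(self.groups)

    def __len__(self):
        return self.labels.size

    def subset(self, idx) -> "Dataset":
        return Dataset(self.images[idx], self.labels[idx], self.groups[idx])

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def one_hot(self, n_classes: int | None = None) -> np.ndarray:
        k = self.n_classes if n_classes is None else n_classes
        oh = np.zeros((len(self), k), dtype=np.float32)
        oh[np.arange(len(self)), self.labels.astype(int)] = 1.0
        return oh


@dataclass
class EvalReport:
    """Per-class confusion counts and derived one-vs-rest metrics."""

    confusion: np.ndarray            # (n_classes, 4): TP, FP, TN, FN
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: np.ndarray             # per-class (TP+TN)/m
    macro: dict = field(default_factory=dict)
    overall_accuracy: float = 0.0
    auc: float | None = None
    loss: float | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "per_class": {
                k: getattr(self, k).tolist()
                for k in ("sensitivity", "specificity", "precision", "recall",
                          "f1", "accuracy")
            },
            "macro": {k: float(v) for k, v in self.macro.items()},
            "overall_accuracy": float(self.overall_accuracy),
        }
        if self.auc is not None:
            d["auc"] = float(self.auc)
        if self.loss is not None:
            d["loss"] = float(self.loss)
        return d


# -- loss ------------------------------------------------------------------

def cross_entropy_loss(batch: LabeledBatch, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy, averaged over the batch.

    ``y_pred`` rows must be probability vectors (sum to 1 within 1e-6);
    probabilities are clipped to [1e-12, 1] before the log.
    """
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_pred.shape != batch.y_true.shape:
        raise ValueError(f"shape mismatch {y_pred.shape} vs {batch.y_true.shape}")
    if not np.allclose(y_pred.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("y_pred rows must sum to 1")
    logp = np.log(np.clip(y_pred, 1e-12, 1.0))
    return float(-(batch.y_true * logp).sum(axis=1).mean())


# -- training --------------------------------------------------------------

def _batch_loss(model: HybridModel, xb: np.ndarray, yb: np.ndarray, loss: str):
    logits = model.logits(Tensor(xb))
    y = Tensor(yb)
    m = xb.shape[0]
    if loss == "cross_entropy":
        return -(y * log_softmax(logits, axis=-1)).sum() * (1.0 / m)
    probs = softmax(logits, axis=-1)
    return ((probs - y) ** 2).sum() * (1.0 / (m * yb.shape[1]))


def _eval_loss(model: HybridModel, ds: Dataset, n_classes: int, loss: str) -> float:
    probs = model.predict_proba(ds.images)
    y = ds.one_hot(n_classes)
    if loss == "mse":
        return float(((probs - y) ** 2).mean())
    return cross_entropy_loss(LabeledBatch(ds.images, y), probs)


def train(model: HybridModel, train_set: Dataset, val_set: Dataset | None,
          cfg: TrainConfig) -> dict:
    """Minibatch-train the model in place; returns the epoch history.

    Validation loss is recorded after every epoch; training stops at
    ``max_epochs`` or once the validation loss has not improved for
    ``early_stop_patience`` epochs, and the best-validation parameters
    are restored.  Fully deterministic in ``cfg.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    n_classes = model.cfg.n_classes
    x = train_set.images[:, None].astype(np.float32)
    y = train_set.one_hot(n_classes)
    params = model.parameters()
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.SGDM(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF17]))
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, best_epoch = np.inf, model.state_vector(), -1
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = _batch_loss(model, x[idx], y[idx], cfg.loss)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        model.eval()
        if val_set is not None and len(val_set):
            vloss = _eval_loss(model, val_set, n_classes, cfg.loss)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        logger.info("epoch %d train_loss=%.4f val_loss=%.4f", epoch,
                    history["train_loss"][-1], vloss)
        if vloss < best_val - 1e-12:
            best_val, best_state, best_epoch = vloss, model.state_vector(), epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    model.load_state_vector(best_state)
    model.eval()
    history["best_epoch"] = best_epoch
    return history


# -- metrics ---------------------------------------------------------------

def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """Per-class one-vs-rest counts, rows = (TP, FP, TN, FN)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    m = y_true.size
    out = np.zeros((n_classes, 4), dtype=int)
    for c in range(n_classes):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        out[c] = (tp, fp, m - tp - fn - fp, fn)
    return out


def _safe_div(num, den, what: str):
    num, den = np.asarray(num, float), np.asarray(den, float)
    bad = den == 0
    if np.any(bad):
        logger.warning("zero denominator in %s for %d class(es); reporting 0",
                       what, int(bad.sum()))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~bad)
    return out


def metrics(confusion: np.ndarray) -> EvalReport:
    """Derive the one-vs-rest metric suite from per-class counts."""
    confusion = np.asarray(confusion)
    tp, fp, tn, fn = confusion.T.astype(float)
    m = confusion[0].sum()
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    prec = _safe_div(tp, tp + fp, "precision")
    rec = sens
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1")
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
    macro = {
        "sensitivity": sens.mean(), "specificity": spec.mean(),
        "precision": prec.mean(), "recall": rec.mean(), "f1": f1.mean(),
        "accuracy": acc.mean(),
    }
    return EvalReport(confusion=confusion, sensitivity=sens, specificity=spec,
                      precision=prec, recall=rec, f1=f1, accuracy=acc,
                      macro=macro, overall_accuracy=float(tp.sum() / m))


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Macro one-vs-rest ROC AUC (trapezoidal, ties averaged)."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true).astype(int)
    aucs = []
    for c in range(scores.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), scores[:, c]))
    return float(np.mean(aucs)) if aucs else 0.5


def evaluate(model: HybridModel, test_set: Dataset,
             loss: str = "cross_entropy") -> EvalReport:
    """Predict on the test set and assemble the full report."""
    n_classes = model.cfg.n_classes
    probs = model.predict_proba(test_set.images)
    y_pred = probs.argmax(axis=1)
    report = metrics(confusion_counts(test_set.labels, y_pred, n_classes))
    report.auc = roc_auc(probs, test_set.labels)
    report.loss = _eval_loss(model, test_set, n_classes, loss)
    return report


# -- protocols -------------------------------------------------------------

def _grouped_split(ds: Dataset, fraction: float, seed: int):
    """One stratified, group-aware split: (rest_idx, held_out_idx)."""
    n_splits = max(2, int(round(1.0 / fraction)))
    splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                    random_state=seed % (2**31))
    rest, held = next(splitter.split(ds.images, ds.labels, ds.groups))
    return rest, held


def split_train_val_test(ds: Dataset, seed: int, test_fraction: float = 0.2,
                         val_fraction: float = 0.2):
    """Record-grouped stratified train/val/test split."""
    rest_idx, test_idx = _grouped_split(ds, test_fraction, seed)
    rest = ds.subset(rest_idx)
    tr_idx, val_idx = _grouped_split(rest, val_fraction, seed + 1)
    return rest.subset(tr_idx), rest.subset(val_idx), ds.subset(test_idx)


def fit(ds_train: Dataset, ds_val: Dataset | None, model_cfg: ModelConfig,
        train_cfg: TrainConfig) -> tuple[HybridModel, dict]:
    model = build_model(model_cfg)
    history = train(model, ds_train, ds_val, train_cfg)
    return model, history


def kfold_cv(ds: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig) -> dict:
    """Stratified, record-grouped k-fold cross-validation.

    Each cycle holds one fold out as test; the remainder is split again
    into train and validation (``inner_val_fraction``) for early stopping.
    """
    k = train_cfg.k_folds
    counts = np.bincount(ds.labels.astype(int))
    if counts.min() < k:
        raise ValueError(
            f"stratification impossible: a class has {counts.min()} < k={k} samples"
        )
    outer = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                 random_state=train_cfg.seed % (2**31))
    reports, histories = [], []
    for fold, (rest_idx, test_idx) in enumerate(
        outer.split(ds.images, ds.labels, ds.groups)
    ):
        rest, test = ds.subset(rest_idx), ds.subset(test_idx)
        tr_idx, val_idx = _grouped_split(rest, train_cfg.inner_val_fraction,
                                         train_cfg.seed + fold)
        model, hist = fit(rest.subset(tr_idx), rest.subset(val_idx),
                          model_cfg, train_cfg)
        reports.append(evaluate(model, test, train_cfg.loss))
        histories.append(hist)
    accs = np.array([r.overall_accuracy for r in reports])
    aucs = np.array([r.auc for r in reports])
    return {
        "fold_reports": reports,
        "histories": histories,
        "mean_accuracy": float(accs.mean()), "sd_accuracy": float(accs.std()),
        "mean_auc": float(aucs.mean()), "sd_auc": float(aucs.std()),
    }


def cross_dataset_validation(datasets_by_source: dict[str, Dataset],
                             model_cfg: ModelConfig,
                             train_cfg: TrainConfig) -> dict:
    """Rotate sources: train on each one, test on every other.

    Returns a mapping ``(train_source, test_source) -> EvalReport`` for the
    off-diagonal cells and ``(s, s) -> k-fold summary`` on the diagonal.
    All sources must share the same identity label set (identification
    mode evaluates the same softmax classes across sources).
    """
    sources = list(datasets_by_source)
    label_sets = {s: set(np.unique(d.labels)) for s, d in datasets_by_source.items()}
    ref = label_sets[sources[0]]
    for s, ls in label_sets.items():
        if ls != ref:
            raise ValueError(
                f"label mismatch between sources '{sources[0]}' and '{s}': "
                "cross-source identification needs a shared identity set"
            )
    results = {}
    for s in sources:
        ds = datasets_by_source[s]
        results[(s, s)] = kfold_cv(ds, model_cfg, train_cfg)
        tr_idx, val_idx = _grouped_split(ds, train_cfg.inner_val_fraction,
                                         train_cfg.seed)
        model, _ = fit(ds.subset(tr_idx), ds.subset(val_idx), model_cfg, train_cfg)
        for t in sources:
            if t != s:
                results[(s, t)] = evaluate(model, datasets_by_source[t],
                                           train_cfg.loss)
    return results


def identification_experiment(ds: Dataset, model_cfg: ModelConfig,
                              train_cfg: TrainConfig, seed: int,
                              permute_labels: bool = False) -> dict:
    """One train/test cycle on a labeled cohort; the unit of the scaled-down
    identification experiment.

    With ``permute_labels`` the training and validation labels are shuffled
    (test labels kept), which destroys the signal and bounds chance
    performance.
    """
    from dataclasses import replace as _replace

    model_cfg = _replace(model_cfg, seed=seed)
    train_cfg = _replace(train_cfg, seed=seed)
    tr, val, test = split_train_val_test(ds, seed)
    if permute_labels:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBAD]))
        tr = Dataset(tr.images, rng.permutation(tr.labels), tr.groups)
        val = Dataset(val.images, rng.permutation(val.labels), val.groups)
    model, history = fit(tr, val, model_cfg, train_cfg)
    report = evaluate(model, test, train_cfg.loss)
    return {"model": model, "history": history, "report": report,
            "accuracy": report.overall_accuracy, "auc": report.auc}
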