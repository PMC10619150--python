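"""Training loop and the multiclass evaluation stack.

Evaluation follows the standard one-vs-rest decomposition of a KxK confusion
matrix (rows = true class, columns = predicted class):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = trace / total

ROC curves are built per class from softmax scores by sweeping the decision
threshold over the distinct score values (ties grouped), and AUC is the
trapezoidal area under the resulting (FPR, TPR) polyline — equal to the
normalized Mann-Whitney U statistic.

Conventions: a 0/0 precision/recall/F1 (no predicted or no true positives) is
reported as 0.0 with a warning and excluded from macro averages; headline
averages are support-weighted, with macro averages reported alongside;
multiclass AUC is the unweighted mean of the per-class one-vs-rest AUCs.
"""
from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .models import MobileNetClassifier, load_checkpoint
from .nn import Adam, SGD, Tensor, cross_entropy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"           # adam | sgd (momentum 0.9)
    schedule: str = "none"            # none | cosine
    weight_decay: float = 0.0
    seed: int = 0
    pretrained: str | None = None     # checkpoint path for transfer learning
    freeze_backbone_epochs: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("none", "cosine"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def _make_optimizer(cfg: TrainConfig, params):
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    return SGD(params, lr=cfg.learning_rate, momentum=0.9,
               weight_decay=cfg.weight_decay)


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.schedule == "cosine":
        return cfg.learning_rate * 0.5 * (
            1.0 + float(np.cos(np.pi * epoch / max(cfg.epochs - 1, 1))))
    return cfg.learning_rate


def train(model: MobileNetClassifier,
          X_train: np.ndarray, y_train: np.ndarray,
          X_test: np.ndarray | None = None, y_test: np.ndarray | None = None,
          cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Cross-entropy training; returns the per-epoch history frame.

    Inputs are preprocessed float32 arrays (N, 3, H, W) with integer labels.
    With ``cfg.pretrained`` set, every stored tensor whose name and shape
    match is loaded (others are skipped with a logged summary) and the loaded
    tensors are optionally frozen for ``freeze_backbone_epochs`` epochs while
    the fresh modules (front end, attention, classifier) train.
    """
    cfg = cfg or TrainConfig()
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)

    frozen: set[int] = set()
    if cfg.pretrained is not None:
        _, summary = load_checkpoint(cfg.pretrained, model=model, strict=False)
        logger.info("transfer init: %d tensors loaded, %d skipped",
                    len(summary["loaded"]), len(summary["skipped"]))
        if cfg.freeze_backbone_epochs > 0:
            loaded = set(summary["loaded"])
            for name, p in model.named_parameters():
                if name in loaded:
                    p.requires_grad = False
                    frozen.add(id(p))

    def trainable():
        return [p for p in model.parameters() if p.requires_grad]

    opt = _make_optimizer(cfg, trainable())
    history = []
    n = len(X_train)
    for epoch in range(cfg.epochs):
        if frozen and epoch == cfg.freeze_backbone_epochs:
            for p in model.parameters():
                p.requires_grad = True
            frozen.clear()
            opt = _make_optimizer(cfg, trainable())
        opt.lr = _epoch_lr(cfg, epoch)
        model.train()
        t0 = time.time()
        perm = rng.permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += loss.data.item() * len(idx)
            tot_correct += int((logits.data.argmax(axis=1) == yb).sum())
        row = {"epoch": epoch, "train_loss": tot_loss / n,
               "train_acc": tot_correct / n, "lr": opt.lr,
               "seconds": time.time() - t0}
        if X_test is not None and len(X_test):
            te_loss, te_acc = _eval_loss_acc(model, X_test, y_test,
                                             batch_size=max(cfg.batch_size, 64))
            row.update(test_loss=te_loss, test_acc=te_acc)
        history.append(row)
        logger.info("epoch %d: %s", epoch,
                    " ".join(f"{k}={v:.4f}" for k, v in row.items()
                             if k != "epoch"))
    return pd.DataFrame(history)


def _eval_loss_acc(model, X, y, batch_size=64):
    model.eval()
    tot_loss, correct = 0.0, 0
    with nn.no_grad():
        for lo in range(0, len(X), batch_size):
            xb, yb = X[lo:lo + batch_size], y[lo:lo + batch_size]
            logits = model(Tensor(xb))
            tot_loss += cross_entropy(logits, yb).data.item() * len(xb)
            correct += int((logits.data.argmax(axis=1) == yb).sum())
    return tot_loss / len(X), correct / len(X)


def run_synthetic_benchmark(seed: int = 1, *, epochs: int = 15,
                            n_per_class: int = 200, image_size: int = 96,
                            attention: str = "fsca", with_frontend: bool = True,
                            batch_size: int = 32):
    """Desk-scale end-to-end run: generate the synthetic nine-class dataset,
    split it 4:1, train the compact multi-scale FSCA classifier and evaluate.

    Returns ``(report, history)``.  Fully deterministic in ``seed``: the
    generator, the split shuffle, the weight initialization and the batch
    order all derive from it.
    """
    from .datasets import (SyntheticSpec, generate_synthetic_arrays,
                           preprocess_images, stratified_split)
    from .models import build_compact_mfs

    spec = SyntheticSpec(image_size=image_size, n_per_class=n_per_class,
                         seed=seed)
    images, labels, _ = generate_synthetic_arrays(spec)
    rng = np.random.default_rng(seed + 1)
    train_mask = np.zeros(len(labels), dtype=bool)
    for ci in range(len(spec.classes)):
        idx = np.nonzero(labels == ci)[0]
        (n_train, _), = stratified_split([len(idx)])
        train_mask[rng.permutation(idx)[:n_train]] = True
    X = preprocess_images(images)
    model = build_compact_mfs(len(spec.classes), attention=attention,
                              with_frontend=with_frontend, seed=seed)
    cfg = TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    history = train(model, X[train_mask], labels[train_mask],
                    X[~train_mask], labels[~train_mask], cfg)
    report = evaluate(model, X[~train_mask], labels[~train_mask],
                      classes=spec.classes, history=history)
    return report, history


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """KxK integer counts; rows = true class, columns = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def one_vs_rest_counts(cm: np.ndarray, k: int) -> dict[str, int]:
    """TP/FP/FN/TN of class ``k`` pooled from the confusion matrix."""
    tp = int(cm[k, k])
    fp = int(cm[:, k].sum() - tp)
    fn = int(cm[k, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 0.0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(cm: np.ndarray) -> pd.DataFrame:
    """Per-class one-vs-rest precision, recall and F1 with supports."""
    rows = []
    for k in range(cm.shape[0]):
        c = one_vs_rest_counts(cm, k)
        support = c["tp"] + c["fn"]
        defined = support > 0 or (c["tp"] + c["fp"]) > 0
        prec = _safe_div(c["tp"], c["tp"] + c["fp"], f"precision[{k}]") \
            if defined else np.nan
        rec = _safe_div(c["tp"], c["tp"] + c["fn"], f"recall[{k}]") \
            if support > 0 else np.nan
        if np.isnan(prec) or np.isnan(rec):
            f1 = np.nan
        elif prec + rec == 0:
            f1 = 0.0
        else:
            f1 = 2 * prec * rec / (prec + rec)
        rows.append({"class": k, "precision": prec, "recall": rec, "f1": f1,
                     "support": support})
    return pd.DataFrame(rows)


def roc_curve(scores: np.ndarray, labels: np.ndarray
              ) -> list[tuple[float, float]]:
    """One-vs-rest ROC polyline from (0,0) to (1,1), ties grouped.

    ``labels`` are binary (1 = positive); requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # group tied scores: cumulate at the last index of each tie block
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(l)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc_trapezoid(curve: list[tuple[float, float]]) -> float:
    pts = np.asarray(curve, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    return auc_trapezoid(roc_curve(scores, labels))


@dataclass
class MetricsReport:
    """Full evaluation summary for one model on one labeled set."""
    classes: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    per_class: pd.DataFrame            # precision/recall/f1/support/auc
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    macro_auc: float
    micro_precision: float
    micro_recall: float
    roc_curves: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    history: pd.DataFrame | None = None

    def to_json(self) -> str:
        d = {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class.where(
                self.per_class.notna(), None).to_dict(orient="records"),
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1,
                      "auc": self.macro_auc},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall,
                         "f1": self.weighted_f1},
            "micro": {"precision": self.micro_precision,
                      "recall": self.micro_recall},
        }
        return json.dumps(d, indent=2)

    def save(self, out_dir, prefix: str = "metrics") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{prefix}.json").write_text(self.to_json())
        pd.DataFrame(self.confusion, index=list(self.classes),
                     columns=list(self.classes)) \
            .to_csv(out_dir / f"{prefix}_confusion.csv")
        if self.history is not None:
            self.history.to_csv(out_dir / f"{prefix}_history.csv", index=False)
        for cls, curve in self.roc_curves.items():
            pd.DataFrame(curve, columns=["fpr", "tpr"]).to_csv(
                out_dir / f"{prefix}_roc_{cls.replace(' ', '_')}.csv",
                index=False)


def metrics_from_confusion(cm: np.ndarray,
                           classes: tuple[str, ...] | None = None
                           ) -> MetricsReport:
    """All threshold-free metrics from a confusion matrix alone."""
    k = cm.shape[0]
    classes = classes or tuple(str(i) for i in range(k))
    total = int(cm.sum())
    accuracy = float(np.trace(cm)) / total if total else 0.0
    pc = precision_recall_f1(cm)
    defined = pc.dropna(subset=["precision", "recall", "f1"])
    if len(defined) < k:
        warnings.warn("classes absent from the test set are excluded from "
                      "macro averages", RuntimeWarning, stacklevel=2)
    macro = defined[["precision", "recall", "f1"]].mean()
    support = pc["support"].to_numpy(dtype=float)
    w = support / support.sum() if support.sum() else support
    weighted = {
        col: float(np.nansum(pc[col].to_numpy(dtype=float) * w))
        for col in ("precision", "recall", "f1")}
    # micro pooling: every off-diagonal entry is one FP and one FN
    tp_sum = float(np.trace(cm))
    micro = tp_sum / total if total else 0.0
    return MetricsReport(
        classes=classes, confusion=cm, accuracy=accuracy, per_class=pc,
        macro_precision=float(macro["precision"]),
        macro_recall=float(macro["recall"]), macro_f1=float(macro["f1"]),
        weighted_precision=weighted["precision"],
        weighted_recall=weighted["recall"], weighted_f1=weighted["f1"],
        macro_auc=float("nan"), micro_precision=micro, micro_recall=micro)


def evaluate(model: MobileNetClassifier, X_test: np.ndarray,
             y_test: np.ndarray, classes: tuple[str, ...] | None = None,
             history: pd.DataFrame | None = None) -> MetricsReport:
    """Predict, build the confusion matrix and all derived metrics plus
    per-class one-vs-rest ROC/AUC from softmax scores."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    k = model.spec.num_classes
    classes = classes or tuple(str(i) for i in range(k))
    probs = model.predict_proba(X_test)
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(y_test, preds, k)
    report = metrics_from_confusion(cm, classes)
    aucs, curves = [], {}
    auc_col = np.full(k, np.nan)
    for ci in range(k):
        binary = (y_test == ci).astype(int)
        if binary.sum() == 0 or binary.sum() == len(binary):
            warnings.warn(f"class {classes[ci]!r} absent from the test set; "
                          "AUC undefined", RuntimeWarning, stacklevel=2)
            continue
        curve = roc_curve(probs[:, ci], binary)
        curves[classes[ci]] = curve
        auc_col[ci] = auc_trapezoid(curve)
        aucs.append(auc_col[ci])
    report.per_class["auc"] = auc_col
    report.macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    report.roc_curves = curves
    report.history = history
    return report
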