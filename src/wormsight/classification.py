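"""WormNet: shallow CNN classification of lifespan and movement classes.

WormNet stacks five (conv3x3 - batch norm - ReLU - 2x2 max pool - spatial
dropout) blocks and a two-way softmax head, trained with binary
cross-entropy under Adam (starting learning rate 0.005, beta1 0.9,
beta2 0.999, epsilon 1e-8, decay 0).  Two heads are available:

* ``flatten_fc`` — flatten + fully-connected ReLU layer + softmax, the
  classification workhorse;
* ``gap_cam`` — global average pooling over the final conv maps + a single
  dense softmax layer, the head whose class weights make class activation
  maps computable for the interpretation stage.

Training draws an independently augmented stream (flips, sub-10% shifts,
+/-90 degree rotations, nearest-value fill) each epoch when an
:class:`~wormsight.dataio.AugmentationConfig` is supplied.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion

from .dataio import AugmentationConfig, SplitAssignment, augment_stream
from .nn import Adam, WormNetModel
from .nn.losses import cross_entropy

__all__ = [
    "ClfMetrics",
    "WormNetClassifier",
    "evaluate_classifier",
    "roc_auc_rank",
    "train_classifier",
]


@dataclasses.dataclass
class ClfMetrics:
    """Accuracy / precision / recall at the argmax decision, rank-statistic
    ROC AUC of the positive-class score, and the 2x2 confusion matrix
    (rows = true class, columns = predicted, in ``classes`` order)."""

    accuracy: float
    precision: float
    recall: float
    roc_auc: float | None
    confusion_matrix: np.ndarray
    classes: tuple

    def as_dict(self):
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "roc_auc": self.roc_auc,
            "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
            "classes": list(self.classes),
        }


def roc_auc_rank(scores, y_true_binary):
    """ROC AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true_binary).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC AUC needs both classes in the evaluation set")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


class WormNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary image classifier following the scikit-learn protocol.

    Parameters mirror the architecture: ``filters`` per block (5 blocks),
    ``dropout`` rate of the spatial dropout, ``fc_width`` of the hidden
    fully-connected layer (``flatten_fc`` head only), and ``head_mode``
    selecting between the flatten head and the CAM-capable GAP head.
    ``augmentation`` is an :class:`AugmentationConfig` (each epoch then sees
    ``fold x n`` freshly transformed samples) or None for no augmentation.
    ``early_stopping_patience`` halts training when the monitored loss
    (validation when given, else training) stops improving and restores the
    best weights.
    """

    def __init__(self, input_size=96, filters=(16, 32, 64, 128, 256),
                 dropout=0.25, fc_width=64, head_mode="flatten_fc",
                 lr=0.005, beta1=0.9, beta2=0.999, epsilon=1e-8, decay=0.0,
                 epochs=30, batch_size=16, augmentation=None,
                 early_stopping_patience=None, seed=0):
        self.input_size = input_size
        self.filters = filters
        self.dropout = dropout
        self.fc_width = fc_width
        self.head_mode = head_mode
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.decay = decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.augmentation = augmentation
        self.early_stopping_patience = early_stopping_patience
        self.seed = seed

    def _build(self):
        return WormNetModel(
            input_size=self.input_size, filters=tuple(self.filters),
            dropout=self.dropout, fc_width=self.fc_width,
            head_mode=self.head_mode, seed=self.seed)

    def _encode(self, y):
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        if not np.array_equal(np.asarray(self.classes_)[idx], y):
            raise ValueError("labels outside the fitted classes")
        return idx

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.input_size:
            raise ValueError(
                f"expected images (n, {self.input_size}, {self.input_size}), "
                f"got {X.shape}")
        classes = np.unique(np.asarray(y))
        if classes.size != 2:
            raise ValueError(
                f"need exactly 2 classes in the training set, got {classes!r}")
        self.classes_ = classes
        y_idx = self._encode(y)
        eye = np.eye(2, dtype=np.float32)
        self.model_ = self._build()
        opt = Adam(self.model_.params_and_grads(), lr=self.lr,
                   beta1=self.beta1, beta2=self.beta2, eps=self.epsilon,
                   decay=self.decay)
        rng = np.random.default_rng(self.seed)
        best = (np.inf, None, -1)
        patience_left = self.early_stopping_patience
        history = []
        for epoch in range(self.epochs):
            if self.augmentation is not None:
                pairs = list(augment_stream(X, y_idx, self.augmentation, rng=rng))
                Xe = np.stack([p for p, _ in pairs])
                ye = np.array([t for _, t in pairs])
            else:
                Xe, ye = X, y_idx
            order = rng.permutation(len(Xe))
            losses, hits, total = [], 0, 0
            for start in range(0, len(Xe), self.batch_size):
                idx = order[start : start + self.batch_size]
                prob = self.model_.forward(Xe[idx][..., None], train=True)
                loss, dprob = cross_entropy(prob, eye[ye[idx]])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                self.model_.backward(dprob)
                opt.step()
                losses.append(loss)
                hits += int((prob.argmax(axis=1) == ye[idx]).sum())
                total += len(idx)
            row = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "accuracy": hits / total}
            monitored = row["loss"]
            if validation_data is not None:
                Xv, yv = validation_data
                pv = self._proba(np.asarray(Xv, dtype=np.float32))
                yvi = self._encode(yv)
                row["val_loss"], _ = cross_entropy(pv, eye[yvi])
                row["val_accuracy"] = float((pv.argmax(axis=1) == yvi).mean())
                monitored = row["val_loss"]
            history.append(row)
            if self.early_stopping_patience is not None:
                if monitored < best[0] - 1e-6:
                    best = (monitored,
                            copy.deepcopy(self.model_.state_dict()), epoch)
                    patience_left = self.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if self.early_stopping_patience is not None and best[1] is not None:
            self.model_.load_state_dict(best[1])
            self.best_epoch_ = best[2]
        self.history_ = history
        self.n_iter_ = len(history)
        return self

    def _proba(self, X, batch=32):
        out = [self.model_.forward(X[i : i + batch][..., None], train=False)
               for i in range(0, len(X), batch)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, X):
        """(n, 2) class probabilities in ``classes_`` order."""
        X = np.asarray(X, dtype=np.float32)
        return self._proba(X)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())


def train_classifier(model: WormNetClassifier, images, labels,
                     split: SplitAssignment, worm_ids=None,
                     validation=True):
    """Fit on the train side of a worm-level split; returns (model, metrics).

    ``worm_ids`` aligns images to split sides (defaults to one image per
    worm in split order).  Training validation curves go to
    ``model.history_``; the returned metrics are computed on the test side.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if worm_ids is None:
        raise ValueError("worm_ids are required to apply a worm-level split")
    sides = np.array([split.side(w) for w in worm_ids])
    tr, te = sides == "train", sides == "test"
    if not tr.any() or not te.any():
        raise ValueError("split leaves train or test side empty")
    val = (images[te], labels[te]) if validation else None
    model.fit(images[tr], labels[tr], validation_data=val)
    return model, evaluate_classifier(model, images[te], labels[te])


def evaluate_classifier(model: WormNetClassifier, X, y) -> ClfMetrics:
    """Metric panel at the argmax decision.

    Positive class = ``classes_[1]``.  ROC AUC comes from the rank statistic
    of the positive-class probability; with a one-class evaluation set it is
    undefined and reported as None.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    proba = model.predict_proba(X)
    pred = model.classes_[proba.argmax(axis=1)]
    pos = model.classes_[1]
    tp = int(((pred == pos) & (y == pos)).sum())
    fp = int(((pred == pos) & (y != pos)).sum())
    fn = int(((pred != pos) & (y == pos)).sum())
    accuracy = float((pred == y).mean())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    try:
        auc = roc_auc_rank(proba[:, 1], y == pos)
    except ValueError:
        auc = None
    cm = _sk_confusion(y, pred, labels=list(model.classes_))
    return ClfMetrics(accuracy=accuracy, precision=precision, recall=recall,
                      roc_auc=auc, confusion_matrix=cm,
                      classes=tuple(model.classes_))
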