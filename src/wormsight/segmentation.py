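"""Worm body-part segmentation: binary / multi-class U-Net and HydraNet.

Four architectures cover the segmentation problem at the working 96 x 96
resolution:

* :class:`BinaryUNet` — whole-worm vs background with a 1-channel sigmoid head.
* :class:`MulticlassUNet` — softmax over {background, anterior, mid,
  posterior}; per-channel thresholding of the soft maps can produce
  overlapping part masks, which is the failure mode that motivates HydraNet.
* :class:`HydraNet` — one shared encoder with an independent full decoder
  ("head") per part, each solving its own binary problem; the joint loss is
  the unweighted sum of per-head Dice losses.  Three heads (anterior, mid,
  posterior) or four (plus whole worm).

All are trained with Dice loss under Adam (starting learning rate 0.001,
library-default moments) while the Jaccard index of the thresholded
predictions is monitored, and follow the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``get_params``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dataio import HEAD_NAMES, PART_NAMES, PartMaskSet, WormImage
from .nn import Adam, HydraNetModel, UNetModel
from .nn.losses import DICE_EPS, dice_loss_grad

__all__ = [
    "BinaryUNet",
    "HydraNet",
    "MulticlassUNet",
    "dice_loss",
    "evaluate_segmentation",
    "jaccard_index",
    "predict_part_masks",
]


def dice_loss(pred, truth, eps=DICE_EPS):
    """1 - smoothed Dice coefficient, averaged over samples and channels."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    loss, _ = dice_loss_grad(pred, truth, eps)
    return float(loss)


def jaccard_index(pred_binary, truth):
    """|A n B| / |A u B| for binary masks; 1.0 when both are empty."""
    a = np.asarray(pred_binary).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _as_batch(X):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    if X.ndim == 3:
        X = X[..., None]
    return X


class _SegmenterBase(BaseEstimator):
    """Shared Dice-loss training loop and prediction plumbing."""

    def _build(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _n_channels(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` (n, H, W) and targets ``y`` (see subclass).

        ``validation_data=(X_val, y_val)`` adds per-epoch validation loss and
        Jaccard to ``history_``.
        """
        X = _as_batch(X)
        Y = self._prepare_targets(y, X.shape[0])
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"images of shape {X.shape[1:3]} do not match input_size "
                f"{self.input_size}")
        self.model_ = self._build()
        opt = Adam(self.model_.params_and_grads(), lr=self.lr)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        history = []
        for epoch in range(self.epochs):
            if self.lr_schedule and epoch in self.lr_schedule:
                opt.lr = self.lr_schedule[epoch]
            order = rng.permutation(n)
            losses, jacs = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                prob = self.model_.forward(X[idx], train=True)
                loss, dprob = dice_loss_grad(prob, Y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite Dice loss at epoch {epoch}; "
                        "lower the learning rate or check the targets")
                self.model_.backward(dprob)
                opt.step()
                losses.append(loss)
                jacs.append(jaccard_index(prob >= self.threshold, Y[idx] >= 0.5))
            row = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "jaccard": float(np.mean(jacs))}
            if validation_data is not None:
                Xv, yv = validation_data
                Xv = _as_batch(Xv)
                Yv = self._prepare_targets(yv, Xv.shape[0])
                pv = self._forward_eval(Xv)
                row["val_loss"], _ = dice_loss_grad(pv, Yv)
                row["val_jaccard"] = jaccard_index(pv >= self.threshold, Yv >= 0.5)
            history.append(row)
        self.history_ = history
        return self

    def _forward_eval(self, X, batch=None):
        batch = batch or self.batch_size  # reuse the training-shape buffers
        out = [self.model_.forward(X[i : i + batch], train=False).copy()
               for i in range(0, X.shape[0], batch)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, X):
        """Per-pixel probability maps, shape (n, H, W, n_channels)."""
        X = _as_batch(X)
        if X.shape[1] != self.input_size:
            raise ValueError(
                f"images of shape {X.shape[1:3]} do not match input_size "
                f"{self.input_size}")
        return self._forward_eval(X)


class BinaryUNet(_SegmenterBase):
    """Whole-worm segmentation U-Net with a sigmoid head."""

    def __init__(self, input_size=96, depth=4, base_filters=16, dropout=0.25,
                 lr=0.001, lr_schedule=None, epochs=40, batch_size=8,
                 threshold=0.5, seed=0):
        self.input_size = input_size
        self.depth = depth
        self.base_filters = base_filters
        self.dropout = dropout
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed

    def _build(self):
        return UNetModel(input_size=self.input_size, depth=self.depth,
                         base_filters=self.base_filters, dropout=self.dropout,
                         out_channels=1, head="sigmoid", seed=self.seed)

    def _prepare_targets(self, y, n):
        Y = np.asarray(y, dtype=np.float32)
        if Y.ndim == 3:
            Y = Y[..., None]
        if Y.shape[0] != n:
            raise ValueError("images and masks are not aligned")
        return Y

    def predict(self, X):
        """Binary whole-worm masks (n, H, W)."""
        return self.predict_proba(X)[..., 0] >= self.threshold


class MulticlassUNet(_SegmenterBase):
    """One-hot {bg, anterior, mid, posterior} segmentation with softmax head."""

    def __init__(self, input_size=96, depth=4, base_filters=16, dropout=0.25,
                 n_classes=4, lr=0.001, lr_schedule=None, epochs=40,
                 batch_size=8, threshold=0.5, seed=0):
        self.input_size = input_size
        self.depth = depth
        self.base_filters = base_filters
        self.dropout = dropout
        self.n_classes = n_classes
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed

    def _build(self):
        return UNetModel(input_size=self.input_size, depth=self.depth,
                         base_filters=self.base_filters, dropout=self.dropout,
                         out_channels=self.n_classes, head="softmax",
                         seed=self.seed)

    def _prepare_targets(self, y, n):
        """Accept label images (n, H, W) in {0..n_classes-1} or one-hot."""
        Y = np.asarray(y)
        if Y.ndim == 3:
            Y = np.eye(self.n_classes, dtype=np.float32)[Y.astype(int)]
        if Y.shape[0] != n:
            raise ValueError("images and masks are not aligned")
        return Y.astype(np.float32)

    def predict(self, X):
        """Per-pixel argmax label image (n, H, W) in {0..n_classes-1}."""
        return self.predict_proba(X).argmax(axis=-1)


class HydraNet(_SegmenterBase):
    """Shared encoder, one independent binary decoder per body part.

    ``heads`` is an ordered subset of (anterior, mid, posterior, whole) of
    length 3 or 4; the joint loss is the unweighted sum of per-head Dice
    losses (equivalently their mean, which leaves the Adam direction
    unchanged).  Default dropout and batch size are tuned per architecture
    (lighter regularization and more updates per epoch than the plain
    U-Nets), which converges markedly faster on this multi-head objective.
    """

    def __init__(self, heads=HEAD_NAMES, input_size=96, depth=4,
                 base_filters=16, dropout=0.1, lr=0.001, lr_schedule=None,
                 epochs=40, batch_size=4, threshold=0.5, seed=0):
        self.heads = tuple(heads)
        self.input_size = input_size
        self.depth = depth
        self.base_filters = base_filters
        self.dropout = dropout
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed

    def _build(self):
        if len(self.heads) not in (3, 4):
            raise ValueError("HydraNet takes 3 or 4 heads")
        return HydraNetModel(self.heads, input_size=self.input_size,
                             depth=self.depth, base_filters=self.base_filters,
                             dropout=self.dropout, seed=self.seed)

    def _prepare_targets(self, y, n):
        """(n, H, W, n_heads) stack of binary masks in head order."""
        Y = np.asarray(y, dtype=np.float32)
        if Y.ndim != 4 or Y.shape[-1] != len(self.heads):
            raise ValueError(
                f"expected masks of shape (n, H, W, {len(self.heads)}) "
                f"matching heads {self.heads}, got {Y.shape}")
        if Y.shape[0] != n:
            raise ValueError("images and masks are not aligned")
        return Y

    def predict(self, X):
        """Thresholded per-head masks, shape (n, H, W, n_heads)."""
        return self.predict_proba(X) >= self.threshold


def predict_part_masks(model, image, threshold=0.5):
    """Predict a :class:`PartMaskSet` for one image with any trained model.

    HydraNet heads are thresholded independently (for a 3-head net the whole
    mask is the union of the parts).  For the multi-class U-Net the per-pixel
    argmax rules out overlap by construction; thresholding its raw soft maps
    instead (``MulticlassUNet.predict_proba``) reproduces the overlapping
    anterior/posterior masks the architecture is known for.  A binary U-Net
    yields only the whole-worm mask (parts empty).
    """
    pixels = image.pixels if isinstance(image, WormImage) else np.asarray(image)
    if pixels.shape != (model.input_size, model.input_size):
        raise ValueError(
            f"image shape {pixels.shape} does not match model input_size "
            f"{model.input_size}")
    prob = model.predict_proba(pixels[None])[0]
    if isinstance(model, HydraNet):
        maps = {h: prob[..., k] >= threshold for k, h in enumerate(model.heads)}
        if "whole" not in maps:
            maps["whole"] = maps["anterior"] | maps["mid"] | maps["posterior"]
        return PartMaskSet(**{h: maps[h] for h in HEAD_NAMES})
    if isinstance(model, MulticlassUNet):
        label = prob.argmax(axis=-1)
        return PartMaskSet.from_label_image(label)
    if isinstance(model, BinaryUNet):
        whole = prob[..., 0] >= threshold
        empty = np.zeros_like(whole)
        return PartMaskSet(anterior=empty, mid=empty, posterior=empty,
                           whole=whole)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def evaluate_segmentation(model, X, mask_sets, threshold=0.5):
    """Mean Jaccard per head over a dataset plus the across-head average.

    ``mask_sets`` is a sequence of ground-truth :class:`PartMaskSet`.  For a
    binary U-Net only the whole-worm head is scored; for the multi-class
    U-Net parts come from the argmax label image.
    """
    X = np.asarray(X, dtype=np.float32)
    mask_sets = list(mask_sets)
    if len(mask_sets) == 0:
        raise ValueError("empty evaluation dataset")
    if isinstance(model, BinaryUNet):
        heads = ("whole",)
    elif isinstance(model, HydraNet):
        heads = model.heads
    else:
        heads = HEAD_NAMES
    scores = {h: [] for h in heads}
    for i, truth in enumerate(mask_sets):
        pred = predict_part_masks(model, X[i], threshold=threshold)
        for h in heads:
            scores[h].append(jaccard_index(getattr(pred, h), getattr(truth, h)))
    result = {h: float(np.mean(v)) for h, v in scores.items()}
    result["average"] = float(np.mean([result[h] for h in heads]))
    return result
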