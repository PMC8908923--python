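"""Tandem interpretation: which body part drives the classification?

The procedure unites classifier saliency with part segmentation:

1. a class activation map (CAM) is computed for an image from the GAP-head
   WormNet as the class-weighted sum of the final convolutional feature
   maps, bilinearly upsampled to the input resolution;
2. the CAM is binarized at its upper quartile (pixels >= the 75th
   percentile are "salient");
3. the salient mask is intersected with the anterior / mid-body / posterior
   masks (HydraNet predictions or ground truth) and each part's share of the
   within-worm salient pixels is reported as a percentage;
4. per-class part percentages are compared with a one-way ANOVA followed by
   Tukey's HSD adjustment.

On cohorts where a discriminative feature was planted into a known part,
that part should carry the largest percentage — the synthetic analogue of
asking which worm body part carries lifespan information.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from .classification import WormNetClassifier
from .dataio import PART_NAMES, PartMaskSet, WormImage

__all__ = [
    "AnovaResult",
    "OverlapRecord",
    "SaliencyMap",
    "anova_tukey",
    "compute_cam",
    "interpret_cohort",
    "overlap_fractions",
    "threshold_upper_quartile",
]


@dataclasses.dataclass
class SaliencyMap:
    """Raw (un-normalized) class-evidence map at input resolution."""

    values: np.ndarray
    class_index: int
    worm_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency map contains non-finite values")


@dataclasses.dataclass
class OverlapRecord:
    """Per-image percentages of within-worm salient pixels by body part."""

    worm_id: str
    class_label: object
    pct_anterior: float
    pct_mid: float
    pct_posterior: float
    flagged: bool = False  # no salient pixel fell inside the worm

    def total(self):
        return self.pct_anterior + self.pct_mid + self.pct_posterior


@dataclasses.dataclass
class AnovaResult:
    """One-way ANOVA F/p plus Tukey HSD pairwise table and group summaries."""

    F: float
    p: float
    group_means: dict  # name -> {"mean", "sem", "n"}
    tukey: list  # [{"pair": (a, b), "mean_diff", "p_adj"}]


def compute_cam(classifier, image, class_index: int) -> SaliencyMap:
    """CAM(x, y) = sum_k w_k[class] * f_k(x, y) from a gap_cam WormNet.

    ``f_k`` are the final conv feature maps entering the global average
    pooling; ``w_k`` the dense class weights.  The raw map is bilinearly
    upsampled to the model input resolution and not normalized.
    """
    model = classifier.model_ if isinstance(classifier, WormNetClassifier) else classifier
    weights = model.cam_weights  # raises for flatten_fc heads
    pixels = image.pixels if isinstance(image, WormImage) else np.asarray(image)
    worm_id = image.worm_id if isinstance(image, WormImage) else ""
    model.forward(pixels[None, ..., None].astype(np.float32), train=False)
    feats = model.feature_maps_[0]  # (g, g, K)
    cam_small = feats @ weights[:, class_index]
    size = model.input_size
    cam = resize(cam_small.astype(np.float64), (size, size), order=1,
                 anti_aliasing=False, preserve_range=True)
    return SaliencyMap(values=cam, class_index=int(class_index), worm_id=worm_id)


def threshold_upper_quartile(saliency) -> np.ndarray:
    """Salient iff value >= Q3 (75th percentile, linear interpolation).

    ``>=`` keeps ties; a constant map is degenerate and comes back
    all-salient with a warning.
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if values.max() == values.min():
        warnings.warn("constant saliency map: upper-quartile threshold is "
                      "degenerate, marking all pixels salient", stacklevel=2)
        return np.ones_like(values, dtype=bool)
    q3 = np.percentile(values, 75)
    return values >= q3


def overlap_fractions(salient, parts: PartMaskSet, part_probs=None,
                      worm_id="", class_label=None) -> OverlapRecord:
    """Percentage of within-worm salient pixels in each body part.

    The denominator is ``|salient n (anterior u mid u posterior)|`` so the
    three percentages sum to 100 for non-flagged records.  Predicted part
    masks may overlap; contested pixels go to the part with the highest soft
    probability (``part_probs``: (H, W, 3) in anterior/mid/posterior order),
    ties and missing probabilities resolving toward the more anterior part.
    If no salient pixel lies inside the worm the record is flagged all-zero.
    """
    salient = np.asarray(salient).astype(bool)
    if salient.shape != parts.shape:
        raise ValueError(
            f"salient map shape {salient.shape} does not match masks {parts.shape}")
    masks = np.stack([getattr(parts, p) for p in PART_NAMES], axis=-1)
    if part_probs is None:
        probs = masks.astype(np.float32)
    else:
        probs = np.asarray(part_probs, dtype=np.float32)
        if probs.shape != masks.shape:
            raise ValueError("part_probs must be (H, W, 3)")
    # owner = highest-probability part among those claiming the pixel;
    # argmax takes the first (most anterior) maximum, which is the tie rule
    owner = np.where(masks.any(axis=-1),
                     np.argmax(np.where(masks, probs, -np.inf), axis=-1), -1)
    counts = np.array([(salient & (owner == k)).sum() for k in range(3)],
                      dtype=float)
    denom = counts.sum()
    if denom == 0:
        return OverlapRecord(worm_id=worm_id, class_label=class_label,
                             pct_anterior=0.0, pct_mid=0.0, pct_posterior=0.0,
                             flagged=True)
    pct = 100.0 * counts / denom
    return OverlapRecord(worm_id=worm_id, class_label=class_label,
                         pct_anterior=float(pct[0]), pct_mid=float(pct[1]),
                         pct_posterior=float(pct[2]), flagged=False)


def anova_tukey(groups) -> AnovaResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise comparisons.

    ``groups`` is either a mapping name -> 1-D observations or a sequence of
    :class:`OverlapRecord` (grouped into the three part-percentage groups).
    The HSD adjusted p for a pair is the studentized-range tail probability
    of q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with k groups
    and N - k error degrees of freedom.
    """
    if not isinstance(groups, dict):
        records = [r for r in groups]
        groups = {
            "anterior": [r.pct_anterior for r in records if not r.flagged],
            "mid": [r.pct_mid for r in records if not r.flagged],
            "posterior": [r.pct_posterior for r in records if not r.flagged],
        }
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(data)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(d) for d in data])
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 observations")
    n_total = int(ns.sum())
    means = np.array([d.mean() for d in data])
    grand = np.concatenate(data).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - m) ** 2).sum() for d, m in zip(data, means)))
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        F = 0.0 if ms_between == 0 else np.inf
        p = 1.0 if ms_between == 0 else 0.0
    else:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_b, df_w))
    group_means = {
        g: {"mean": float(m), "sem": float(d.std(ddof=1) / np.sqrt(len(d))),
            "n": int(len(d))}
        for g, m, d in zip(names, means, data)
    }
    tukey = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[j] - means[i])
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            tukey.append({"pair": (names[i], names[j]), "mean_diff": diff,
                          "p_adj": p_adj})
    return AnovaResult(F=float(F), p=float(p), group_means=group_means,
                       tukey=tukey)


def interpret_cohort(classifier, segmenter, images, labels, worm_ids=None,
                     mask_sets=None, use_true_class=False, threshold=0.5):
    """Run the tandem interpretation over a cohort.

    For each image: predict the class (or take the true one when
    ``use_true_class``), compute the CAM for that class, binarize at the
    upper quartile, segment the parts with ``segmenter`` (or use the
    supplied ground-truth ``mask_sets``), and record the per-part salient
    percentages.  Records are grouped by the *true* class label and each
    class with enough non-flagged records gets an ANOVA + Tukey comparison
    of the three parts.

    Returns ``(table, stats_by_class, n_flagged)`` where ``table`` is a
    DataFrame of the per-image records.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    n = len(images)
    if worm_ids is None:
        worm_ids = [f"img{i:04d}" for i in range(n)]
    if mask_sets is None and segmenter is None:
        raise ValueError("need a segmenter or ground-truth mask_sets")
    class_order = list(classifier.classes_)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate CAMs are counted below
        for i in range(n):
            if use_true_class:
                class_index = class_order.index(labels[i])
            else:
                class_index = int(classifier.predict_proba(images[i][None]).argmax())
            cam = compute_cam(classifier, images[i], class_index)
            cam.worm_id = worm_ids[i]
            salient = threshold_upper_quartile(cam)
            if mask_sets is not None:
                parts = mask_sets[i]
                probs = None
            else:
                from .segmentation import HydraNet  # local: avoid cycle

                soft = segmenter.predict_proba(images[i][None])[0]
                if isinstance(segmenter, HydraNet):
                    chan = [segmenter.heads.index(p) for p in PART_NAMES]
                    probs = soft[..., chan]
                    part_masks = {p: soft[..., c] >= threshold
                                  for p, c in zip(PART_NAMES, chan)}
                    whole = (part_masks["anterior"] | part_masks["mid"]
                             | part_masks["posterior"])
                    parts = PartMaskSet(whole=whole, **part_masks)
                else:  # multi-class U-Net: argmax labels, no overlap
                    label_img = soft.argmax(axis=-1)
                    parts = PartMaskSet.from_label_image(label_img)
                    probs = soft[..., 1:4]
            records.append(
                overlap_fractions(salient, parts, part_probs=probs,
                                  worm_id=worm_ids[i], class_label=labels[i]))
    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    n_flagged = int(table["flagged"].sum())
    stats_by_class = {}
    for cls in class_order:
        sub = [r for r in records if r.class_label == cls and not r.flagged]
        if len(sub) >= 2:
            stats_by_class[cls] = anova_tukey(sub)
    return table, stats_by_class, n_flagged
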