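# wormsight

Tandem segmentation–classification interpretability for *C. elegans*
micrographs: which part of the worm carries the signal a classifier uses?

Transmission-light micrographs of young adult worms (days 1–3, one worm per
580.5 μm × 580.5 μm field of view, worked at 96 × 96 px) carry morphological
information about how long the animal will live and how much it will move
over its lifetime. A plain CNN can exploit that signal but cannot say where
it sits. `wormsight` implements the full tandem pipeline:

* **HydraNet** — a U-Net encoder shared by independent per-part decoders
  (anterior / mid-body / posterior, optionally whole worm), each a binary
  sigmoid head trained jointly with Dice loss
  (`1 − (2|A∩B|+ε)/(|A|+|B|+ε)`), evaluated by Jaccard index
  `J = |A∩B|/|A∪B|`. Plain binary and 4-class softmax U-Nets are included
  as baselines.
* **WormNet** — a shallow 5-block CNN (conv–BN–ReLU–maxpool–spatial
  dropout) classifying lifespan ("short" < 8 adult days vs "long" ≥ 8) or
  movement (lifetime crawled distance below vs above the cohort mean),
  trained with binary cross-entropy under 30-fold flip/shift/rotation
  augmentation. A global-average-pooling head variant exposes class
  activation maps: `CAM(x,y) = Σₖ wₖ[c]·fₖ(x,y)`.
* **Interpretation** — binarize the CAM at its upper quartile, intersect
  with the HydraNet part masks, report the percentage of within-worm
  salient pixels per part, and compare parts by one-way ANOVA with Tukey's
  HSD adjustment.
* **Synthetic worms** — a fully seeded generator of curved, textured,
  orientable worms with exact ground-truth part masks and metadata, plus
  the ability to plant a class-discriminative texture into a chosen body
  part. This makes the whole pipeline testable end-to-end: the planted
  part is known, so the interpretation stage has a ground truth.

All networks train on a small numpy/numba backprop core shipped in
`wormsight.nn` — one CPU core and a few GB of RAM suffice at the working
resolution. Estimators follow the scikit-learn protocol
(`fit`/`predict`/`predict_proba`/`get_params`).

## Worked example

```python
import numpy as np
from wormsight import (
    GeneratorConfig, generate_dataset, split_by_worm_id,
    HydraNet, WormNetClassifier, evaluate_segmentation,
    evaluate_classifier, interpret_cohort,
)

# 1. synthetic cohort with the discriminative feature planted posteriorly
cfg = GeneratorConfig(planted_part="posterior", effect_size=0.3)
ds = generate_dataset(200, cfg, master_seed=7)
X, y = ds.images(), ds.planted_labels()
split = split_by_worm_id([w.record.worm_id for w in ds], 0.3, seed=1)
tr = np.array([split.side(w.record.worm_id) == "train" for w in ds])

# 2. part segmentation (HydraNet4) and classification (WormNet, CAM head)
seg = HydraNet(epochs=30, lr_schedule={20: 3e-4, 26: 1e-4}, seed=0)
seg.fit(X[tr], ds.mask_stack()[tr])
clf = WormNetClassifier(head_mode="gap_cam", epochs=25, seed=0).fit(X[tr], y[tr])

seg_report = evaluate_segmentation(
    seg, X[~tr], [w.masks for w, t in zip(ds, tr) if not t])
print({k: round(v, 3) for k, v in seg_report.items()})
m = evaluate_classifier(clf, X[~tr], y[~tr]).as_dict()
print({k: round(v, 3) for k, v in m.items()
       if k in ("accuracy", "precision", "recall", "roc_auc")})

# 3. which part drives the classification?  (here scored against the exact
#    part definitions; pass `seg` instead of mask_sets for the full tandem)
table, stats, n_flagged = interpret_cohort(
    clf, None, X[~tr], y[~tr],
    mask_sets=[w.masks for w, t in zip(ds, tr) if not t])
for cls, res in stats.items():
    means = {g: round(v["mean"], 1) for g, v in res.group_means.items()}
    print(cls, means, "ANOVA p =", f"{res.p:.2e}")
```

Output (~15 min on one CPU core):

```
{'anterior': 0.965, 'mid': 0.94, 'posterior': 0.94, 'whole': 0.989, 'average': 0.959}
{'accuracy': 0.983, 'precision': 1.0, 'recall': 0.972, 'roc_auc': 1.0}
0 {'anterior': 40.9, 'mid': 6.9, 'posterior': 52.2} ANOVA p = 3.98e-03
1 {'anterior': 0.0, 'mid': 45.3, 'posterior': 54.7} ANOVA p = 1.40e-58
```

Read: the segmenter recovers each body part on held-out worms at Jaccard
0.94–0.99; the classifier separates the planted classes essentially
perfectly; and in the planted class (label 1) the posterior carries the
largest share of the salient CAM pixels while the anterior carries almost
none — the pipeline localizes the feature where it was planted. Saliency
attribution through HydraNet-predicted masks instead of the exact part
definitions is coarser near the mid/posterior boundary; `docs/methods.md`
discusses that sensitivity.

A command-line interface wraps the same stages:

```bash
wormsight generate --n 130 --seed 42 --out runs/data
wormsight train-seg --data runs/data --arch hydranet4 --out runs/seg
wormsight train-clf --data runs/data --task lifespan --out runs/clf
wormsight interpret --data runs/data \
    --classifier runs/clf/checkpoint.npz --segmenter runs/seg/checkpoint.npz \
    --out runs/interp
```

## Layout

```
src/wormsight/
  nn/              numpy CNN core (layers, losses, Adam, model wiring)
  synthetic.py     seeded worm generator + planted class features
  dataio.py        images, masks, labels, splits, augmentation, ablation
  segmentation.py  BinaryUNet / MulticlassUNet / HydraNet estimators
  classification.py WormNet classifier + metric panel
  interpretation.py CAM, upper-quartile saliency, part overlap, ANOVA/Tukey
  cli.py           generate / train-seg / train-clf / interpret / evaluate
docs/methods.md    model, generator and statistics documentation
scripts/acceptance.py  benchmark reproduction
```
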