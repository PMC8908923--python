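"""Checkpointing of fitted estimators (.npz: weights + constructor params)."""

from __future__ import annotations

import json

import numpy as np

from . import classification, segmentation

_REGISTRY = {
    "BinaryUNet": segmentation.BinaryUNet,
    "MulticlassUNet": segmentation.MulticlassUNet,
    "HydraNet": segmentation.HydraNet,
    "WormNetClassifier": classification.WormNetClassifier,
}


def save_estimator(estimator, path):
    """Persist a fitted estimator (model weights + get_params) to ``path``."""
    if not hasattr(estimator, "model_"):
        raise ValueError("estimator is not fitted")
    params = estimator.get_params()
    meta = {"class": type(estimator).__name__, "params": params}
    if hasattr(estimator, "classes_"):
        meta["classes"] = np.asarray(estimator.classes_).tolist()
    state = {f"state/{k}": v for k, v in estimator.model_.state_dict().items()}
    np.savez_compressed(path, meta=json.dumps(meta, default=str), **state)


def load_estimator(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cls = _REGISTRY[meta["class"]]
        params = meta["params"]
        for key in ("filters", "heads"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        est = cls(**{k: v for k, v in params.items()
                     if k in cls().get_params()})
        est.model_ = est._build() if hasattr(est, "_build") else None
        if est.model_ is None:
            raise ValueError(f"cannot rebuild {meta['class']}")
        if "classes" in meta:
            est.classes_ = np.asarray(meta["classes"])
        est.model_.load_state_dict(
            {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")})
    return est
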