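"""Image / mask / metadata containers, class-label derivation, leak-free
splits, augmentation and the image-ablation controls.

Conventions: micrographs are single-channel arrays min-max normalized to
[0, 1]; the working resolution is 96 x 96 pixels covering a reference
field of view of 580.5 um x 580.5 um.  Lifespan classes are "short"
(< 8 adult days) vs "long" (>= 8 days); movement classes are "low"/"high"
around the arithmetic-mean lifetime crawled distance of the cohort.
Train/test splits are made per worm identity so that repeated images of the
same animal never straddle the split.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

REFERENCE_FOV_UM = 580.5
WORKING_SIZE = 96

PART_NAMES = ("anterior", "mid", "posterior")
HEAD_NAMES = ("anterior", "mid", "posterior", "whole")


@dataclasses.dataclass
class WormImage:
    """One grayscale micrograph plus provenance."""

    pixels: np.ndarray
    worm_id: str = ""
    adult_day: int = 1
    pixel_size: float = REFERENCE_FOV_UM / WORKING_SIZE  # um / px

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D pixels, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")


@dataclasses.dataclass
class PartMaskSet:
    """Binary masks for the three body parts and the whole worm.

    Ground-truth sets partition the whole-worm mask exactly; predicted sets
    may overlap (independent sigmoid heads / soft multi-class maps carry no
    disjointness guarantee).
    """

    anterior: np.ndarray
    mid: np.ndarray
    posterior: np.ndarray
    whole: np.ndarray

    def __post_init__(self):
        arrays = {}
        shape = None
        for name in HEAD_NAMES:
            a = np.asarray(getattr(self, name)).astype(bool)
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("part masks must share one grid")
            arrays[name] = a
            setattr(self, name, a)
        self._shape = shape

    @property
    def shape(self):
        return self._shape

    def parts(self):
        return {name: getattr(self, name) for name in PART_NAMES}

    def is_partition(self):
        """True when the parts are pairwise disjoint and tile ``whole``."""
        a, m, p = self.anterior, self.mid, self.posterior
        disjoint = not ((a & m).any() or (a & p).any() or (m & p).any())
        return disjoint and bool(((a | m | p) == self.whole).all())

    def to_label_image(self):
        """Indexed label image {0: bg, 1: anterior, 2: mid, 3: posterior}."""
        label = np.zeros(self.shape, dtype=np.uint8)
        for value, name in enumerate(PART_NAMES, start=1):
            label[getattr(self, name)] = value
        return label

    @classmethod
    def from_label_image(cls, label):
        label = np.asarray(label)
        return cls(anterior=label == 1, mid=label == 2, posterior=label == 3,
                   whole=label > 0)


@dataclasses.dataclass
class SplitAssignment:
    """worm_id -> 'train' / 'test'; the worm is the unit of the split."""

    assignment: dict

    @property
    def train_ids(self):
        return [w for w, side in self.assignment.items() if side == "train"]

    @property
    def test_ids(self):
        return [w for w, side in self.assignment.items() if side == "test"]

    def side(self, worm_id):
        return self.assignment[worm_id]

    def to_frame(self):
        return pd.DataFrame(
            {"worm_id": list(self.assignment), "side": list(self.assignment.values())})

    def save(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path):
        df = pd.read_csv(path, dtype={"worm_id": str})
        return cls(dict(zip(df["worm_id"], df["side"])))


@dataclasses.dataclass
class AugmentationConfig:
    """Random flips, sub-10% shifts and +/-90 degree rotations with
    nearest-value fill, drawn independently ``fold`` times per original
    image each epoch."""

    horizontal_flip: bool = True
    vertical_flip: bool = True
    shift_fraction: float = 0.10
    rotation_range_deg: float = 90.0
    fill_strategy: str = "nearest"
    fold: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shift_fraction < 1:
            raise ValueError("shift_fraction must lie in [0, 1)")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.fill_strategy != "nearest":
            raise ValueError("only the nearest-value fill strategy is supported")


# ---------------------------------------------------------------------------
# loading / preprocessing


def normalize_minmax(pixels):
    pixels = np.asarray(pixels, dtype=np.float32)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise ValueError("image has zero dynamic range (constant pixels)")
    return (pixels - lo) / (hi - lo)


def load_image(path, target_size=None, worm_id="", adult_day=1):
    """Read a single-channel image, min-max normalize, optionally resample.

    Multi-channel files are collapsed by channel averaging.  ``target_size``
    resamples to ``target_size x target_size`` with bilinear interpolation.
    """
    raw = np.asarray(iio.imread(path)).astype(np.float32)
    if raw.ndim == 3:
        raw = raw.mean(axis=-1)
    if raw.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {raw.shape}")
    pixels = normalize_minmax(raw)
    fov_um = REFERENCE_FOV_UM
    if target_size is not None:
        pixels = resize(pixels, (target_size, target_size), order=1,
                        anti_aliasing=True, preserve_range=True).astype(np.float32)
        pixels = np.clip(pixels, 0.0, 1.0)
    size = pixels.shape[0]
    return WormImage(pixels=pixels, worm_id=worm_id, adult_day=adult_day,
                     pixel_size=fov_um / size)


def crop_center(image: WormImage, crop_size: int) -> WormImage:
    """Central crop; offsets are floor((dim - crop) / 2) on each axis."""
    h, w = image.pixels.shape
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop_size {crop_size} exceeds image shape {(h, w)}")
    oy, ox = (h - crop_size) // 2, (w - crop_size) // 2
    return dataclasses.replace(
        image, pixels=image.pixels[oy : oy + crop_size, ox : ox + crop_size])


# ---------------------------------------------------------------------------
# class labels


def assign_lifespan_class(record):
    """'short' iff lifespan < 8 adult days, else 'long'.

    The class definition is <=7 days vs >=8 days; fractional lifespans in
    (7, 8) are resolved by the single threshold at 8.
    """
    lifespan = getattr(record, "lifespan_days", record)
    if lifespan is None or (isinstance(lifespan, float) and np.isnan(lifespan)):
        raise ValueError("record has no lifespan_days")
    if lifespan < 0:
        raise ValueError("lifespan_days must be nonnegative")
    return "short" if lifespan < 8.0 else "long"


def assign_movement_class(records):
    """'high' iff total lifetime distance exceeds the cohort mean (ties 'low')."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to define the mean threshold")
    distances = {}
    for r in records:
        d = getattr(r, "total_distance", None)
        if d is None or (isinstance(d, float) and np.isnan(d)):
            raise ValueError(f"record {getattr(r, 'worm_id', r)!r} has no total_distance")
        distances[r.worm_id] = float(d)
    mean = float(np.mean(list(distances.values())))
    return {w: ("high" if d > mean else "low") for w, d in distances.items()}


def split_by_worm_id(worm_ids, test_fraction, seed):
    """Deterministic worm-level train/test split (no image of a worm leaks)."""
    unique = list(dict.fromkeys(worm_ids))
    if not unique:
        raise ValueError("no worm ids to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = round(len(unique) * test_fraction)
    if n_test == 0 or n_test == len(unique):
        raise ValueError("split would leave one side empty")
    order = np.random.default_rng(seed).permutation(len(unique))
    test = {unique[i] for i in order[:n_test]}
    return SplitAssignment({w: ("test" if w in test else "train") for w in unique})


# ---------------------------------------------------------------------------
# augmentation


def _transform_once(pixels, rng, config):
    out = pixels
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :]
    if config.shift_fraction > 0:
        dy = rng.uniform(-config.shift_fraction, config.shift_fraction) * out.shape[0]
        dx = rng.uniform(-config.shift_fraction, config.shift_fraction) * out.shape[1]
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
    if config.rotation_range_deg > 0:
        angle = rng.uniform(-config.rotation_range_deg, config.rotation_range_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    return np.ascontiguousarray(out, dtype=np.float32)


def augment_stream(images, targets, config: AugmentationConfig, rng=None):
    """Yield one epoch of ``fold x n`` independently transformed pairs.

    Each original image is drawn ``fold`` times under independent flips,
    shifts within ``shift_fraction`` of each dimension and rotations uniform
    in +/- ``rotation_range_deg``; vacated pixels take the nearest edge
    value.  Targets are classification labels and pass through untouched.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    images = list(images)
    targets = list(targets)
    if len(images) != len(targets):
        raise ValueError("images and targets must be aligned")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(config.fold):
        for pixels, target in zip(images, targets):
            arr = pixels.pixels if isinstance(pixels, WormImage) else pixels
            yield _transform_once(arr, rng, config), target


# ---------------------------------------------------------------------------
# ablation transforms


def _check_mask(image: WormImage, mask):
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.pixels.shape}")
    return mask


def ablate_worm(image: WormImage, whole_mask, noise_seed: int) -> WormImage:
    """Replace worm pixels with i.i.d. uniform [0, 1] noise (background kept).

    Training on such images probes whether a classifier leans on the
    background rather than worm morphology.
    """
    mask = _check_mask(image, whole_mask)
    rng = np.random.default_rng(noise_seed)
    pixels = image.pixels.copy()
    pixels[mask] = rng.random(int(mask.sum()), dtype=np.float32)
    return dataclasses.replace(image, pixels=pixels)


def mask_background(image: WormImage, whole_mask, fill_value: float) -> WormImage:
    """Set background (mask == 0) pixels to ``fill_value``; worm kept."""
    mask = _check_mask(image, whole_mask)
    pixels = image.pixels.copy()
    pixels[~mask] = np.float32(fill_value)
    return dataclasses.replace(image, pixels=pixels)


# ---------------------------------------------------------------------------
# on-disk formats


def write_mask_set(masks: PartMaskSet, directory, stem):
    """One 8-bit {0,255} PNG per part plus the whole-worm mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in HEAD_NAMES:
        arr = (getattr(masks, name).astype(np.uint8)) * 255
        iio.imwrite(directory / f"{stem}_{name}.png", arr)


def read_dataset_dir(directory):
    """Load a generated dataset directory (images, masks, metadata.csv).

    Returns ``(images, mask_sets, table)``: a (N, H, W) float32 stack in
    [0, 1], the ground-truth :class:`PartMaskSet` per image (None where
    masks are absent), and the metadata table.
    """
    directory = Path(directory)
    table = pd.read_csv(directory / "metadata.csv", dtype={"worm_id": str})
    images, mask_sets = [], []
    for worm_id in table["worm_id"]:
        raw = np.asarray(iio.imread(directory / f"{worm_id}_image.png"))
        scale = 65535.0 if raw.dtype == np.uint16 else 255.0
        images.append((raw / scale).astype(np.float32))
        try:
            mask_sets.append(read_mask_set(directory, worm_id))
        except FileNotFoundError:
            mask_sets.append(None)
    return np.stack(images), mask_sets, table


def read_mask_set(directory, stem) -> PartMaskSet:
    directory = Path(directory)
    arrays = {}
    for name in HEAD_NAMES:
        arr = np.asarray(iio.imread(directory / f"{stem}_{name}.png"))
        arrays[name] = arr > 127
    return PartMaskSet(**arrays)
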