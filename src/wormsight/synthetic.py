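"""Synthetic *C. elegans* micrograph generator with exact part masks.

Generates desk-scale stand-ins for transmission-light micrographs of single
adult worms: a smooth random spline midline, a tapering tube body darker than
the textured background, and ground-truth anterior / mid-body / posterior /
whole masks obtained from the same geometry that renders the image, so the
masks are exact by construction.  A class-discriminative texture feature can
be planted into a chosen body part to create cohorts where the part that
drives a classification is known, which is what makes the downstream
CAM-x-segmentation interpretation testable without real data.

Geometry defaults emulate day 1-3 adults in the reference field of view
(580.5 um across 96 px, i.e. ~6 um/px): midline arc length 70-110 px
(~0.4-0.7 mm of worm visible, curled), peak half-width 4-5.5 px (~50-65 um
body width).  Part boundaries follow arc-length fractions (default equal
thirds); pixels are assigned to the part owning the nearest midline point,
with ties resolved toward the more anterior part.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import interpolate, ndimage

from .dataio import PART_NAMES, PartMaskSet, WormImage, write_mask_set

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "SyntheticWorm",
    "WormRecord",
    "WormSpec",
    "generate_dataset",
    "midline_polyline",
    "partition_midline",
    "plant_class_feature",
    "render_worm",
    "sample_worm_spec",
]


class ConfigurationError(ValueError):
    """A generator configuration that cannot produce a valid worm."""


@dataclasses.dataclass(frozen=True)
class TextureParams:
    amplitude: float
    spatial_freq: float  # cycles / px; smoothing sigma = 1 / (2 pi f)

    @property
    def sigma(self):
        return 1.0 / (2.0 * np.pi * self.spatial_freq)


@dataclasses.dataclass(frozen=True)
class BackgroundParams:
    mean: float
    lowfreq_amplitude: float
    lowfreq_sigma: float
    noise_scale: float


@dataclasses.dataclass
class WormRecord:
    """Per-worm metadata from which the class labels derive."""

    worm_id: str
    adult_day: int
    lifespan_days: float
    total_distance: float
    planted_part: str = "none"

    def __post_init__(self):
        if self.adult_day < 1:
            raise ValueError("adult_day must be >= 1")
        if self.lifespan_days < 0 or self.total_distance < 0:
            raise ValueError("lifespan_days and total_distance must be nonnegative")


@dataclasses.dataclass
class WormSpec:
    """Geometry and appearance of one synthetic worm.

    The body is a tube around the midline whose half-width tapers
    asymmetrically: a blunt anterior end (small taper exponent) and a long
    pointed posterior tail (large exponent), the way an adult hermaphrodite
    is oriented under transmission light.  A dark pharynx-like structure
    sits along the first part of the midline; both features make the
    anterior/posterior distinction learnable, as it is for real worms.
    """

    midline_control_points: np.ndarray  # (k, 2) as (row, col)
    width_max: float  # peak half-width, px
    width_taper_head: float  # arc-fraction scale of the blunt head taper
    width_taper_tail: float  # arc-fraction scale of the pointed tail taper
    body_intensity: float
    part_intensity_offsets: tuple  # added to body_intensity per part
    shading_amplitude: float
    pharynx_contrast: float  # extra darkening of the pharynx corridor
    pharynx_band: tuple  # arc-length fraction interval of the pharynx
    vulva_contrast: float  # brightening of the vulva-like mid/posterior marker
    vulva_band: tuple  # arc-length fraction interval of that marker
    texture_params: dict  # part name -> TextureParams
    background_params: BackgroundParams
    part_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        self.midline_control_points = np.asarray(
            self.midline_control_points, dtype=float)
        f = np.asarray(self.part_fractions, dtype=float)
        if f.shape != (3,) or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"part_fractions must be three positive values summing to 1, got {f}")
        if self.width_max <= 0:
            raise ValueError("width_max must be positive")

    def width_profile(self, s):
        """Half-width (px) at arc-length fraction ``s``.

        Near-cylindrical trunk with short tapers at the ends: a blunt head
        (small taper scale) and a longer pointed tail spike; > 0 on (0, 1)
        and ~0 at both ends."""
        s = np.clip(s, 0.0, 1.0)
        return self.width_max * (np.tanh(s / self.width_taper_head)
                                 * np.tanh((1.0 - s) / self.width_taper_tail))


@dataclasses.dataclass
class SyntheticWorm:
    image: np.ndarray  # (H, W) float32 in [0, 1]
    masks: PartMaskSet
    record: WormRecord
    spec: WormSpec
    seed: int

    def __post_init__(self):
        if self.image.shape != self.masks.shape:
            raise ValueError("image and mask dimensions differ")

    def worm_image(self) -> WormImage:
        return WormImage(pixels=self.image, worm_id=self.record.worm_id,
                         adult_day=self.record.adult_day)


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort (defaults are the working
    96 x 96 resolution conditions)."""

    canvas_size: int = 96
    margin: float = 8.0  # keep midline +/- half-width this far inside
    n_control_points: int = 5
    arc_length_range: tuple = (70.0, 110.0)
    turn_sigma: float = 0.55  # rad, per-step heading change of the midline walk
    width_max_range: tuple = (4.0, 5.5)
    width_taper_head: float = 0.05  # blunt anterior (short taper)
    width_taper_tail: float = 0.10  # longer pointed tail spike
    # anatomical landmarks; the pharynx corridor ends at the anterior/mid
    # boundary and the vulva-like marker abuts the mid/posterior boundary,
    # so the annotated part boundaries are visible in the image (as the
    # landmark-guided annotations of real micrographs are)
    pharynx_contrast: float = 0.12
    pharynx_start: float = 0.04
    vulva_contrast: float = 0.18
    vulva_extent: float = 0.035  # arc-length fraction covered by the marker
    body_intensity_range: tuple = (0.25, 0.40)
    # anterior slightly darker (dense pharyngeal muscle), posterior lighter
    # (translucent tail): the optical-density differences that let part
    # identity be read locally in real micrographs
    part_intensity_offsets: tuple = (-0.04, 0.0, 0.05)
    shading_amplitude: float = 0.12
    texture_amplitude_range: tuple = (0.04, 0.08)
    # per-part spatial frequencies (anterior, mid, posterior): body parts
    # have visibly different interior texture (pharynx vs gonad/intestine
    # vs eggs/tail), which is what makes them locally recognizable
    texture_spatial_freq: tuple = (0.22, 0.12, 0.17)
    bg_mean_range: tuple = (0.60, 0.75)
    bg_lowfreq_amplitude: float = 0.05
    bg_lowfreq_sigma: float = 8.0
    bg_noise_scale: float = 0.03
    part_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)
    max_retries: int = 200
    # cohort metadata
    lifespan_range: tuple = (3.0, 14.0)  # adult days
    distance_range: tuple = (20.0, 300.0)  # arbitrary length units
    adult_day_choices: tuple = (1, 2, 3)
    # planted class feature
    planted_part: str | None = None
    effect_size: float = 0.3
    couple_to: str = "lifespan"  # 'lifespan' | 'movement' | 'label'


def _fit_spline(points):
    pts = np.asarray(points, dtype=float)
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
    return tck


def midline_polyline(spec: WormSpec, n_points: int = 600) -> np.ndarray:
    """Evaluate the spline through the control points as an (n, 2) polyline."""
    tck = _fit_spline(spec.midline_control_points)
    u = np.linspace(0.0, 1.0, n_points)
    x, y = interpolate.splev(u, tck)
    return np.column_stack([x, y])


def _polyline_arclength(poly):
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def sample_worm_spec(rng_seed: int, canvas_size: int = 96,
                     config: GeneratorConfig | None = None) -> WormSpec:
    """Draw a random worm geometry/appearance, deterministic given the seed.

    The midline is a cubic spline through ``n_control_points`` waypoints of a
    correlated random walk, rescaled to a target arc length and placed so the
    midline dilated by the peak half-width stays ``margin`` pixels inside the
    canvas; self-overlapping (coiled) geometries are rejected.
    """
    config = config or GeneratorConfig(canvas_size=canvas_size)
    if canvas_size < 32:
        raise ConfigurationError(f"canvas_size must be >= 32, got {canvas_size}")
    rng = np.random.default_rng(rng_seed)
    lo, hi = config.margin, canvas_size - 1 - config.margin
    if hi <= lo:
        raise ConfigurationError(
            f"margin {config.margin} leaves no room on a {canvas_size} px canvas")
    for _ in range(config.max_retries):
        target_len = rng.uniform(*config.arc_length_range)
        width_max = rng.uniform(*config.width_max_range)
        k = config.n_control_points
        heading = rng.uniform(0.0, 2.0 * np.pi)
        step = target_len / (k - 1)
        pts = [np.zeros(2)]
        for _ in range(k - 1):
            heading += rng.normal(0.0, config.turn_sigma)
            pts.append(pts[-1] + step * np.array([np.sin(heading), np.cos(heading)]))
        pts = np.asarray(pts)
        # exact arc-length rescale: chord-length spline parametrization is
        # affine-invariant, so scaling waypoints scales the curve
        tck = _fit_spline(pts)
        u = np.linspace(0, 1, 600)
        poly = np.column_stack(interpolate.splev(u, tck))
        length = _polyline_arclength(poly)[-1]
        scale = target_len / length
        pts = pts * scale
        poly = poly * scale
        # random placement keeping the dilated midline inside the margin
        pmin, pmax = poly.min(axis=0), poly.max(axis=0)
        off_lo = lo - pmin
        off_hi = hi - pmax
        if (off_hi < off_lo).any():
            continue
        offset = rng.uniform(off_lo, off_hi)
        poly = poly + offset
        pts = pts + offset
        # reject coiling: non-neighbouring midline points closer than a body width
        idx = np.arange(0, 600, 8)
        sub = poly[idx]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
        far = np.abs(idx[:, None] - idx[None, :]) > 80
        if far.any() and (d[far] < 2.2 * width_max).any():
            continue
        texture = {
            part: TextureParams(rng.uniform(*config.texture_amplitude_range),
                                config.texture_spatial_freq[k])
            for k, part in enumerate(PART_NAMES)
        }
        background = BackgroundParams(
            mean=rng.uniform(*config.bg_mean_range),
            lowfreq_amplitude=config.bg_lowfreq_amplitude,
            lowfreq_sigma=config.bg_lowfreq_sigma,
            noise_scale=config.bg_noise_scale,
        )
        f1 = config.part_fractions[0]
        f12 = f1 + config.part_fractions[1]
        return WormSpec(
            midline_control_points=pts,
            width_max=width_max,
            width_taper_head=config.width_taper_head,
            width_taper_tail=config.width_taper_tail,
            body_intensity=rng.uniform(*config.body_intensity_range),
            part_intensity_offsets=tuple(config.part_intensity_offsets),
            shading_amplitude=config.shading_amplitude,
            pharynx_contrast=config.pharynx_contrast,
            pharynx_band=(config.pharynx_start, f1),
            vulva_contrast=config.vulva_contrast,
            vulva_band=(f12 - config.vulva_extent, f12),
            texture_params=texture,
            background_params=background,
            part_fractions=tuple(config.part_fractions),
        )
    raise ConfigurationError(
        f"could not place a worm of arc length in {config.arc_length_range} "
        f"inside a {canvas_size} px canvas with margin {config.margin} "
        f"after {config.max_retries} attempts")


def partition_midline(midline, part_fractions):
    """Split a polyline at cumulative arc-length fractions f1 and f1 + f2.

    Cut points are interpolated and included in the neighbouring segments, so
    concatenating the three segments reproduces the midline.
    """
    poly = np.asarray(midline, dtype=float)
    if len(poly) < 2:
        raise ValueError("midline needs at least 2 points")
    cum = _polyline_arclength(poly)
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length midline")
    f = np.asarray(part_fractions, dtype=float)
    if f.shape != (3,) or (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid part fractions: {f}")
    cuts = [f[0] * total, (f[0] + f[1]) * total]
    segments = []
    start_pt, start_len, i0 = poly[0], 0.0, 0
    for cut in cuts:
        j = int(np.searchsorted(cum, cut))
        t = (cut - cum[j - 1]) / (cum[j] - cum[j - 1])
        cut_pt = poly[j - 1] + t * (poly[j] - poly[j - 1])
        seg = np.vstack([start_pt[None], poly[i0 + 1 : j], cut_pt[None]])
        segments.append(seg)
        start_pt, i0 = cut_pt, j - 1
    segments.append(np.vstack([start_pt[None], poly[i0 + 1 :]]))
    return segments


def render_worm(spec: WormSpec, canvas_size: int = 96,
                rng_seed: int = 0) -> SyntheticWorm:
    """Rasterize a spec into an image and its exact part masks.

    Each pixel takes the arc-length fraction of its nearest midline point;
    it belongs to the worm when its distance is within the local half-width
    and to the part owning that fraction (ties toward anterior).  The image
    is a textured background with the darker, shaded, per-part-textured worm
    body composited on top.
    """
    rng = np.random.default_rng(rng_seed)
    poly = midline_polyline(spec)
    cum = _polyline_arclength(poly)
    frac = cum / cum[-1]
    rr, cc = np.meshgrid(np.arange(canvas_size), np.arange(canvas_size),
                         indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float32)
    pts = poly.astype(np.float32)
    d2 = ((pix[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(pix)), nearest]).reshape(canvas_size, canvas_size)
    sfrac = frac[nearest].reshape(canvas_size, canvas_size)
    halfw = spec.width_profile(sfrac)
    inside = dist <= halfw
    f1, f2, _ = spec.part_fractions
    anterior = inside & (sfrac <= f1)
    mid = inside & (sfrac > f1) & (sfrac <= f1 + f2)
    posterior = inside & (sfrac > f1 + f2)
    masks = PartMaskSet(anterior=anterior, mid=mid, posterior=posterior,
                        whole=inside)

    bg = spec.background_params
    field = ndimage.gaussian_filter(
        rng.standard_normal((canvas_size, canvas_size)), bg.lowfreq_sigma)
    field /= max(field.std(), 1e-12)
    image = bg.mean + bg.lowfreq_amplitude * field
    image = image + bg.noise_scale * rng.standard_normal(image.shape)

    # body: radial shading (darkest at the midline) plus per-part texture
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(halfw > 0, dist / np.maximum(halfw, 1e-9), 1.0)
    base = spec.body_intensity + (
        spec.part_intensity_offsets[0] * anterior
        + spec.part_intensity_offsets[1] * mid
        + spec.part_intensity_offsets[2] * posterior)
    body = base - spec.shading_amplitude * (1.0 - rel ** 2)
    # anatomical landmarks: dark pharynx corridor ending at the
    # anterior/mid boundary, bright vulva-like marker at the mid/posterior
    # boundary
    lo_s, hi_s = spec.pharynx_band
    pharynx = ((sfrac >= lo_s) & (sfrac <= hi_s)
               & (dist <= 0.85 * np.maximum(halfw, 1e-9)))
    body = body - spec.pharynx_contrast * pharynx
    lo_v, hi_v = spec.vulva_band
    vulva = ((sfrac >= lo_v) & (sfrac <= hi_v)
             & (dist <= 0.9 * np.maximum(halfw, 1e-9)))
    body = body + spec.vulva_contrast * vulva
    image = np.where(inside, body, image)
    for part in PART_NAMES:
        tp = spec.texture_params[part]
        tex = ndimage.gaussian_filter(
            rng.standard_normal((canvas_size, canvas_size)), tp.sigma)
        tex /= max(tex.std(), 1e-12)
        part_mask = getattr(masks, part)
        image = np.where(part_mask, image + tp.amplitude * tex, image)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    record = WormRecord(worm_id="", adult_day=1, lifespan_days=0.0,
                        total_distance=0.0)
    return SyntheticWorm(image=image, masks=masks, record=record, spec=spec,
                         seed=int(rng_seed))


def plant_class_feature(spec: WormSpec, class_label, target_part: str,
                        effect_size: float) -> WormSpec:
    """Shift the texture amplitude of ``target_part`` for positive-class worms.

    Negative-class specs are returned unchanged; the effect never touches the
    other parts or the background, so any classifier signal is localized in
    the target part by construction.
    """
    if target_part not in PART_NAMES:
        raise ValueError(f"unknown part {target_part!r}; expected one of {PART_NAMES}")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not class_label:
        return spec
    texture = dict(spec.texture_params)
    old = texture[target_part]
    texture[target_part] = TextureParams(old.amplitude + effect_size,
                                         old.spatial_freq)
    return dataclasses.replace(spec, texture_params=texture)


class SyntheticDataset:
    """A generated cohort: worms plus the metadata table."""

    def __init__(self, worms, config: GeneratorConfig, master_seed: int):
        self.worms = list(worms)
        self.config = config
        self.master_seed = master_seed
        ids = [w.record.worm_id for w in self.worms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate worm_id in generated dataset")

    def __len__(self):
        return len(self.worms)

    def __iter__(self):
        return iter(self.worms)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "worm_id": w.record.worm_id,
                "adult_day": w.record.adult_day,
                "lifespan_days": w.record.lifespan_days,
                "total_distance": w.record.total_distance,
                "planted_part": w.record.planted_part,
                "seed": w.seed,
            }
            for w in self.worms
        ]
        return pd.DataFrame(rows)

    def images(self) -> np.ndarray:
        return np.stack([w.image for w in self.worms])

    def mask_stack(self, heads=("anterior", "mid", "posterior", "whole")):
        """(N, H, W, n_heads) float32 ground-truth mask tensor."""
        return np.stack(
            [np.stack([getattr(w.masks, h) for h in heads], axis=-1)
             for w in self.worms]).astype(np.float32)

    def planted_labels(self) -> np.ndarray:
        """1 where the class feature was planted, else 0."""
        return np.array(
            [0 if w.record.planted_part == "none" else 1 for w in self.worms])

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for w in self.worms:
            stem = w.record.worm_id
            iio.imwrite(directory / f"{stem}_image.png",
                        np.round(w.image * 65535).astype(np.uint16))
            write_mask_set(w.masks, directory, stem)
        self.table.to_csv(directory / "metadata.csv", index=False)


def generate_dataset(n_worms: int, config: GeneratorConfig | None = None,
                     master_seed: int = 0) -> SyntheticDataset:
    """Generate a cohort; (master_seed, config) determine every pixel.

    Per-worm seeds derive from ``master_seed`` via a seed sequence.  When
    ``config.planted_part`` is set, class labels are balanced exactly 50/50
    and the positive class receives the planted texture feature; the labels
    are coupled to the metadata per ``config.couple_to`` so that the
    lifespan / movement classes recover them ('lifespan': positive worms are
    short-lived; 'movement': positive worms crawl farther than the mean;
    'label': metadata independent of the class).
    """
    config = config or GeneratorConfig()
    if n_worms < 2:
        raise ValueError("n_worms must be >= 2")
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_worms + 1,
                                                               dtype=np.uint32)
    meta_rng = np.random.default_rng(seeds[-1])
    if config.planted_part is not None:
        labels = meta_rng.permutation(np.arange(n_worms) < (n_worms + 1) // 2)
        labels = labels.astype(int)
    else:
        labels = np.zeros(n_worms, dtype=int)
    lo_l, hi_l = config.lifespan_range
    lo_d, hi_d = config.distance_range
    worms = []
    for i in range(n_worms):
        planted = config.planted_part is not None and labels[i] == 1
        lifespan = meta_rng.uniform(lo_l, hi_l)
        distance = meta_rng.uniform(lo_d, hi_d)
        if config.planted_part is not None and config.couple_to == "lifespan":
            lifespan = (meta_rng.uniform(lo_l, min(7.4, hi_l)) if labels[i]
                        else meta_rng.uniform(8.0, hi_l))
        elif config.planted_part is not None and config.couple_to == "movement":
            mid_d = 0.5 * (lo_d + hi_d)
            distance = (meta_rng.uniform(0.55 * (lo_d + hi_d), hi_d) if labels[i]
                        else meta_rng.uniform(lo_d, 0.45 * (lo_d + hi_d)))
        spec = sample_worm_spec(int(seeds[2 * i]), config.canvas_size, config)
        if config.planted_part is not None:
            spec = plant_class_feature(spec, labels[i], config.planted_part,
                                       config.effect_size)
        worm = render_worm(spec, config.canvas_size, int(seeds[2 * i + 1]))
        worm.record = WormRecord(
            worm_id=f"w{i:04d}",
            adult_day=int(meta_rng.choice(config.adult_day_choices)),
            lifespan_days=float(lifespan),
            total_distance=float(distance),
            planted_part=config.planted_part if planted else "none",
        )
        worms.append(worm)
    return SyntheticDataset(worms, config, master_seed)
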