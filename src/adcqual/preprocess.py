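"""Deterministic image preparation and training-time augmentation.

Pipeline for each visit/modality: select the centred consecutive slices,
apply CLAHE per slice, center-crop, cut the three overlapping anatomical
region windows (bladder / prostate / rectum) and resize each to the network
input size. All steps except :func:`augment` are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

log = logging.getLogger(__name__)

REGIONS = ("bladder", "prostate", "rectum")


@dataclass
class PreprocessConfig:
    slices: int = 14
    clahe_clip_limit: float = 2.0  # OpenCV-count convention (see clahe())
    clahe_tiles: tuple = (8, 8)
    crop_px: int = 164
    net_input_px: int = 299
    bladder_row_fraction: float = 0.55
    rectum_row_fraction: float = 0.55
    prostate_fraction: float = 0.50

    def __post_init__(self):
        if not (0 < self.prostate_fraction <= 1):
            raise ValueError("prostate_fraction must lie in (0, 1]")
        for f in (self.bladder_row_fraction, self.rectum_row_fraction):
            if not (0 < f <= 1):
                raise ValueError("region row fractions must lie in (0, 1]")


@dataclass
class RegionCrop:
    region: str
    image: np.ndarray
    patient_id: str | None = None
    site_id: str | None = None
    modality: str | None = None
    slice_index: int | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")


def select_slices(stack: np.ndarray, n: int) -> np.ndarray:
    """The ``n`` consecutive slices centred on the stack middle.

    Slice index is taken to increase toward the inferior end; for odd
    remainders the extra retained slice is on the inferior side. Stacks
    shorter than ``n`` are returned whole with a warning.
    """
    if len(stack) == 0:
        raise ValueError("empty slice stack")
    total = len(stack)
    if n < 1:
        raise ValueError("n must be >= 1")
    if total <= n:
        if total < n:
            log.warning("stack has %d < %d slices; returning all", total, n)
        return stack
    start = (total - n + 1) // 2
    return stack[start : start + n]


def clahe(image: np.ndarray, clip_limit: float = 2.0, tiles=(8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit
    quantized copy of the image, returned in [0, 1].

    ``clip_limit`` follows the histogram-count convention (a limit of 2.0
    means clipping at twice the uniform bin height); it is converted to the
    normalized convention of the underlying implementation.
    """
    img = np.asarray(image, np.float64)
    if img.ndim != 2:
        raise ValueError("clahe expects a 2-D image")
    th, tw = tiles
    if img.shape[0] < th or img.shape[1] < tw:
        raise ValueError("image smaller than the tile grid")
    if img.max() > img.min():
        q = np.round(np.clip(img, 0, 1) * 255.0) / 255.0
    else:
        return np.full_like(img, float(np.clip(img.flat[0], 0, 1)))
    nbins = 256
    kernel = (max(img.shape[0] // th, 1), max(img.shape[1] // tw, 1))
    out = exposure.equalize_adapthist(
        q, kernel_size=kernel, clip_limit=clip_limit / nbins, nbins=nbins
    )
    return np.clip(out, 0.0, 1.0)


def crop_resize(image: np.ndarray, crop: int = 164, out: int = 299) -> np.ndarray:
    """Central ``crop`` x ``crop`` window, bilinearly resized to ``out``."""
    h, w = image.shape
    if h < crop or w < crop:
        raise ValueError(f"image {image.shape} smaller than crop {crop}")
    r0 = (h - crop) // 2
    c0 = (w - crop) // 2
    win = image[r0 : r0 + crop, c0 : c0 + crop]
    if crop == out:
        return win.astype(np.float64)
    return transform.resize(win, (out, out), order=1, mode="edge",
                            anti_aliasing=crop > out, preserve_range=True)


def region_windows(n: int, config: PreprocessConfig | None = None) -> dict:
    """Half-open (row0, row1, col0, col1) windows for the three regions of
    an n x n image."""
    cfg = config or PreprocessConfig()
    nb = int(round(cfg.bladder_row_fraction * n))
    nr = int(round(cfg.rectum_row_fraction * n))
    np_ = int(round(cfg.prostate_fraction * n))
    p0 = int(np.floor((1 - cfg.prostate_fraction) / 2 * n))
    return {
        "bladder": (0, nb, 0, n),
        "rectum": (n - nr, n, 0, n),
        "prostate": (p0, p0 + np_, p0, p0 + np_),
    }


def extract_regions(image: np.ndarray, config: PreprocessConfig | None = None,
                    out_px: int | None = None, **ids) -> list[RegionCrop]:
    """Cut the three overlapping anatomical windows and resize each to the
    network input size."""
    cfg = config or PreprocessConfig()
    h, w = image.shape
    if h != w:
        raise ValueError("extract_regions expects a square image")
    out = out_px or cfg.net_input_px
    crops = []
    for region, (r0, r1, c0, c1) in region_windows(h, cfg).items():
        win = image[r0:r1, c0:c1]
        res = transform.resize(win, (out, out), order=1, mode="edge",
                               anti_aliasing=min(win.shape) > out,
                               preserve_range=True)
        crops.append(RegionCrop(region=region, image=np.clip(res, 0, 1), **ids))
    return crops


@dataclass
class AugmentConfig:
    p_flip: float = 0.5
    max_rotation_deg: float = 10.0
    contrast_range: tuple = (0.8, 1.2)
    brightness_range: tuple = (-0.1, 0.1)
    p_cutout: float = 0.90
    cutout_fraction: float = 0.25


def augment(image: np.ndarray, rng: np.random.Generator | int,
            config: AugmentConfig | None = None) -> np.ndarray:
    """Stochastic training-time augmentation of one image.

    Horizontal flip (p=0.5), rotation uniform in +-max_rotation_deg,
    multiplicative contrast and additive brightness jitter, and with
    probability ``p_cutout`` one square cutout (side = cutout_fraction of
    the image) filled with the image mean. Deterministic under a fixed rng.
    """
    cfg = config or AugmentConfig()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = np.asarray(image, np.float64).copy()
    if rng.random() < cfg.p_flip:
        out = out[:, ::-1].copy()
    if cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    gain = rng.uniform(*cfg.contrast_range)
    bias = rng.uniform(*cfg.brightness_range)
    out = out * gain + bias
    if rng.random() < cfg.p_cutout:
        h, w = out.shape
        side = max(int(round(cfg.cutout_fraction * h)), 1)
        r = rng.integers(0, h - side + 1)
        c = rng.integers(0, w - side + 1)
        out[r : r + side, c : c + side] = out.mean()
    return np.clip(out, 0.0, 1.0)


def augment_batch(batch: np.ndarray, rng: np.random.Generator,
                  config: AugmentConfig | None = None) -> np.ndarray:
    """Vectorized augmentation of a (N, H, W) batch.

    Applies the same family of transforms as :func:`augment` minus rotation
    (flip, contrast/brightness jitter, cutout); used in the inner training
    loop where per-image resampling would dominate the runtime.
    """
    cfg = config or AugmentConfig()
    x = np.array(batch, np.float32)
    n, h, w = x.shape
    flip = rng.random(n) < cfg.p_flip
    x[flip] = x[flip, :, ::-1]
    gain = rng.uniform(*cfg.contrast_range, size=(n, 1, 1)).astype(np.float32)
    bias = rng.uniform(*cfg.brightness_range, size=(n, 1, 1)).astype(np.float32)
    x = x * gain + bias
    do_cut = rng.random(n) < cfg.p_cutout
    side = max(int(round(cfg.cutout_fraction * h)), 1)
    rs = rng.integers(0, h - side + 1, size=n)
    cs = rng.integers(0, w - side + 1, size=n)
    means = x.mean(axis=(1, 2))
    for i in np.flatnonzero(do_cut):
        x[i, rs[i] : rs[i] + side, cs[i] : cs[i] + side] = means[i]
    return np.clip(x, 0.0, 1.0)


def prepare_stack(stack: np.ndarray, config: PreprocessConfig,
                  out_px: int | None = None) -> dict:
    """Full deterministic pipeline for one slice stack.

    Returns {region: (n_slices, out_px, out_px) float32 arrays}.
    """
    sel = select_slices(stack, config.slices)
    out = out_px or config.net_input_px
    crop = min(config.crop_px, sel.shape[1])
    per_region = {r: [] for r in REGIONS}
    for sl in sel:
        eq = clahe(sl, config.clahe_clip_limit, config.clahe_tiles)
        cr = crop_resize(eq, crop, crop)  # crop only; regions are resized below
        for rc in extract_regions(cr, config, out_px=out):
            per_region[rc.region].append(rc.image)
    return {r: np.asarray(v, np.float32) for r, v in per_region.items()}
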