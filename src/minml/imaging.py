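"""Grayscale CT enhancement and hemorrhage segmentation chain.

The pipeline turns an 8-bit head slice into an enhanced, hemorrhage-
highlighted image and a flattened pattern vector:

1. CLAHE — tile-wise contrast-limited histogram equalization;
2. noise filtering — 9x9 median by default (a mean filter is also
   provided), replicate padding at the borders;
3. skull removal — intensities strictly above the bone threshold ``alpha``
   are zeroed, soft tissue is kept;
4. hemorrhage band segmentation — pixels inside the closed intensity band
   ``[alpha1, alpha2]`` become foreground (255), everything else 0 — then
   a morphological opening (erosion followed by dilation, 3x3 square
   structuring element) removes speckle;
5. superimposition — the mask is burnt into the skull-removed image as
   pure white, preserving the grayscale elsewhere;
6. flattening — row-major concatenation into a 1 x (rows*cols) pattern.

All images are plain ``numpy`` ``uint8`` arrays; binary masks use the two
values {0, 255}.  The band thresholds are dataset properties; the
supported calibration (averaging region intensities over a small
calibration subset) is available as :func:`estimate_alpha`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "ClaheConfig",
    "NoiseFilterConfig",
    "PreprocessConfig",
    "PipelineResult",
    "full_square",
    "clahe_enhance",
    "mean_filter",
    "median_filter",
    "remove_skull",
    "segment_hemorrhage",
    "erode",
    "dilate",
    "superimpose",
    "flatten",
    "unflatten",
    "estimate_alpha",
    "preprocess_pipeline",
]


# ---------------------------------------------------------------------------
# validation helpers

def _as_gray(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    if arr.size == 0:
        raise ValueError("image must be non-empty")
    a = arr.astype(float)
    if not np.all(np.isfinite(a)) or a.min() < 0 or a.max() > 255 or np.any(a != np.round(a)):
        raise ValueError("intensities must be integers in [0, 255]")
    return arr.astype(np.uint8)


def _as_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("binary mask must be 2-D")
    vals = np.unique(arr)
    if not set(vals.tolist()) <= {0, 255}:
        raise ValueError("binary mask may only contain the values 0 and 255")
    return arr.astype(np.uint8)


def _as_se(se) -> np.ndarray:
    arr = np.asarray(se).astype(bool)
    if arr.ndim != 2:
        raise ValueError("structuring element must be 2-D")
    if arr.shape[0] % 2 == 0 or arr.shape[1] % 2 == 0:
        raise ValueError("structuring element dimensions must be odd")
    if not arr[arr.shape[0] // 2, arr.shape[1] // 2]:
        raise ValueError("structuring element origin (center cell) must be set")
    return arr


def full_square(size: int = 3) -> np.ndarray:
    """A full ``size x size`` structuring element (odd ``size``)."""
    if size % 2 == 0 or size < 1:
        raise ValueError("structuring element size must be odd and >= 1")
    return np.ones((size, size), dtype=bool)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ClaheConfig:
    """Tile grid, clip limit and redistribution mode for CLAHE."""

    tile_grid: tuple = (8, 8)  # (rows, cols) of tiles
    clip_limit: float = 0.01
    distribution: str = "uniform"  # rayleigh not supported by the backend
    enabled: bool = True


@dataclass
class NoiseFilterConfig:
    kind: str = "median"  # or "mean"
    size: int = 9

    def __post_init__(self):
        if self.kind not in ("median", "mean"):
            raise ValueError("noise filter kind must be 'median' or 'mean'")
        if self.size % 2 == 0 or self.size < 3:
            raise ValueError("noise filter window must be odd and >= 3")


@dataclass
class PreprocessConfig:
    """Thresholds and options of the enhancement/segmentation chain.

    ``alpha`` is the skull (bone) threshold; ``alpha1 <= alpha2`` bound the
    hemorrhage intensity band.  The numeric defaults are placeholders —
    the thresholds are dataset properties and should be calibrated (see
    :func:`estimate_alpha`).
    """

    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    noise_filter: NoiseFilterConfig = field(default_factory=NoiseFilterConfig)
    alpha: float = 200.0
    alpha1: float = 130.0
    alpha2: float = 200.0
    se_size: int = 3
    morphology: str = "opening"  # "opening" (erode->dilate), "closing", "none"
    filter_before_skull_removal: bool = True

    def __post_init__(self):
        if isinstance(self.clahe, dict):
            self.clahe = ClaheConfig(**{**self.clahe, "tile_grid": tuple(self.clahe.get("tile_grid", (8, 8)))})
        if isinstance(self.noise_filter, dict):
            self.noise_filter = NoiseFilterConfig(**self.noise_filter)
        for name in ("alpha", "alpha1", "alpha2"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.alpha1 > self.alpha2:
            raise ValueError("alpha1 must not exceed alpha2")
        if self.se_size % 2 == 0 or self.se_size < 1:
            raise ValueError("se_size must be odd and >= 1")
        if self.morphology not in ("opening", "closing", "none"):
            raise ValueError("morphology must be 'opening', 'closing' or 'none'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clahe"]["tile_grid"] = list(self.clahe.tile_grid)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "PreprocessConfig":
        return cls(**payload)

    @classmethod
    def load(cls, path) -> "PreprocessConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# enhancement

def clahe_enhance(img, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tiles of the image ("mosaics") are equalized with a clipped histogram
    and blended by bilinear interpolation (delegated to
    ``skimage.exposure.equalize_adapthist``).  Output stays in [0, 255].
    """
    img = _as_gray(img)
    cfg = cfg or ClaheConfig()
    if cfg.distribution != "uniform":
        raise ValueError(
            "only the 'uniform' redistribution is supported by this backend"
        )
    rows, cols = cfg.tile_grid
    h, w = img.shape
    if rows < 1 or cols < 1 or rows > h or cols > w:
        raise ValueError(f"tile grid {rows}x{cols} does not fit a {h}x{w} image")
    if img.min() == img.max():
        return img.copy()  # constant image: nothing to equalize
    kernel = (max(1, int(np.ceil(h / rows))), max(1, int(np.ceil(w / cols))))
    out = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=cfg.clip_limit)
    return _round_half_up(out * 255.0)


def mean_filter(img, size: int = 3) -> np.ndarray:
    """Sliding-window arithmetic-mean filter, replicate border padding.

    Each pixel becomes the rounded (half-up) average of its ``size x size``
    neighborhood.
    """
    img = _as_gray(img)
    if size % 2 == 0 or size < 3:
        raise ValueError("window size must be odd and >= 3")
    acc = ndimage.correlate(img.astype(float), np.ones((size, size)) / size**2, mode="nearest")
    return _round_half_up(acc)


def median_filter(img, size: int = 9) -> np.ndarray:
    """Sliding-window median filter, replicate border padding."""
    img = _as_gray(img)
    if size % 2 == 0 or size < 3:
        raise ValueError("window size must be odd and >= 3")
    return ndimage.median_filter(img, size=size, mode="nearest").astype(np.uint8)


def remove_skull(img, alpha: float) -> np.ndarray:
    """Zero every pixel strictly above ``alpha`` (bone), keep the rest."""
    img = _as_gray(img)
    if not 0 <= alpha <= 255:
        raise ValueError("alpha must lie in [0, 255]")
    out = img.copy()
    out[img > alpha] = 0
    return out


def segment_hemorrhage(img, alpha1: float, alpha2: float) -> np.ndarray:
    """Binary mask of the closed intensity band ``[alpha1, alpha2]``."""
    img = _as_gray(img)
    if not (0 <= alpha1 <= 255 and 0 <= alpha2 <= 255):
        raise ValueError("band limits must lie in [0, 255]")
    if alpha1 > alpha2:
        raise ValueError("alpha1 must not exceed alpha2")
    mask = (img >= alpha1) & (img <= alpha2)
    return (mask.astype(np.uint8)) * 255


# ---------------------------------------------------------------------------
# binary morphology (set definitions, zero padding outside the raster)

def _shift(a: np.ndarray, dr: int, dc: int, pad: bool) -> np.ndarray:
    """Translate a boolean raster by (dr, dc), filling exposed cells with
    ``pad`` (background False by default)."""
    out = np.full_like(a, pad)
    h, w = a.shape
    rs = slice(max(dr, 0), min(h, h + dr))
    cs = slice(max(dc, 0), min(w, w + dc))
    rs_src = slice(max(-dr, 0), min(h, h - dr))
    cs_src = slice(max(-dc, 0), min(w, w - dc))
    out[rs, cs] = a[rs_src, cs_src]
    return out


def _se_offsets(se: np.ndarray) -> list[tuple[int, int]]:
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    return [(r - cy, c - cx) for r, c in zip(*np.nonzero(se))]


def erode(mask, se, *, pad: int = 0) -> np.ndarray:
    """Binary erosion: a pixel survives iff the structuring element,
    translated there, fits entirely inside the foreground.

    Cells outside the raster count as ``pad`` (default background 0;
    ``pad=255`` treats the outside as foreground, which is what makes the
    erosion/dilation duality exact on a finite raster).
    """
    a = _as_mask(mask) > 0
    se = _as_se(se)
    pad_bool = bool(pad)
    out = np.ones_like(a)
    for dr, dc in _se_offsets(se):
        # z + (dr, dc) must be foreground for every SE cell
        out &= _shift(a, -dr, -dc, pad_bool)
    return out.astype(np.uint8) * 255


def dilate(mask, se) -> np.ndarray:
    """Binary dilation: a pixel is set iff the reflected structuring
    element translated there intersects the foreground (equivalently, the
    union of the foreground translated by every SE offset)."""
    a = _as_mask(mask) > 0
    se = _as_se(se)
    out = np.zeros_like(a)
    for dr, dc in _se_offsets(se):
        out |= _shift(a, dr, dc, False)
    return out.astype(np.uint8) * 255


def superimpose(base, mask) -> np.ndarray:
    """Burn the mask into the grayscale base: 255 where the mask is
    foreground, the base intensity elsewhere."""
    base = _as_gray(base)
    mask = _as_mask(mask)
    if base.shape != mask.shape:
        raise ValueError("base image and mask must have the same shape")
    out = base.copy()
    out[mask == 255] = 255
    return out


def flatten(img) -> np.ndarray:
    """Row-major flattening to a length rows*cols pattern vector."""
    return _as_gray(img).reshape(-1)


def unflatten(vec, shape) -> np.ndarray:
    """Inverse of :func:`flatten` given the original shape."""
    return np.asarray(vec).reshape(shape).astype(np.uint8)


def estimate_alpha(images: Sequence, masks: Sequence | None = None) -> float:
    """Average of per-image mean intensities over a calibration set.

    With ``masks`` given (one boolean/0-255 region per image), only pixels
    inside each region contribute — this is how the band limits are
    derived from annotated regions of a reduced group of images.
    """
    images = list(images)
    if not images:
        raise ValueError("calibration set must be non-empty")
    per_image = []
    if masks is None:
        for img in images:
            per_image.append(_as_gray(img).mean())
    else:
        masks = list(masks)
        if len(masks) != len(images):
            raise ValueError("one region mask per image is required")
        for img, msk in zip(images, masks):
            img = _as_gray(img)
            sel = np.asarray(msk) > 0
            if sel.shape != img.shape or not sel.any():
                raise ValueError("each region mask must be non-empty and match its image")
            per_image.append(img[sel].mean())
    return float(np.mean(per_image))


# ---------------------------------------------------------------------------
# the full chain

@dataclass(frozen=True)
class PipelineResult:
    """All intermediates of the preprocessing chain, for inspection."""

    enhanced: np.ndarray       # after CLAHE
    denoised: np.ndarray       # after the noise filter
    skull_removed: np.ndarray  # after bone thresholding
    raw_mask: np.ndarray       # band segmentation before morphology
    mask: np.ndarray           # after morphology
    superimposed: np.ndarray   # highlighted grayscale image
    pattern: np.ndarray        # flattened superimposed image

    def stages(self) -> dict:
        return {
            "enhanced": self.enhanced,
            "denoised": self.denoised,
            "skull_removed": self.skull_removed,
            "raw_mask": self.raw_mask,
            "mask": self.mask,
            "superimposed": self.superimposed,
        }


def preprocess_pipeline(img, cfg: PreprocessConfig | None = None) -> PipelineResult:
    """Run the full enhancement/segmentation chain on one image.

    Deterministic: the same image and configuration always produce
    bit-identical outputs.
    """
    cfg = cfg or PreprocessConfig()
    img = _as_gray(img)

    enhanced = clahe_enhance(img, cfg.clahe) if cfg.clahe.enabled else img.copy()

    def denoise(x):
        if cfg.noise_filter.kind == "median":
            return median_filter(x, cfg.noise_filter.size)
        return mean_filter(x, cfg.noise_filter.size)

    if cfg.filter_before_skull_removal:
        denoised = denoise(enhanced)
        skull_removed = remove_skull(denoised, cfg.alpha)
    else:
        skull_removed = denoise(remove_skull(enhanced, cfg.alpha))
        denoised = skull_removed

    raw_mask = segment_hemorrhage(skull_removed, cfg.alpha1, cfg.alpha2)
    se = full_square(cfg.se_size)
    if cfg.morphology == "opening":
        mask = dilate(erode(raw_mask, se), se)
    elif cfg.morphology == "closing":
        mask = erode(dilate(raw_mask, se), se)
    else:
        mask = raw_mask
    superimposed = superimpose(skull_removed, mask)
    return PipelineResult(
        enhanced=enhanced,
        denoised=denoised,
        skull_removed=skull_removed,
        raw_mask=raw_mask,
        mask=mask,
        superimposed=superimposed,
        pattern=flatten(superimposed),
    )
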