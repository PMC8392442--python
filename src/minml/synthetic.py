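"""Seeded generators for two-class feature tables and head phantoms.

These generators make every stage of the package testable without any
external download, and they always return the planted ground truth
(informative attribute positions, hemorrhage blob masks) so that tests
measure *recovery*, not resemblance to real data.

``make_table`` emulates microarray-style inputs: Gaussian class-
conditional noise with a mean shift ``delta`` planted on a chosen number
of informative attributes.

``make_phantom`` emulates an 8-bit axial head CT slice at desk scale: a
dark background, a bright elliptical skull ring in the bone intensity
band, mid-gray brain tissue inside it, an optional brighter elliptical
hemorrhage blob, and additive Gaussian noise.  The tissue intensity bands
are non-overlapping by default so each preprocessing stage has a clean
oracle; they do not model Hounsfield calibration, partial-volume effects
or anatomical texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .dmeans import FeatureDataset

__all__ = [
    "TableSpec",
    "PhantomSpec",
    "make_table",
    "make_phantom",
    "phantom_region_masks",
    "make_image_dataset",
]


@dataclass(frozen=True)
class TableSpec:
    """Two-class Gaussian table with a planted class-mean shift.

    ``m_per_class`` patterns per class, ``n`` attributes of which
    ``n_informative`` carry a mean shift of ``delta`` in class C2;
    i.i.d. Gaussian noise of scale ``sigma`` everywhere.
    """

    m_per_class: int = 20
    n: int = 100
    n_informative: int = 5
    delta: float = 5.0
    sigma: float = 1.0
    labels: tuple = ("C1", "C2")
    seed: int = 0

    def __post_init__(self):
        if self.m_per_class < 2:
            raise ValueError("need at least 2 patterns per class")
        if not 0 <= self.n_informative <= self.n:
            raise ValueError("n_informative must lie in [0, n]")
        if self.n < 2:
            raise ValueError("need at least 2 attributes")
        if self.sigma < 0:
            raise ValueError("noise scale must be non-negative")
        if len(set(self.labels)) != 2:
            raise ValueError("two distinct class labels required")


def make_table(spec: TableSpec) -> tuple[FeatureDataset, np.ndarray]:
    """Generate a table plus the 1-based informative attribute positions.

    The smaller label's class sits at baseline mean 0; the larger label's
    class is shifted by ``delta`` on the informative attributes only.
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    informative = np.sort(rng.choice(spec.n, size=spec.n_informative, replace=False)) + 1
    m = spec.m_per_class
    X = rng.normal(0.0, spec.sigma or 1e-12, size=(2 * m, spec.n))
    if spec.sigma == 0:
        X[:] = 0.0
    lo, hi = sorted(spec.labels, key=str)
    X[m:, informative - 1] += spec.delta  # second block = larger label = C2
    labels = np.array([lo] * m + [hi] * m, dtype=object)
    return FeatureDataset(X, labels), informative


# ---------------------------------------------------------------------------
# phantoms

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity bands and noise of a synthetic head slice.

    Intensities are drawn per-pixel uniformly from the closed integer
    range of each tissue band, then perturbed by Gaussian noise of scale
    ``noise_sigma`` and clamped to [0, 255].  The skull is the elliptical
    ring between the outer and inner axes fractions; the brain fills the
    interior.  The optional hemorrhage blob must fit inside the brain.
    """

    shape: tuple = (128, 128)
    skull_range: tuple = (230, 255)
    brain_range: tuple = (80, 120)
    blob: bool = True
    blob_center: tuple | None = None  # (row, col); default: slightly off-center
    blob_radii: tuple = (10, 8)
    blob_range: tuple = (150, 200)
    background: int = 0
    noise_sigma: float = 2.0
    outer_frac: float = 0.46
    inner_frac: float = 0.38
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.skull_range, self.brain_range, self.blob_range):
            lo, hi = rng_
            if not (0 <= lo <= hi <= 255):
                raise ValueError("intensity ranges must satisfy 0 <= lo <= hi <= 255")
        if not 0 <= self.background <= 255:
            raise ValueError("background intensity must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise scale must be non-negative")
        if not 0 < self.inner_frac < self.outer_frac <= 0.5:
            raise ValueError("need 0 < inner_frac < outer_frac <= 0.5")


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    ry, rx = radii
    return ((rr - center[0]) / ry) ** 2 + ((cc - center[1]) / rx) ** 2 <= 1.0


def phantom_region_masks(spec: PhantomSpec) -> dict:
    """Boolean region masks (skull ring, brain interior, blob) of a spec."""
    h, w = spec.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    outer = _ellipse_mask(spec.shape, center, (spec.outer_frac * h, spec.outer_frac * w))
    inner = _ellipse_mask(spec.shape, center, (spec.inner_frac * h, spec.inner_frac * w))
    skull = outer & ~inner
    blob = np.zeros(spec.shape, dtype=bool)
    if spec.blob:
        bc = spec.blob_center
        if bc is None:
            bc = (center[0] - h * 0.08, center[1] + w * 0.05)
        blob = _ellipse_mask(spec.shape, bc, spec.blob_radii)
        if not blob.any():
            raise ValueError("hemorrhage blob is empty")
        if np.any(blob & ~inner):
            raise ValueError("hemorrhage blob must fit inside the brain region")
    return {"skull": skull, "brain": inner, "blob": blob}


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom slice; returns (image uint8, blob mask {0,255})."""
    regions = phantom_region_masks(spec)
    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.shape, float(spec.background))

    def fill(mask, band):
        lo, hi = band
        img[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    fill(regions["brain"], spec.brain_range)
    fill(regions["skull"], spec.skull_range)
    if spec.blob:
        fill(regions["blob"], spec.blob_range)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    blob_mask = regions["blob"].astype(np.uint8) * 255
    return img, blob_mask


def make_image_dataset(
    root,
    n_per_class: tuple = (129, 123),
    template: PhantomSpec | None = None,
    seed: int = 0,
    class_names: tuple = ("IVH", "Normal"),
    jitter_blob: bool = False,
) -> dict:
    """Write a directory tree of labeled phantom PNGs.

    ``<root>/<class_names[0]>/`` receives ``n_per_class[0]`` phantoms with
    a hemorrhage blob and ``<root>/<class_names[1]>/`` receives blob-free
    phantoms.  Images differ by their per-image seed (intensity draws and
    noise field); with ``jitter_blob`` the blob position and radii are
    additionally perturbed per image, a deliberately harder variant.
    Bit-deterministic per seed.  Returns ``{class_name: [paths]}``.
    """
    template = template or PhantomSpec()
    root = Path(root)
    n_ivh, n_normal = n_per_class
    if n_ivh < 1 or n_normal < 1:
        raise ValueError("each class needs at least one image")
    # independent child seeds, kept below 2**31
    child = np.random.SeedSequence(seed).generate_state(2 * (n_ivh + n_normal)) & 0x7FFFFFFF
    jitter_rng = np.random.default_rng(int(child[-1]))

    manifest: dict = {name: [] for name in class_names}
    h, w = template.shape
    idx = 0
    for name, count, with_blob in (
        (class_names[0], n_ivh, True),
        (class_names[1], n_normal, False),
    ):
        class_dir = root / name
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            spec = replace(template, blob=with_blob, seed=int(child[idx]))
            if with_blob and jitter_blob:
                # jitter blob placement within the brain; fall back to the
                # template's default placement if a draw lands outside
                for _ in range(20):
                    dy = jitter_rng.integers(-h // 10, h // 10 + 1)
                    dx = jitter_rng.integers(-w // 10, w // 10 + 1)
                    ry = int(jitter_rng.integers(max(3, template.blob_radii[0] - 2),
                                                 template.blob_radii[0] + 3))
                    rx = int(jitter_rng.integers(max(3, template.blob_radii[1] - 2),
                                                 template.blob_radii[1] + 3))
                    cand = replace(
                        spec,
                        blob_center=((h - 1) / 2.0 + dy, (w - 1) / 2.0 + dx),
                        blob_radii=(ry, rx),
                    )
                    try:
                        phantom_region_masks(cand)
                    except ValueError:
                        continue
                    spec = cand
                    break
            img, _ = make_phantom(spec)
            path = class_dir / f"{name.lower()}_{i:04d}.png"
            Image.fromarray(img, mode="L").save(path)
            manifest[name].append(path)
            idx += 1
    return manifest
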