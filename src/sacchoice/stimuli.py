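"""Luminance and contrast equalization of grayscale stimuli.

All stimuli in the task were normalized to a common mean pixel intensity
(128) and intensity standard deviation (40) on the 0-255 scale. The
operation is the affine per-image map

    out = clip(target_mean + (pixels - mean) * target_sd / sd, 0, 255)

with clipping applied after the transform, so the achieved moments can
deviate slightly from the targets when values saturate; the achieved
moments are reported per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_MEAN = 128.0
DEFAULT_SD = 40.0

# Rec. 601 luma weights for collapsing color inputs to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class StimulusImage:
    """A grayscale stimulus with intensities in [0, 255]."""

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.size == 0:
            raise ValueError("empty image")
        if px.ndim == 3:
            px = to_grayscale(px)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D image, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = px

    @property
    def mean(self) -> float:
        return float(self.pixels.mean())

    @property
    def sd(self) -> float:
        return float(self.pixels.std())


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to single-channel luma."""
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 2:
        return px
    return px[..., :3] @ _LUMA


def lum_match(
    image: StimulusImage | np.ndarray,
    target_mean: float = DEFAULT_MEAN,
    target_sd: float = DEFAULT_SD,
    mask: np.ndarray | None = None,
) -> StimulusImage:
    """Force an image's mean intensity and contrast to target values.

    Parameters
    ----------
    image : StimulusImage or array
        Grayscale input with values in [0, 255].
    target_mean, target_sd : float
        Target mean and standard deviation of pixel intensity.
    mask : bool array, optional
        If given, moments are computed over (and the transform applied
        to) the masked region only; pixels outside are left unchanged.

    Returns
    -------
    StimulusImage
        The equalized image (values clipped to [0, 255]).

    Warns
    -----
    UserWarning
        If the input region has zero variance while ``target_sd > 0``:
        the output is constant at ``target_mean`` and the requested
        contrast is unattainable.
    """
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    img = image if isinstance(image, StimulusImage) else StimulusImage(np.asarray(image))
    px = img.pixels.copy()
    region = px if mask is None else px[mask]
    if region.size == 0:
        raise ValueError("empty image or mask")
    mean, sd = region.mean(), region.std()
    if sd == 0:
        if target_sd > 0:
            warnings.warn(
                f"image {img.id or '<unnamed>'} has zero variance; "
                "returning a constant image, contrast unattainable"
            )
        out = np.full_like(region, float(np.clip(target_mean, 0, 255)))
    else:
        out = np.clip(target_mean + (region - mean) * (target_sd / sd), 0.0, 255.0)
    if mask is None:
        px = out
    else:
        px[mask] = out
    return StimulusImage(px, id=img.id)


def match_set(
    images,
    target_mean: float = DEFAULT_MEAN,
    target_sd: float = DEFAULT_SD,
) -> tuple[list[StimulusImage], "object"]:
    """Apply :func:`lum_match` to every image and report achieved moments.

    Returns the matched images and a DataFrame with per-image achieved
    mean and SD (which can deviate from the targets when clipping
    occurred).
    """
    import pandas as pd

    images = list(images)
    if not images:
        raise ValueError("match_set requires at least one image")
    matched = [lum_match(im, target_mean, target_sd) for im in images]
    report = pd.DataFrame(
        {
            "id": [m.id for m in matched],
            "mean": [m.mean for m in matched],
            "sd": [m.sd for m in matched],
            "target_mean": target_mean,
            "target_sd": target_sd,
        }
    )
    return matched, report


def synthetic_stimulus(
    category: str,
    identity: int,
    orientation: int,
    size: int = 128,
    rng: np.random.Generator | None = None,
) -> StimulusImage:
    """Procedural stand-in stimulus (synthetic; no photographs involved).

    Faces are rendered as smooth oval blobs with eye/mouth spots, objects
    as rectangles, each perturbed deterministically by identity and
    orientation so the set has 3 categories x 3 identities x 3
    orientations of distinct images, mirroring the stimulus set layout.
    """
    rng = rng or np.random.default_rng(abs(hash((category, identity, orientation))) % 2**31)
    yy, xx = np.mgrid[0:size, 0:size]
    cx = size / 2 + (orientation - 2) * size * 0.05
    cy = size / 2
    px = np.full((size, size), 128.0)
    if category == "Object":
        w = size * (0.25 + 0.05 * identity)
        h = size * 0.3
        box = (np.abs(xx - cx) < w) & (np.abs(yy - cy) < h)
        px[box] = 80.0 + 15 * identity
    else:
        r2 = ((xx - cx) / (size * 0.3)) ** 2 + ((yy - cy) / (size * 0.38)) ** 2
        px += (r2 < 1) * (60.0 + 8 * identity) * np.exp(-r2)
        for ex in (-0.12, 0.12):
            d2 = ((xx - cx - ex * size * (1 + 0.1 * orientation)) / (size * 0.05)) ** 2 + (
                (yy - cy + 0.1 * size) / (size * 0.04)
            ) ** 2
            px -= (d2 < 1) * 90.0
    px += rng.normal(0, 6.0, px.shape)
    px = np.clip(px, 0, 255)
    return StimulusImage(px, id=f"{category}_id{identity}_or{orientation}")


def synthetic_stimulus_set(size: int = 128, seed: int = 0) -> list[StimulusImage]:
    """The full 27-image synthetic set (3 categories x 3 ids x 3 views)."""
    from .design import CATEGORIES

    rng = np.random.default_rng(seed)
    return [
        synthetic_stimulus(cat, i, o, size=size, rng=rng)
        for cat in CATEGORIES
        for i in range(1, 4)
        for o in range(1, 4)
    ]


def read_image(path) -> StimulusImage:
    """Read a PNG/PGM grayscale image (color collapsed to luma)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    return StimulusImage(np.asarray(arr, dtype=float), id=str(path))


def write_image(image: StimulusImage, path) -> None:
    """Write as 8-bit grayscale PNG/PGM (values rounded)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.round(image.pixels).astype(np.uint8))
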