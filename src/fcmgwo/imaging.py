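"""Raster-image I/O and the preprocessing chain used before segmentation.

Stained cytology smears are photographed at high magnification; before
clustering, each image is resized to a common working resolution, collapsed
to a single intensity channel, denoised with a median filter, and lightly
closed morphologically so that small bright speckles inside dark nuclei do
not fragment them.  Images are plain ``numpy`` arrays in the scikit-image
convention: ``(H, W)`` uint8 for grayscale, ``(H, W, 3)`` uint8 for RGB.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import morphology, transform

__all__ = [
    "PreprocessSettings",
    "read_image",
    "write_image",
    "resize_image",
    "to_grayscale",
    "median_filter",
    "morphological_closing",
    "preprocess",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessSettings:
    """Configuration of the preprocessing chain.

    Steps run in the fixed order resize -> grayscale -> median -> closing;
    setting a field to ``None`` (or ``False`` for ``grayscale``) skips that
    step.

    Parameters
    ----------
    resize_to
        Target ``(width, height)`` in pixels, default ``(800, 600)``.
    grayscale
        Collapse RGB to a single luminance channel.
    median_size
        Side length of the square median-filter window (odd), default 5.
    closing_radius
        Radius in pixels of the disk structuring element used for grayscale
        closing, default 2 (a 5x5 disk footprint).
    """

    resize_to: tuple[int, int] | None = (800, 600)
    grayscale: bool = True
    median_size: int | None = 5
    closing_radius: int | None = 2


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D image array, got ndim={img.ndim}")
    if img.ndim == 3 and img.shape[2] not in (1, 3):
        raise ValueError(f"expected 1 or 3 channels, got {img.shape[2]}")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a uint8 array.

    An alpha channel, if present, is dropped.  Raises :class:`OSError`
    naming the path when the file is missing or undecodable.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise OSError(f"could not decode image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return _check_image(np.clip(arr, 0, 255).astype(np.uint8))


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a uint8 image to ``path``; the format follows the extension."""
    img = _check_image(img)
    iio.imwrite(Path(path), np.clip(img, 0, 255).astype(np.uint8))


def resize_image(img: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Bilinear resize to exactly ``target_w`` x ``target_h`` pixels."""
    img = _check_image(img)
    if target_w < 1 or target_h < 1:
        raise ValueError(f"resize target must be positive, got {(target_w, target_h)}")
    shape = (target_h, target_w) + img.shape[2:]
    out = transform.resize(
        img.astype(float), shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luminance (BT.601 weights); grayscale passes through."""
    img = _check_image(img)
    if img.ndim == 2:
        return img
    gray = img.astype(float) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_filter(img: np.ndarray, size: int = 5) -> np.ndarray:
    """Median filter with a ``size`` x ``size`` window and reflected borders.

    ``size`` must be odd so the window has a central pixel; ``size=1`` is the
    identity.
    """
    img = _check_image(img)
    if img.ndim != 2:
        raise ValueError("median_filter expects a single-channel image")
    if size < 1 or size % 2 == 0:
        raise ValueError(f"median window size must be odd and >= 1, got {size}")
    return ndimage.median_filter(img, size=size, mode="reflect")


def morphological_closing(img: np.ndarray, selem_radius: int = 2) -> np.ndarray:
    """Grayscale closing (dilation then erosion) with a disk structuring element.

    Closing is extensive (output >= input pointwise) and idempotent; it fills
    dark gaps narrower than the disk, consolidating nucleus interiors.
    """
    img = _check_image(img)
    if img.ndim != 2:
        raise ValueError("morphological_closing expects a single-channel image")
    if selem_radius < 1:
        raise ValueError(f"structuring-element radius must be >= 1, got {selem_radius}")
    return morphology.closing(img, morphology.disk(selem_radius))


def preprocess(img: np.ndarray, cfg: PreprocessSettings | None = None) -> np.ndarray:
    """Apply the configured chain: resize -> grayscale -> median -> closing."""
    if cfg is None:
        cfg = PreprocessSettings()
    out = _check_image(img)
    if cfg.resize_to is not None:
        out = resize_image(out, *cfg.resize_to)
    if cfg.grayscale:
        out = to_grayscale(out)
    if cfg.median_size is not None:
        out = median_filter(out, cfg.median_size)
    if cfg.closing_radius is not None:
        out = morphological_closing(out, cfg.closing_radius)
    return out
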