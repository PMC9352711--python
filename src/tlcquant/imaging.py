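"""Image container, colour handling and resampling.

All pixel data is carried as floating point in [0, 1].  A colorspace tag
distinguishes gamma-encoded (sRGB) from linear-intensity data so that the
inverse electro-optical transfer is applied exactly once: the densitometric
stages require *linear* channel values, while JPEG/PNG files store encoded
ones.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin at the
top-left pixel centre.  This convention is shared by every module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageOps

from .errors import ImagingError

#: colorspace tags
SRGB = "srgb-encoded"
LINEAR = "linear"

#: Rec. 709 / sRGB luminance weights (sum to exactly 1.0)
GRAY_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass
class RasterImage:
    """A 2-D grayscale or 3-plane RGB image in [0, 1].

    Parameters
    ----------
    pixels:
        ``(H, W)`` or ``(H, W, 3)`` array.  Converted to float64 on entry.
    colorspace:
        Either :data:`SRGB` (gamma-encoded, as decoded from a JPEG/PNG) or
        :data:`LINEAR` (linear intensity, ready for densitometry).
    """

    pixels: np.ndarray
    colorspace: str = LINEAR

    def __post_init__(self) -> None:
        self.pixels = np.array(self.pixels, dtype=np.float64)  # owned, writable copy
        if self.pixels.ndim not in (2, 3):
            raise ImagingError(f"expected 2-D or 3-D pixel array, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ImagingError(f"colour images must have 3 planes, got {self.pixels.shape[2]}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImagingError("image must be at least 1x1")
        if not np.all(np.isfinite(self.pixels)):
            raise ImagingError("pixel values must be finite")
        # tolerate tiny floating-point excursions, reject genuine range errors
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ImagingError(f"pixel values outside [0, 1]: min={lo:g} max={hi:g}")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)
        if self.colorspace not in (SRGB, LINEAR):
            raise ImagingError(f"unknown colorspace tag {self.colorspace!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy(), self.colorspace)


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)


def srgb_to_linear(image: RasterImage) -> RasterImage:
    """Invert the sRGB electro-optical transfer, per channel.

    Raises if the image is already linear: a double linearization would
    silently corrupt all downstream intensities.
    """
    if image.colorspace != SRGB:
        raise ImagingError("image is already linear; refusing to linearize twice")
    return RasterImage(_srgb_decode(image.pixels), LINEAR)


def linear_to_srgb(image: RasterImage) -> RasterImage:
    """Apply the forward sRGB transfer (for writing image files)."""
    if image.colorspace != LINEAR:
        raise ImagingError("image is already sRGB-encoded")
    return RasterImage(_srgb_encode(image.pixels), SRGB)


def to_grayscale(image: RasterImage) -> RasterImage:
    """Luminance of a linear RGB image: Y = 0.2126 R + 0.7152 G + 0.0722 B."""
    if not image.is_color:
        raise ImagingError("image is already grayscale")
    if image.colorspace != LINEAR:
        raise ImagingError("grayscale conversion requires linear channels; linearize first")
    w = np.asarray(GRAY_WEIGHTS)
    return RasterImage(image.pixels @ w, LINEAR)


def _block_reduce_mean(a: np.ndarray, factor: int) -> np.ndarray:
    """Mean over ``factor`` x ``factor`` blocks; edge blocks average the
    pixels actually present."""
    h, w = a.shape[:2]
    ri = np.arange(0, h, factor)
    ci = np.arange(0, w, factor)
    s = np.add.reduceat(np.add.reduceat(a, ri, axis=0), ci, axis=1)
    rn = np.diff(np.append(ri, h)).astype(float)
    cn = np.diff(np.append(ci, w)).astype(float)
    counts = np.outer(rn, cn)
    if a.ndim == 3:
        counts = counts[..., None]
    return s / counts


def downsample(image: RasterImage, factor: int) -> RasterImage:
    """Area-average (block-mean) reduction by an integer factor.

    Output dimensions are ``ceil(dim / factor)``; a factor of 1 returns an
    identical copy.
    """
    if int(factor) != factor or factor < 1:
        raise ImagingError(f"downsample factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return image.copy()
    return RasterImage(_block_reduce_mean(image.pixels, factor), image.colorspace)


def luma(pixels: np.ndarray) -> np.ndarray:
    """Weighted channel mean of a raw array (no colorspace bookkeeping).

    Used internally where only relative brightness matters, e.g. plate
    detection.
    """
    if pixels.ndim == 2:
        return pixels
    return pixels @ np.asarray(GRAY_WEIGHTS)


def read_image(path) -> RasterImage:
    """Decode an 8-bit JPEG/PNG to a float sRGB-tagged image.

    The EXIF orientation tag, if present, is applied; no other metadata is
    interpreted.
    """
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        if im.mode in ("L", "I;16"):
            im = im.convert("L")
            arr = np.asarray(im, dtype=np.float64) / 255.0
        else:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    return RasterImage(arr, SRGB)


def write_image(path, image: RasterImage, *, jpeg_quality: int = 92) -> None:
    """Write an 8-bit JPEG or PNG; linear images are sRGB-encoded first."""
    if image.colorspace == LINEAR:
        image = linear_to_srgb(image)
    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    pil = Image.fromarray(arr)
    path = str(path)
    if path.lower().endswith((".jpg", ".jpeg")):
        pil.save(path, quality=jpeg_quality)
    else:
        pil.save(path)
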