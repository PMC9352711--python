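"""Illumination correction, spot detection and spot integration.

The UV lamp illuminates the plate unevenly.  Its smooth field is modelled by
a 15-term two-dimensional quartic polynomial

    f(x, y) = a1 y^4 + a2 x y^3 + a3 x^2 y^2 + a4 x^3 y + a5 x^4
            + a6 y^3 + a7 x y^2 + a8 x^2 y + a9 x^3
            + a10 y^2 + a11 x y + a12 x^2 + a13 x + a14 y + a15

fitted by ordinary least squares to a 4x-subsampled copy of the rectified
grayscale plate, in coordinates normalised to [-1, 1] for conditioning.

The residual is defined as *background minus image*, so fluorescence-
quenching (dark) analyte spots carry positive residual.  Thresholding the
residual at its own mean, 8-connected component labelling, and shape/size
filtering isolate the spots; each spot is then integrated as the sum of the
top 15% of residual values inside its covering disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .errors import DensitometryError
from .imaging import RasterImage

#: (x power, y power) of the 15 quartic basis terms, in coefficient order
#: a1 ... a15.
QUARTIC_EXPONENTS: tuple[tuple[int, int], ...] = (
    (0, 4), (1, 3), (2, 2), (3, 1), (4, 0),
    (0, 3), (1, 2), (2, 1), (3, 0),
    (0, 2), (1, 1), (2, 0),
    (1, 0), (0, 1), (0, 0),
)

#: Reference pixel count for the small-shape filter: ``min_area`` is
#: specified at a ~12-megapixel plate and scales proportionally with area.
MIN_AREA_REFERENCE_PIXELS = 12_000_000


@dataclass
class CoordNorm:
    """Affine map from pixel coordinates to the [-1, 1]^2 fitting frame."""

    width: int
    height: int

    def normalize(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sx = 2.0 / (self.width - 1) if self.width > 1 else 0.0
        sy = 2.0 / (self.height - 1) if self.height > 1 else 0.0
        return np.asarray(x) * sx - 1.0, np.asarray(y) * sy - 1.0


def quartic_design_matrix(xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
    """Stack the 15 basis terms evaluated at normalised coordinates."""
    xn = np.asarray(xn, float).ravel()
    yn = np.asarray(yn, float).ravel()
    # repeated multiplication instead of pow: this matrix is rebuilt on the
    # full pixel grid for every background evaluation
    xp = [np.ones_like(xn)]
    yp = [np.ones_like(yn)]
    for _ in range(4):
        xp.append(xp[-1] * xn)
        yp.append(yp[-1] * yn)
    out = np.empty((xn.size, 15))
    for k, (i, j) in enumerate(QUARTIC_EXPONENTS):
        np.multiply(xp[i], yp[j], out=out[:, k])
    return out


@dataclass
class IlluminationModel:
    """Fitted quartic illumination surface."""

    coeffs: np.ndarray
    coord_norm: CoordNorm

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, float).ravel()
        if self.coeffs.shape != (15,):
            raise DensitometryError(f"expected 15 coefficients, got {self.coeffs.size}")
        if not np.all(np.isfinite(self.coeffs)):
            raise DensitometryError("illumination coefficients must be finite")

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xn, yn = self.coord_norm.normalize(x, y)
        return quartic_design_matrix(xn, yn) @ self.coeffs

    def evaluate_grid(self) -> np.ndarray:
        """Evaluate on the full-resolution pixel grid of the fitted plate."""
        h, w = self.coord_norm.height, self.coord_norm.width
        xx, yy = np.meshgrid(np.arange(w), np.arange(h))
        return self.evaluate(xx, yy).reshape(h, w)


def fit_illumination(
    plate: RasterImage,
    *,
    downsample_factor: int = 4,
    refit_exclude_spots: bool = False,
) -> IlluminationModel:
    """Least-squares fit of the quartic surface to the plate background.

    The fit runs on every ``downsample_factor``-th pixel (stride subsampling;
    this keeps polynomial surfaces exactly representable, which block
    averaging would not).  With ``refit_exclude_spots`` a second pass
    excludes pixels whose first-pass residual lies at or above the residual
    mean — i.e. the spot and pencil-mark pixels — removing their leverage on
    the background estimate.
    """
    if plate.is_color:
        raise DensitometryError("illumination fitting requires a grayscale plate")
    if plate.width < 8 or plate.height < 8:
        raise DensitometryError("plate must be at least 8x8 pixels")
    f = max(1, int(downsample_factor))
    ys = np.arange(0, plate.height, f)
    xs = np.arange(0, plate.width, f)
    if ys.size * xs.size < 15:
        raise DensitometryError(
            f"fewer than 15 pixels after downsampling by {f}: cannot fit 15 coefficients"
        )
    values = plate.pixels[np.ix_(ys, xs)].ravel()
    xx, yy = np.meshgrid(xs, ys)
    norm = CoordNorm(plate.width, plate.height)
    xn, yn = norm.normalize(xx.ravel(), yy.ravel())
    design = quartic_design_matrix(xn, yn)

    coeffs, *_ = np.linalg.lstsq(design, values, rcond=None)

    if refit_exclude_spots:
        resid = design @ coeffs - values  # background minus image
        keep = resid < resid.mean()
        # guard: keep the single-pass fit when exclusion would starve it
        if keep.sum() >= 15 and keep.mean() >= 0.25:
            coeffs, *_ = np.linalg.lstsq(design[keep], values[keep], rcond=None)

    return IlluminationModel(coeffs, norm)


def constant_illumination(plate: RasterImage) -> IlluminationModel:
    """Degenerate model: a flat background at the plate's mean intensity.

    Offered so the effect of disabling the polynomial correction can be
    studied; only the constant term a15 is populated.
    """
    if plate.is_color:
        raise DensitometryError("illumination fitting requires a grayscale plate")
    coeffs = np.zeros(15)
    coeffs[14] = float(plate.pixels.mean())
    return IlluminationModel(coeffs, CoordNorm(plate.width, plate.height))


@dataclass
class ResidualImage:
    """Signed residual r = background - plate, with its mean recorded.

    Dark (quenching) spots have positive residual under this sign
    convention, so the mean-threshold rule selects them directly.
    """

    pixels: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        self.mean = float(self.pixels.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def compute_residual(plate: RasterImage, model: IlluminationModel) -> ResidualImage:
    """r(x, y) = f(x, y) - plate(x, y)."""
    if plate.is_color:
        raise DensitometryError("residual requires a grayscale plate")
    if (model.coord_norm.width, model.coord_norm.height) != (plate.width, plate.height):
        raise DensitometryError(
            f"model was fitted on {model.coord_norm.width}x{model.coord_norm.height}, "
            f"plate is {plate.width}x{plate.height}"
        )
    return ResidualImage(model.evaluate_grid() - plate.pixels)


def threshold_residual(residual: ResidualImage) -> np.ndarray:
    """Binary mask t(v) = 1 iff v >= mu_I (the residual mean); inclusive.

    The boundary is evaluated with a one-ulp tolerance so that a constant
    residual (v == mu_I up to summation rounding) is fully selected.
    """
    mean = residual.mean
    return residual.pixels >= mean - 4 * np.spacing(abs(mean))


@dataclass
class SpotComponent:
    """An 8-connected region of above-threshold residual pixels."""

    coords: np.ndarray  # (N, 2) array of (row, col) member pixels
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (inclusive)

    @property
    def area(self) -> int:
        return len(self.coords)

    @property
    def aspect_ratio(self) -> float:
        """Bounding-box width / height."""
        minr, minc, maxr, maxc = self.bbox
        return (maxc - minc + 1) / (maxr - minr + 1)

    @property
    def centroid(self) -> tuple[float, float]:
        """Unweighted (x, y) centroid."""
        return float(self.coords[:, 1].mean()), float(self.coords[:, 0].mean())


def find_components(mask: np.ndarray) -> list[SpotComponent]:
    """Label 8-connected components of a binary mask."""
    labelled = label(np.asarray(mask, bool), connectivity=2)
    out = []
    for region in regionprops(labelled):
        minr, minc, maxr, maxc = region.bbox
        out.append(SpotComponent(region.coords.copy(), (minr, minc, maxr - 1, maxc - 1)))
    return out


def scaled_min_area(plate_shape: tuple[int, int], min_area: float, floor: int = 4) -> float:
    h, w = plate_shape[:2]
    return max(float(floor), min_area * (h * w) / MIN_AREA_REFERENCE_PIXELS)


def filter_components(
    components: list[SpotComponent],
    plate_shape: tuple[int, int],
    *,
    max_aspect: float = 3.0,
    min_area: float = 25.0,
    min_area_floor: int = 4,
) -> list[SpotComponent]:
    """Drop pencil marks and clutter, keep compact spot-sized blobs.

    Removes components whose bounding-box aspect ratio exceeds
    ``max_aspect`` (or its reciprocal), whose area is below the
    resolution-scaled minimum, or whose area exceeds a quarter of the plate.
    Survivors are returned in reading order of their centroids.
    """
    h, w = plate_shape[:2]
    amin = scaled_min_area(plate_shape, min_area, min_area_floor)
    amax = h * w / 4.0
    kept = [
        c
        for c in components
        if (1.0 / max_aspect) <= c.aspect_ratio <= max_aspect
        and c.area >= amin
        and c.area <= amax
    ]
    return sorted(kept, key=lambda c: (c.centroid[1], c.centroid[0]))


@dataclass
class Spot:
    """A detected or manually placed spot, with its covering disk."""

    center: tuple[float, float]  # (x, y)
    radius: float
    integration_value: float | None = None
    detection: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DensitometryError("spot radius must be positive")
        if self.detection not in ("auto", "manual"):
            raise DensitometryError(f"unknown detection source {self.detection!r}")


def locate_spot(component: SpotComponent, residual: ResidualImage) -> Spot:
    """Place a spot at the intensity-weighted centroid of a component.

    The centre is sum(c * v) / sum(v) over member pixels; the radius is the
    farthest member's distance from the centre plus a 1-pixel margin, so the
    disk covers the whole component.
    """
    if component.area == 0:
        raise DensitometryError("empty component")
    rows = component.coords[:, 0]
    cols = component.coords[:, 1]
    v = residual.pixels[rows, cols]
    total = float(v.sum())
    if v.max() <= 0 or total <= 0:
        raise DensitometryError("all member residuals are non-positive: cannot weight centroid")
    cx = float((cols * v).sum() / total)
    cy = float((rows * v).sum() / total)
    dist = np.hypot(cols - cx, rows - cy)
    return Spot(center=(cx, cy), radius=float(dist.max()) + 1.0, detection="auto")


def disk_pixels(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centres lie in the disk, clipped to the
    image, in row-major order."""
    cx, cy = center
    h, w = shape[:2]
    r0 = max(0, int(math.floor(cy - radius)))
    r1 = min(h - 1, int(math.ceil(cy + radius)))
    c0 = max(0, int(math.floor(cx - radius)))
    c1 = min(w - 1, int(math.ceil(cx + radius)))
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int)
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return yy[inside], xx[inside]


def integrate_spot(
    spot: Spot, residual: ResidualImage, *, top_fraction: float = 0.15
) -> float:
    """Sum the top ``top_fraction`` of residual values in the spot's disk.

    The pixel count used is ``max(1, ceil(top_fraction * N))``; ties are
    broken deterministically by row-major pixel index.  The value is stored
    on the spot and returned.
    """
    rows, cols = disk_pixels(spot.center, spot.radius, residual.shape)
    n = rows.size
    if n == 0:
        raise DensitometryError("spot disk does not cover any pixel of the image")
    v = residual.pixels[rows, cols]
    n_top = max(1, math.ceil(top_fraction * n))
    # stable selection: descending value, then row-major position
    order = np.lexsort((np.arange(n), -v))
    value = float(v[order[:n_top]].sum())
    spot.integration_value = value
    return value


def add_manual_spot(
    center: tuple[float, float],
    radius: float,
    residual: ResidualImage,
    *,
    top_fraction: float = 0.15,
) -> Spot:
    """Create a user-placed spot and integrate it exactly like an auto spot."""
    spot = Spot(center=tuple(map(float, center)), radius=float(radius), detection="manual")
    rows, _ = disk_pixels(spot.center, spot.radius, residual.shape)
    if rows.size == 0:
        raise DensitometryError("manual spot disk lies entirely outside the image")
    integrate_spot(spot, residual, top_fraction=top_fraction)
    return spot
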