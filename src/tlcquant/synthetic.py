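"""Synthetic TLC plate photographs with exact ground truth.

The generator emulates what the camera sees inside the photography box: a
bright fluorescing plate under uneven UV illumination, dark roughly circular
analyte spots (fluorescence quenching), thin pencil markings, sensor noise,
and optionally a perspective-warped view with a dark surround.

The scene model is ``plate = illumination x base - sum(spot Gaussians) -
pencil marks``: each spot's integrated darkening is *exactly* linear in its
content by construction, because linearity of integrated darkening in
analyte amount is the physical assumption the densitometric method rests
on.  Illumination presets are quartic coefficient fields (matching the
background model family) plus one deliberately non-quartic cosine^4
vignette for model-mismatch studies.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import warp as sk_warp

from .densitometry import CoordNorm, quartic_design_matrix
from .errors import TLCQuantError
from .imaging import SRGB, RasterImage, _srgb_encode

#: noise profile emulating the repeatability regime of a trained operator:
#: 0.1% multiplicative pixel noise (sensor, after in-camera denoising) plus
#: a per-spot amplitude variability dominated by manual 2-ul capillary
#: spotting.  Together these put the single-measurement relative standard
#: deviation of the full pipeline at ~2.8%.
REPEATABILITY_NOISE = {"noise_sigma": 0.001, "spot_amplitude_rsd": 0.0204}

#: named illumination presets as 15-term quartic coefficient vectors over
#: normalised plate coordinates [-1, 1]^2 (see densitometry.QUARTIC_EXPONENTS)
def _central_lamp() -> np.ndarray:
    c = np.zeros(15)
    c[14] = 1.0     # constant
    c[11] = -0.16   # x^2
    c[9] = -0.16    # y^2
    c[2] = -0.04    # x^2 y^2
    return c


def _off_center_lamp() -> np.ndarray:
    c = _central_lamp()
    c[12] = -0.10   # x term: brighter on the left (x = -1)
    return c


ILLUMINATION_PRESETS = {
    "central-lamp": _central_lamp(),
    "off-center-lamp": _off_center_lamp(),
    "low-battery": 0.55 * _central_lamp(),
}

#: non-quartic vignette (outside the background model family)
COSINE4_PRESET = "cosine4-vignette"


@dataclass
class SpotSpec:
    """One analyte spot: anisotropic Gaussian darkening, linear in content."""

    x: float
    y: float
    content: float  # true content, % of the standard concentration
    role: str = "sample"  # sample | reference
    amplitude_per_percent: float = 0.0035
    sigma_x: float = 9.0
    sigma_y: float = 9.0

    def __post_init__(self) -> None:
        if self.content <= 0:
            raise TLCQuantError(f"spot content must be positive, got {self.content}")
        if self.role not in ("sample", "reference"):
            raise TLCQuantError(f"unknown spot role {self.role!r}")


@dataclass
class PencilMark:
    """A thin graphite line segment (e.g. start line or solvent front)."""

    x0: float
    y0: float
    x1: float
    y1: float
    width: float = 2.0
    amplitude: float = 0.06


@dataclass
class WarpSpec:
    """Perspective embedding of the plate into a larger dark canvas."""

    corners: np.ndarray  # (4, 2) plate corner positions in canvas coords, TL TR BR BL
    canvas_width: int
    canvas_height: int
    surround: float = 0.04

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, float).reshape(4, 2)


@dataclass
class PlateSpec:
    """Full scene description for one rendered plate photo."""

    width: int = 450
    height: int = 330
    base_brightness: float = 0.80
    illumination: str | np.ndarray = "central-lamp"
    spots: list[SpotSpec] = field(default_factory=list)
    pencil_marks: list[PencilMark] = field(default_factory=list)
    noise_sigma: float = 0.0
    spot_amplitude_rsd: float = 0.0
    warp: WarpSpec | None = None
    jpeg_quality: int | None = None
    tint: tuple[float, float, float] = (0.55, 1.0, 0.78)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.spot_amplitude_rsd < 0:
            raise TLCQuantError("noise levels must be non-negative")


@dataclass
class SpotTruth:
    x: float
    y: float
    content: float
    role: str
    integrated_darkening: float


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered scene."""

    spots: list[SpotTruth]
    illumination: str | list[float]
    corners: list[list[float]] | None  # plate corners in photo coords (warped scenes)
    seed: int

    def reference_spots(self) -> list[SpotTruth]:
        return [s for s in self.spots if s.role == "reference"]

    def sample_spots(self) -> list[SpotTruth]:
        return [s for s in self.spots if s.role == "sample"]

    def to_json_dict(self) -> dict:
        return {
            "spots": [asdict(s) for s in self.spots],
            "illumination": self.illumination
            if isinstance(self.illumination, str)
            else [float(v) for v in self.illumination],
            "corners": self.corners,
            "seed": self.seed,
        }


def illumination_field(spec: PlateSpec) -> np.ndarray:
    """Evaluate the illumination on the plate grid (values relative to 1)."""
    norm = CoordNorm(spec.width, spec.height)
    xx, yy = np.meshgrid(np.arange(spec.width), np.arange(spec.height))
    xn, yn = norm.normalize(xx, yy)
    illum = spec.illumination
    if isinstance(illum, str):
        if illum == COSINE4_PRESET:
            r = np.hypot(xn, yn)
            return 0.55 + 0.45 * np.cos(0.55 * r) ** 4
        if illum not in ILLUMINATION_PRESETS:
            raise TLCQuantError(f"unknown illumination preset {illum!r}")
        coeffs = ILLUMINATION_PRESETS[illum]
    else:
        coeffs = np.asarray(illum, float).ravel()
        if coeffs.size != 15:
            raise TLCQuantError("explicit illumination must have 15 quartic coefficients")
    return (quartic_design_matrix(xn.ravel(), yn.ravel()) @ coeffs).reshape(
        spec.height, spec.width
    )


def _segment_distance(
    xx: np.ndarray, yy: np.ndarray, mark: PencilMark
) -> np.ndarray:
    px, py = mark.x1 - mark.x0, mark.y1 - mark.y0
    denom = px * px + py * py
    if denom == 0:
        return np.hypot(xx - mark.x0, yy - mark.y0)
    t = np.clip(((xx - mark.x0) * px + (yy - mark.y0) * py) / denom, 0.0, 1.0)
    return np.hypot(xx - (mark.x0 + t * px), yy - (mark.y0 + t * py))


def render_plate(spec: PlateSpec, seed: int) -> tuple[RasterImage, GroundTruth]:
    """Render a plate photo; deterministic for a fixed (spec, seed) pair.

    Returns the sRGB-encoded photo and the ground truth.  Spot amplitude
    jitter (manual-spotting variability) is applied to the rendered image
    only; the recorded integrated darkening is the exact noise-free value
    ``amplitude_per_percent x content x sum(Gaussian)``.
    """
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(np.arange(spec.width, dtype=float), np.arange(spec.height, dtype=float))

    plate = illumination_field(spec) * spec.base_brightness

    truths: list[SpotTruth] = []
    for s in spec.spots:
        if not (
            3 * s.sigma_x <= s.x <= spec.width - 1 - 3 * s.sigma_x
            and 3 * s.sigma_y <= s.y <= spec.height - 1 - 3 * s.sigma_y
        ):
            raise TLCQuantError(
                f"spot at ({s.x:g}, {s.y:g}) extends off the {spec.width}x{spec.height} plate"
            )
        g = np.exp(
            -((xx - s.x) ** 2 / (2 * s.sigma_x**2) + (yy - s.y) ** 2 / (2 * s.sigma_y**2))
        )
        peak = s.content * s.amplitude_per_percent
        jitter = 1.0 + spec.spot_amplitude_rsd * rng.standard_normal()
        plate -= peak * jitter * g
        truths.append(
            SpotTruth(
                x=s.x, y=s.y, content=s.content, role=s.role,
                integrated_darkening=float(peak * g.sum()),
            )
        )

    for mark in spec.pencil_marks:
        plate -= np.where(
            _segment_distance(xx, yy, mark) <= mark.width / 2.0, mark.amplitude, 0.0
        )

    if plate.min() < 0:
        warnings.warn(
            "rendered plate clipped at zero intensity: spot darkening exceeds the "
            "local background, breaking linearity of the scene"
        )
        np.clip(plate, 0.0, None, out=plate)

    corners = None
    if spec.warp is not None:
        w = spec.warp
        plate_corners = np.array(
            [[0, 0], [spec.width - 1, 0], [spec.width - 1, spec.height - 1], [0, spec.height - 1]],
            float,
        )
        from .plate import _estimate_homography

        tform = _estimate_homography(w.corners, plate_corners)
        if tform is None:
            raise TLCQuantError("degenerate warp corner configuration")
        plate = sk_warp(
            plate, inverse_map=tform,
            output_shape=(w.canvas_height, w.canvas_width),
            order=1, mode="constant", cval=w.surround, preserve_range=True,
        )
        corners = [[float(x), float(y)] for x, y in w.corners]

    if spec.noise_sigma > 0:
        plate = plate * (1.0 + spec.noise_sigma * rng.standard_normal(plate.shape))
    np.clip(plate, 0.0, 1.0, out=plate)

    rgb_linear = plate[..., None] * np.asarray(spec.tint, float)
    photo = RasterImage(np.clip(_srgb_encode(rgb_linear), 0.0, 1.0), SRGB)

    if spec.jpeg_quality is not None:
        from PIL import Image

        arr = np.clip(np.rint(photo.pixels * 255.0), 0, 255).astype(np.uint8)
        buf = io.BytesIO()
        Image.fromarray(arr).save(buf, format="JPEG", quality=int(spec.jpeg_quality))
        buf.seek(0)
        with Image.open(buf) as im:
            photo = RasterImage(np.asarray(im.convert("RGB"), np.float64) / 255.0, SRGB)

    truth = GroundTruth(
        spots=truths,
        illumination=spec.illumination
        if isinstance(spec.illumination, str)
        else [float(v) for v in np.asarray(spec.illumination).ravel()],
        corners=corners,
        seed=int(seed),
    )
    return photo, truth


# ---------------------------------------------------------------------------
# standard scenarios

def default_pencil_marks(width: int, height: int) -> list[PencilMark]:
    """Start line near the bottom and solvent front near the top."""
    return [
        PencilMark(0, 0.85 * height, width - 1, 0.85 * height),
        PencilMark(0, 0.08 * height, width - 1, 0.08 * height),
    ]


def make_plate_spec(
    reference_percentages: tuple[float, ...],
    sample_contents: tuple[float, ...],
    *,
    width: int = 450,
    height: int = 330,
    amplitude_per_percent: float = 0.0035,
    illumination: str | np.ndarray = "central-lamp",
    noise_sigma: float = 0.0,
    spot_amplitude_rsd: float = 0.0,
    jpeg_quality: int | None = None,
    warp: WarpSpec | None = None,
) -> PlateSpec:
    """Lay out reference lanes (left) and sample lanes (right) on one plate."""
    contents = list(reference_percentages) + list(sample_contents)
    roles = ["reference"] * len(reference_percentages) + ["sample"] * len(sample_contents)
    n = len(contents)
    band_y = 0.45 * height
    spots = [
        SpotSpec(
            x=(i + 1) * width / (n + 1), y=band_y, content=float(c), role=role,
            amplitude_per_percent=amplitude_per_percent,
        )
        for i, (c, role) in enumerate(zip(contents, roles))
    ]
    return PlateSpec(
        width=width, height=height, spots=spots,
        pencil_marks=default_pencil_marks(width, height),
        illumination=illumination, noise_sigma=noise_sigma,
        spot_amplitude_rsd=spot_amplitude_rsd, jpeg_quality=jpeg_quality, warp=warp,
    )


def standard_scenarios() -> dict[str, PlateSpec]:
    """The spotting patterns used throughout the performance evaluation.

    * ``repeatability_{70,85,90}`` — three reference lanes (60/80/100%) and
      two lanes of the same test solution (pattern with three references).
    * ``simplified_90`` — the two-reference pattern (80% and 100%) with two
      90% sample lanes.
    * ``low_range`` — references 10.0/13.3/16.7% with 12.0/14.2/15.0%
      samples (six-fold diluted test solutions).
    * ``robust_*`` — deliberate condition variations: off-centre UV lamp,
      low battery charge (dim lamp), and JPEG re-encoding.
    """
    scenarios: dict[str, PlateSpec] = {}
    for content in (70.0, 85.0, 90.0):
        scenarios[f"repeatability_{content:.0f}"] = make_plate_spec(
            (60.0, 80.0, 100.0), (content, content)
        )
    scenarios["simplified_90"] = make_plate_spec((80.0, 100.0), (90.0, 90.0))
    scenarios["low_range"] = make_plate_spec(
        (10.0, 13.3, 16.7), (12.0, 14.2, 15.0)
    )
    scenarios["robust_lamp_offcenter"] = make_plate_spec(
        (60.0, 80.0, 100.0), (90.0, 90.0), illumination="off-center-lamp"
    )
    scenarios["robust_low_battery"] = make_plate_spec(
        (60.0, 80.0, 100.0), (90.0, 90.0), illumination="low-battery"
    )
    scenarios["robust_jpeg"] = make_plate_spec(
        (60.0, 80.0, 100.0), (90.0, 90.0), jpeg_quality=85
    )
    return scenarios


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
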