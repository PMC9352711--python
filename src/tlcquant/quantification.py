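"""Calibration against reference spots, sample quantification, and the
result bundle.

Two or more reference spots of known content (as a percentage of the
standard concentration) define a straight calibration line; ordinary least
squares maps integration values to percentages, and every other spot's
content is read off that line.  Each analysis is serialised as a bundle
directory (or ZIP): the raw photo, the rectified plate, the fitted
background, a spot overlay, and a ``capture.json`` record.
"""

from __future__ import annotations

import datetime
import json
import math
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import densitometry as dens
from . import imaging, plate as plate_geometry
from .config import AnalysisConfig
from .errors import BundleSchemaError, CalibrationError, PipelineError, TLCQuantError

BUNDLE_FILES = ("capture.jpg", "warped.png", "background_fit.png", "blobs.png", "capture.json")


# ---------------------------------------------------------------------------
# annotations

@dataclass
class ReferenceAnnotation:
    """Marks one detected (or manual) spot as a reference of known content.

    ``spot`` is either an index into the analysis' spot list (reading order,
    manual spots appended last) or an ``(x, y)`` coordinate matched to the
    nearest spot centre.
    """

    spot: int | tuple[float, float]
    percentage: float

    def __post_init__(self) -> None:
        if self.percentage <= 0:
            raise CalibrationError(f"reference percentage must be positive, got {self.percentage}")


@dataclass
class ManualSpot:
    x: float
    y: float
    radius: float


@dataclass
class Annotations:
    """Everything the operator supplies for one plate analysis."""

    references: list[ReferenceAnnotation]
    agent_name: str = "sample"
    corners: np.ndarray | None = None  # (4, 2) photo coordinates, TL TR BR BL
    manual_spots: list[ManualSpot] = field(default_factory=list)
    delete_spots: list[int | tuple[float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.references) < 2:
            raise CalibrationError(
                f"at least two reference spots are required, got {len(self.references)}"
            )
        if len({float(r.percentage) for r in self.references}) < 2:
            raise CalibrationError("references must include at least two distinct percentages")

    @classmethod
    def from_dict(cls, data: dict) -> "Annotations":
        refs = []
        for entry in data.get("references", []):
            spot = entry["spot"]
            if isinstance(spot, dict):
                spot = (float(spot["x"]), float(spot["y"]))
            refs.append(ReferenceAnnotation(spot=spot, percentage=float(entry["percentage"])))
        corners = data.get("corners")
        if corners is not None:
            if isinstance(corners, str):
                corners = plate_geometry.parse_corners(corners)
            corners = np.asarray(corners, float).reshape(4, 2)
        manual = [
            ManualSpot(float(m["x"]), float(m["y"]), float(m["radius"]))
            for m in data.get("manualSpots", data.get("manual_spots", []))
        ]
        deletes = []
        for entry in data.get("deleteSpots", data.get("delete_spots", [])):
            if isinstance(entry, dict):
                deletes.append((float(entry["x"]), float(entry["y"])))
            else:
                deletes.append(int(entry))
        return cls(
            references=refs,
            agent_name=str(data.get("agentName", data.get("agent_name", "sample"))),
            corners=corners,
            manual_spots=manual,
            delete_spots=deletes,
        )

    @classmethod
    def from_file(cls, path) -> "Annotations":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationModel:
    """percentage = slope * integration + intercept."""

    slope: float
    intercept: float
    n_refs: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, integration: float) -> float:
        return self.slope * float(integration) + self.intercept


def fit_calibration(
    integrations: np.ndarray, percentages: np.ndarray
) -> CalibrationModel:
    """OLS line (with intercept) mapping integration values to percentages."""
    x = np.asarray(integrations, float).ravel()
    y = np.asarray(percentages, float).ravel()
    if x.size != y.size:
        raise CalibrationError("integration and percentage arrays differ in length")
    if x.size < 2:
        raise CalibrationError(f"at least two references are required, got {x.size}")
    if np.ptp(x) == 0:
        raise CalibrationError(
            "degenerate calibration: all reference integration values are identical"
        )
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    intercept = float(ym - slope * xm)
    residuals = y - (slope * x + intercept)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise CalibrationError("calibration coefficients are not finite")
    return CalibrationModel(slope=slope, intercept=intercept, n_refs=int(x.size), residuals=residuals)


def quantify(model: CalibrationModel, spot) -> float:
    """Evaluate the calibration line at a spot's integration value.

    Extrapolation beyond the reference range is permitted; a negative result
    is allowed but flagged with a warning.
    """
    integration = spot.integration_value if hasattr(spot, "integration_value") else spot
    if integration is None:
        raise CalibrationError("spot has no integration value")
    p = model.predict(integration)
    if p < 0:
        warnings.warn(f"quantified percentage is negative ({p:.2f}%)", stacklevel=2)
    return p


def display_percentage(p: float) -> int:
    """On-screen integer percentage: round half away from zero, clamp
    negatives to zero (the raw value is kept in the analysis record)."""
    if p < 0:
        warnings.warn(f"negative percentage {p:.2f} clamped to 0 for display", stacklevel=2)
        return 0
    return int(math.floor(p + 0.5))


# ---------------------------------------------------------------------------
# analysis result

@dataclass
class SpotResult:
    x: float
    y: float
    radius: float
    integration_value: float
    percentage: float
    role: str  # "sample" | "reference"
    reference_percentage: float | None = None
    detection: str = "auto"

    def to_json_dict(self) -> dict:
        return {
            "x": float(self.x),
            "y": float(self.y),
            "radius": float(self.radius),
            "integrationValue": float(self.integration_value),
            "percentage": float(self.percentage),
            "role": self.role,
            "referencePercentage": None
            if self.reference_percentage is None
            else float(self.reference_percentage),
            "detection": self.detection,
        }


@dataclass
class PipelineArtifacts:
    """Intermediate images kept for bundle output (not serialised to JSON)."""

    photo: imaging.RasterImage
    rectified: imaging.RasterImage  # colour or grayscale, linear
    background: np.ndarray
    residual: dens.ResidualImage
    quad: plate_geometry.PlateQuad


@dataclass
class AnalysisResult:
    agent_name: str
    spots: list[SpotResult]
    calibration: CalibrationModel
    provenance: dict
    artifacts: PipelineArtifacts | None = None

    def to_json_dict(self) -> dict:
        return {
            "agentName": self.agent_name,
            "spots": [s.to_json_dict() for s in self.spots],
            "calibration": {
                "slope": float(self.calibration.slope),
                "intercept": float(self.calibration.intercept),
                "nReferences": int(self.calibration.n_refs),
            },
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "AnalysisResult":
        known_top = {"agentName", "spots", "calibration", "provenance"}
        extra = set(data) - known_top
        if extra:
            warnings.warn(f"capture.json carries unknown keys {sorted(extra)}; ignored")
        known_spot = {
            "x", "y", "radius", "integrationValue", "percentage",
            "role", "referencePercentage", "detection",
        }
        spots = []
        for s in data.get("spots", []):
            extra = set(s) - known_spot
            if extra:
                warnings.warn(f"spot record carries unknown keys {sorted(extra)}; ignored")
            spots.append(
                SpotResult(
                    x=float(s["x"]),
                    y=float(s["y"]),
                    radius=float(s["radius"]),
                    integration_value=float(s["integrationValue"]),
                    percentage=float(s["percentage"]),
                    role=s.get("role", "sample"),
                    reference_percentage=s.get("referencePercentage"),
                    detection=s.get("detection", "auto"),
                )
            )
        cal = data.get("calibration", {})
        calibration = CalibrationModel(
            slope=float(cal["slope"]),
            intercept=float(cal["intercept"]),
            n_refs=int(cal.get("nReferences", 0)),
        )
        return cls(
            agent_name=str(data.get("agentName", "")),
            spots=spots,
            calibration=calibration,
            provenance=dict(data.get("provenance", {})),
        )

    def sample_spots(self) -> list[SpotResult]:
        return [s for s in self.spots if s.role == "sample"]

    def reference_spots(self) -> list[SpotResult]:
        return [s for s in self.spots if s.role == "reference"]


# ---------------------------------------------------------------------------
# pipeline

def _match_spot(
    spots: list[dens.Spot], target: int | tuple[float, float], match_radius: float
) -> int:
    if isinstance(target, (int, np.integer)):
        if not 0 <= target < len(spots):
            raise CalibrationError(
                f"spot index {target} out of range (plate has {len(spots)} spots)"
            )
        return int(target)
    tx, ty = target
    dists = [math.hypot(s.center[0] - tx, s.center[1] - ty) for s in spots]
    if not dists:
        raise CalibrationError("no spots detected to match annotation against")
    best = int(np.argmin(dists))
    if dists[best] > match_radius:
        centers = ", ".join(f"({s.center[0]:.0f},{s.center[1]:.0f})" for s in spots)
        raise CalibrationError(
            f"no spot within {match_radius:.0f} px of annotation ({tx:.0f},{ty:.0f}); "
            f"detected centres: {centers}"
        )
    return best


def analyze_plate(
    photo: imaging.RasterImage | str | Path,
    annotations: Annotations | dict | str | Path,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the full pipeline on one plate photo.

    rectify -> grayscale -> illumination fit -> residual threshold ->
    component filtering -> spot location/integration -> calibration ->
    quantification.  Deterministic for fixed inputs and config.
    """
    config = config or AnalysisConfig()
    if isinstance(annotations, (str, Path)):
        annotations = Annotations.from_file(annotations)
    elif isinstance(annotations, dict):
        annotations = Annotations.from_dict(annotations)
    annotations.validate()  # fail before any computation

    input_name = None
    if isinstance(photo, (str, Path)):
        input_name = str(photo)
        photo = imaging.read_image(photo)

    try:
        if config.assume_srgb and photo.colorspace == imaging.SRGB:
            linear = imaging.srgb_to_linear(photo)
        else:
            linear = imaging.RasterImage(photo.pixels, imaging.LINEAR)
    except TLCQuantError as exc:
        raise PipelineError("decode", str(exc)) from exc

    try:
        if annotations.corners is not None:
            quad = plate_geometry.PlateQuad(annotations.corners, source="manual")
        else:
            quad = plate_geometry.detect_plate(
                linear, downsample_factor=config.detect_downsample
            )
        rectified = plate_geometry.rectify(linear, quad)
    except TLCQuantError as exc:
        raise PipelineError("plate-geometry", str(exc)) from exc

    try:
        gray = imaging.to_grayscale(rectified) if rectified.is_color else rectified
        if config.background_model == "constant":
            model = dens.constant_illumination(gray)
        elif config.background_model == "quartic":
            model = dens.fit_illumination(
                gray,
                downsample_factor=config.fit_downsample,
                refit_exclude_spots=config.refit_background,
            )
        else:
            raise PipelineError(
                "background", f"unknown background model {config.background_model!r}"
            )
        residual = dens.compute_residual(gray, model)
    except PipelineError:
        raise
    except TLCQuantError as exc:
        raise PipelineError("background", str(exc)) from exc

    try:
        mask = dens.threshold_residual(residual)
        components = dens.filter_components(
            dens.find_components(mask),
            residual.shape,
            max_aspect=config.max_aspect,
            min_area=config.min_area,
            min_area_floor=config.min_area_floor,
        )
        spots = [dens.locate_spot(c, residual) for c in components]
        for target in annotations.delete_spots:
            idx = _match_spot(spots, target, config.match_radius)
            del spots[idx]
        for s in spots:
            dens.integrate_spot(s, residual, top_fraction=config.top_fraction)
        for m in annotations.manual_spots:
            spots.append(
                dens.add_manual_spot(
                    (m.x, m.y), m.radius, residual, top_fraction=config.top_fraction
                )
            )
    except TLCQuantError as exc:
        raise PipelineError("spot-detection", str(exc)) from exc

    try:
        ref_percent: dict[int, float] = {}
        for ref in annotations.references:
            idx = _match_spot(spots, ref.spot, config.match_radius)
            if idx in ref_percent:
                raise CalibrationError(
                    f"two reference annotations resolve to the same spot (index {idx})"
                )
            ref_percent[idx] = float(ref.percentage)
        calibration = fit_calibration(
            np.array([spots[i].integration_value for i in ref_percent]),
            np.array(list(ref_percent.values())),
        )
    except TLCQuantError as exc:
        raise PipelineError("calibration", str(exc)) from exc

    results = []
    for i, s in enumerate(spots):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = quantify(calibration, s)
        results.append(
            SpotResult(
                x=s.center[0],
                y=s.center[1],
                radius=s.radius,
                integration_value=s.integration_value,
                percentage=p,
                role="reference" if i in ref_percent else "sample",
                reference_percentage=ref_percent.get(i),
                detection=s.detection,
            )
        )

    provenance = {
        "inputFile": input_name,
        "corners": [[float(v) for v in pt] for pt in quad.corners],
        "cornerSource": quad.source,
        "configHash": config.hash(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    artifacts = PipelineArtifacts(
        photo=photo, rectified=rectified, background=model.evaluate_grid(),
        residual=residual, quad=quad,
    )
    return AnalysisResult(
        agent_name=annotations.agent_name,
        spots=results,
        calibration=calibration,
        provenance=provenance,
        artifacts=artifacts,
    )


# ---------------------------------------------------------------------------
# result bundle

def _blobs_overlay(rectified: imaging.RasterImage, spots: list[SpotResult]) -> np.ndarray:
    """Rectified plate with detected disks overdrawn in red."""
    from skimage.draw import circle_perimeter

    gray = rectified.pixels if not rectified.is_color else imaging.luma(rectified.pixels)
    rgb = np.dstack([gray, gray, gray])
    h, w = gray.shape
    for s in spots:
        for dr in (-1, 0):
            r = max(1, int(round(s.radius)) + dr)
            rr, cc = circle_perimeter(int(round(s.y)), int(round(s.x)), r, shape=(h, w))
            rgb[rr, cc] = (1.0, 0.1, 0.1)
    return np.clip(rgb, 0, 1)


def write_bundle(
    result: AnalysisResult,
    path,
    *,
    photo: imaging.RasterImage | None = None,
    as_zip: bool = False,
):
    """Write the per-analysis bundle.

    Produces ``capture.jpg`` (raw photo), ``warped.png`` (rectified plate),
    ``background_fit.png`` (fitted illumination), ``blobs.png`` (spot
    overlay) and ``capture.json``.  With ``as_zip`` the directory content is
    archived to ``<path>.zip`` (or ``path`` itself if it ends in .zip).

    Returns the path written (directory or ZIP file).
    """
    art = result.artifacts
    if art is None and photo is None:
        raise BundleSchemaError("cannot write a bundle without pipeline artifacts")
    photo = photo if photo is not None else art.photo

    path = Path(path)
    if as_zip:
        zip_path = path if path.suffix == ".zip" else path.with_suffix(".zip")
        with tempfile.TemporaryDirectory() as tmp:
            write_bundle(result, Path(tmp) / "bundle", photo=photo, as_zip=False)
            with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
                for name in BUNDLE_FILES:
                    zf.write(Path(tmp) / "bundle" / name, name)
        return zip_path

    path.mkdir(parents=True, exist_ok=True)
    imaging.write_image(path / "capture.jpg", photo)
    if art is not None:
        imaging.write_image(path / "warped.png", art.rectified)
        bg = np.clip(art.background, 0.0, 1.0)
        imaging.write_image(path / "background_fit.png", imaging.RasterImage(bg, imaging.LINEAR))
        overlay = _blobs_overlay(art.rectified, result.spots)
        imaging.write_image(path / "blobs.png", imaging.RasterImage(overlay, imaging.LINEAR))
    (path / "capture.json").write_text(
        json.dumps(result.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    return path


def read_bundle(path) -> AnalysisResult:
    """Read a bundle directory or ZIP back into an :class:`AnalysisResult`.

    Only the JSON-carried fields are restored; image artifacts stay on disk.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for name in BUNDLE_FILES:
                if name not in names:
                    raise BundleSchemaError(f"bundle is missing mandatory file {name!r}")
            data = json.loads(zf.read("capture.json").decode())
    else:
        for name in BUNDLE_FILES:
            if not (path / name).exists():
                raise BundleSchemaError(f"bundle is missing mandatory file {name!r}")
        data = json.loads((path / "capture.json").read_text())
    return AnalysisResult.from_json_dict(data)
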