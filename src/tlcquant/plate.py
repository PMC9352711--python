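"""Plate localisation and perspective rectification.

The TLC plate is a bright rectangle on a dark surround.  Detection runs on a
4x-downsampled luminance image: Otsu binarization, boundary extraction, and a
(rho, theta) Hough transform pick the four dominant boundary lines, whose
intersections give the corner candidates.  Manually supplied corners always
take precedence over detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import ProjectiveTransform, hough_line, hough_line_peaks, warp

from .errors import GeometryError, PlateNotFoundError
from .imaging import RasterImage, _block_reduce_mean, luma


def _estimate_homography(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform | None:
    """Projective transform mapping src points onto dst, or None if
    degenerate."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        return tform if tform else None
    tform = ProjectiveTransform()
    return tform if tform.estimate(src, dst) else None


def _canonical_corners(corners: np.ndarray) -> np.ndarray:
    """Order corners TL, TR, BR, BL (clockwise in image coordinates).

    Corners are sorted by angle around their centroid and rotated so the
    corner with the smallest x + y (top-left) comes first.
    """
    c = np.asarray(corners, dtype=float).reshape(4, 2)
    centroid = c.mean(axis=0)
    ang = np.arctan2(c[:, 1] - centroid[1], c[:, 0] - centroid[0])
    c = c[np.argsort(ang)]
    start = int(np.argmin(c.sum(axis=1)))
    return np.roll(c, -start, axis=0)


@dataclass
class PlateQuad:
    """Four ordered corner points (TL, TR, BR, BL) delimiting the plate.

    ``source`` records whether the quad came from automatic detection or
    from manual entry; manual corners are never canonically reordered beyond
    the TL-first angular sort, so the user's orientation choice is kept.
    """

    corners: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise GeometryError(f"expected 4 corner points, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise GeometryError("corner coordinates must be finite")
        self.corners = c
        if self.source not in ("auto", "manual"):
            raise GeometryError(f"unknown quad source {self.source!r}")
        self._validate_convex()

    def _validate_convex(self) -> None:
        c = self.corners
        cross = []
        for i in range(4):
            a, b, d = c[i], c[(i + 1) % 4], c[(i + 2) % 4]
            u, v = b - a, d - b
            cross.append(u[0] * v[1] - u[1] * v[0])
        cross = np.asarray(cross)
        if np.any(cross == 0) or not (np.all(cross > 0) or np.all(cross < 0)):
            raise GeometryError("corners must form a convex, non-degenerate quadrilateral")
        # shoelace area
        x, y = c[:, 0], c[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area <= 1.0:
            raise GeometryError(f"quadrilateral area {area:g} px^2 is degenerate")

    def edge_lengths(self) -> tuple[float, float, float, float]:
        """(top, right, bottom, left) edge lengths in pixels."""
        c = self.corners
        d = lambda i, j: float(np.hypot(*(c[j] - c[i])))
        return d(0, 1), d(1, 2), d(2, 3), d(3, 0)


def full_frame_quad(width: int, height: int, source: str = "auto") -> PlateQuad:
    return PlateQuad(
        np.array([[0, 0], [width - 1, 0], [width - 1, height - 1], [0, height - 1]], float),
        source=source,
    )


def parse_corners(text: str) -> np.ndarray:
    """Parse ``x1,y1,...,x4,y4`` (TL,TR,BR,BL order) into a (4, 2) array."""
    vals = [float(t) for t in text.replace(";", ",").split(",") if t.strip()]
    if len(vals) != 8:
        raise GeometryError(f"expected 8 comma-separated numbers, got {len(vals)}")
    return np.asarray(vals, float).reshape(4, 2)


def detect_plate(
    photo: RasterImage,
    *,
    downsample_factor: int = 4,
    theta_step_deg: float = 1.0,
    min_foreground_fraction: float = 0.02,
    low_contrast: float = 0.10,
) -> PlateQuad:
    """Locate the bright plate rectangle in a photo.

    Raises :class:`PlateNotFoundError` when no supported four-line boundary
    exists; the error message points the user at manual corner entry.
    """
    gray = luma(photo.pixels)
    f = int(downsample_factor)
    ds = _block_reduce_mean(gray, f) if f > 1 else gray
    h, w = ds.shape

    p2, p98 = np.percentile(ds, [2, 98])
    if p98 - p2 < low_contrast:
        # Near-constant image: either the photo is entirely plate (bright to
        # the edges) or there is nothing to find.
        if float(ds.mean()) >= 0.25:
            return full_frame_quad(photo.width, photo.height)
        raise PlateNotFoundError(
            "plate not found: image is uniformly dark; "
            "enter the four corner points manually (--corners)"
        )

    mask = ds > threshold_otsu(ds)
    fg = float(mask.mean())
    if fg < min_foreground_fraction:
        raise PlateNotFoundError(
            "plate not found: no bright region above threshold; "
            "enter the four corner points manually (--corners)"
        )
    if fg > 0.995:
        return full_frame_quad(photo.width, photo.height)

    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    theta = np.deg2rad(np.arange(-90.0, 90.0, theta_step_deg))
    acc, angles, dists = hough_line(boundary, theta=theta)
    _, peak_angles, peak_dists = hough_line_peaks(
        acc, angles, dists, num_peaks=24, threshold=0.2 * acc.max(), min_distance=5, min_angle=5
    )
    peak_strengths = [
        acc[np.argmin(np.abs(dists - d)), np.argmin(np.abs(angles - a))]
        for a, d in zip(peak_angles, peak_dists)
    ]

    rows, cols = np.nonzero(mask)
    cx, cy = float(cols.mean()), float(rows.mean())

    best: dict[str, tuple[float, float, float]] = {}  # side -> (strength, theta, rho)
    for strength, th, rho in zip(peak_strengths, peak_angles, peak_dists):
        ct, st = np.cos(th), np.sin(th)
        if abs(ct) >= abs(st):  # near-vertical line
            x_at_cy = (rho - cy * st) / ct
            side = "left" if x_at_cy < cx else "right"
        else:  # near-horizontal line
            y_at_cx = (rho - cx * ct) / st
            side = "top" if y_at_cx < cy else "bottom"
        if side not in best or strength > best[side][0]:
            best[side] = (strength, th, rho)

    missing = [s for s in ("left", "top", "right", "bottom") if s not in best]
    if missing:
        raise PlateNotFoundError(
            f"plate not found: no supported boundary line on side(s) {missing}; "
            "enter the four corner points manually (--corners)"
        )

    def intersect(a: str, b: str) -> np.ndarray:
        _, th1, r1 = best[a]
        _, th2, r2 = best[b]
        m = np.array([[np.cos(th1), np.sin(th1)], [np.cos(th2), np.sin(th2)]])
        if abs(np.linalg.det(m)) < 1e-9:
            raise PlateNotFoundError(
                "plate not found: boundary lines do not intersect; "
                "enter the four corner points manually (--corners)"
            )
        return np.linalg.solve(m, np.array([r1, r2]))

    corners_ds = np.array(
        [
            intersect("left", "top"),
            intersect("top", "right"),
            intersect("right", "bottom"),
            intersect("bottom", "left"),
        ]
    )
    # map downsampled coordinates back to full-resolution block centres
    corners = corners_ds * f + (f - 1) / 2.0
    corners[:, 0] = np.clip(corners[:, 0], 0, photo.width - 1)
    corners[:, 1] = np.clip(corners[:, 1], 0, photo.height - 1)
    try:
        return PlateQuad(_canonical_corners(corners), source="auto")
    except GeometryError as exc:
        raise PlateNotFoundError(
            f"plate not found: detected corners are degenerate ({exc}); "
            "enter the four corner points manually (--corners)"
        ) from exc


def rectify(photo: RasterImage, quad: PlateQuad) -> RasterImage:
    """Warp the quad content onto an upright rectangle.

    Output width is the rounded mean of the top/bottom edge spans, height the
    rounded mean of the left/right spans (plus one pixel, so a full-frame quad
    reproduces the input exactly).  Bilinear interpolation.
    """
    c = quad.corners
    area = 0.5 * abs(
        np.dot(c[:, 0], np.roll(c[:, 1], -1)) - np.dot(c[:, 1], np.roll(c[:, 0], -1))
    )
    if area <= 1.0:
        raise GeometryError("degenerate quad: collinear or near-collinear corners")
    top, right, bottom, left = quad.edge_lengths()
    out_w = int(round((top + bottom) / 2.0)) + 1
    out_h = int(round((left + right) / 2.0)) + 1
    if out_w < 2 or out_h < 2:
        raise GeometryError("quad is too small to rectify")

    dst_rect = np.array([[0, 0], [out_w - 1, 0], [out_w - 1, out_h - 1], [0, out_h - 1]], float)
    tform = _estimate_homography(dst_rect, quad.corners)
    if tform is None:
        raise GeometryError("degenerate quad: homography estimation failed")
    def _warp2d(plane: np.ndarray) -> np.ndarray:
        return warp(
            plane, inverse_map=tform, output_shape=(out_h, out_w),
            order=1, mode="edge", preserve_range=True,
        )

    if photo.is_color:
        out = np.dstack([_warp2d(photo.pixels[..., k]) for k in range(3)])
    else:
        out = _warp2d(photo.pixels)
    return RasterImage(np.clip(out, 0.0, 1.0), photo.colorspace)
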