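"""Spheroid shape scoring: area, circularity and ellipse-fit roughness.

A spheroid is segmented from a grayscale microscope image (threshold +
largest connected particle), and three shape parameters are measured:

* area — foreground pixel count, scaled by the pixel size;
* circularity — 4*pi*area / perimeter**2, 1 for a perfect disc, capped at 1;
* roughness — the area of the symmetric difference between the mask and its
  moment-fitted ellipse: spheroid area outside the ellipse plus ellipse
  area not covered by the spheroid.  Reported raw (px^2) and normalised by
  the mask area.

The fitted ellipse shares the mask's centroid and second central moments
and is rescaled so its area equals the mask area (the "fit ellipse"
convention of common imaging software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu


class EmptySegmentationError(ValueError):
    """No connected component survived thresholding and size filtering."""


@dataclass
class BinaryMask:
    """A single-object binary mask with an optional physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse: centroid, semi-axes and orientation.

    Orientation is the angle of the major axis measured from the +x (column)
    axis toward the +y (row) axis, in [0, pi).
    """

    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")


@dataclass
class MorphometricRecord:
    area: float
    perimeter: float
    circularity: float
    ellipse: EllipseFit
    roughness_raw: float
    roughness_norm: float
    image_id: str | None = None


def segment_spheroid(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_size: float = 50.0,
    fill_holes: bool = True,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Threshold the image and keep the largest sufficiently large particle.

    ``threshold_method`` is ``"otsu"`` or a fixed numeric threshold; pixels
    strictly above the threshold are foreground.  Components smaller than
    ``min_size`` (px^2) are dropped; holes in the surviving component are
    filled when ``fill_holes`` is set.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if np.ptp(image) == 0:
        raise ValueError("constant image cannot be thresholded")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        thr = threshold_otsu(image)
    else:
        thr = float(threshold_method)
    fg = image > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EmptySegmentationError("no foreground above threshold")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size)
    if keep.size == 0:
        raise EmptySegmentationError(
            f"no component reaches min_size={min_size} px^2"
        )
    best = keep[np.argmax(sizes[keep])] + 1
    mask = labels == best
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(mask, pixel_size=pixel_size)


def measure_area(mask: BinaryMask) -> float:
    """Foreground pixel count times pixel_size squared."""
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    return mask.n_foreground * mask.pixel_size**2


def measure_perimeter(mask: BinaryMask, simplify_tol: float = 0.8) -> float:
    """Sub-pixel boundary length from the marching-squares 0.5 iso-contour.

    The longest contour of the (zero-padded) mask is taken as the object
    outline.  The raw contour zig-zags along the pixel grid and overstates
    the length of smooth boundaries by ~5%, so it is simplified with
    Douglas-Peucker (deviation tolerance ``simplify_tol`` px) before the
    polygonal arc length is measured; straight edges are unaffected.
    """
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    padded = np.pad(mask.pixels.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found")

    def _arclen(poly: np.ndarray) -> float:
        return float(np.hypot(*np.diff(poly, axis=0).T).sum())

    outline = max(contours, key=_arclen)
    if simplify_tol > 0:
        outline = measure.approximate_polygon(outline, simplify_tol)
    return _arclen(outline) * mask.pixel_size


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter^2, capped at 1 (rasterized discs can overshoot)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def fit_ellipse(mask: BinaryMask) -> EllipseFit:
    """Moment-equivalent ellipse with its area matched to the mask area.

    The semi-axes come from the eigenvalues of the covariance matrix of the
    foreground pixel coordinates (a solid ellipse with semi-axes a, b has
    coordinate variances a^2/4 and b^2/4 along its principal axes); they are
    then rescaled by a common factor so pi*a*b equals the pixel-count area.
    """
    if mask.n_foreground < 5:
        raise ValueError("need at least 5 foreground pixels")
    coords = np.argwhere(mask.pixels).astype(float)  # (row, col)
    center = coords.mean(axis=0)
    cov = np.cov(coords, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-9:
        raise ValueError("degenerate (collinear) pixel set")
    a0 = 2.0 * np.sqrt(evals[1])
    b0 = 2.0 * np.sqrt(evals[0])
    scale = np.sqrt(mask.n_foreground / (np.pi * a0 * b0))
    major_vec = evecs[:, 1]  # (d_row, d_col)
    theta = np.arctan2(major_vec[0], major_vec[1]) % np.pi
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_major=float(a0 * scale),
        semi_minor=float(b0 * scale),
        orientation=float(theta),
    )


def rasterize_ellipse(ellipse: EllipseFit, shape: tuple[int, int]) -> np.ndarray:
    """Boolean grid of pixel centers inside the ellipse."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - ellipse.center[0]
    dx = cc - ellipse.center[1]
    ct, st = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2 <= 1.0


def roughness(mask: BinaryMask, ellipse: EllipseFit) -> tuple[float, float]:
    """Symmetric-difference roughness against the fitted ellipse.

    ``roughness_raw`` is the area of (mask \\ ellipse) plus (ellipse \\ mask)
    with the ellipse rasterized on the mask's own pixel grid;
    ``roughness_norm`` divides by the mask area.
    """
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    ell = rasterize_ellipse(ellipse, mask.pixels.shape)
    sym_diff = int(np.logical_xor(mask.pixels, ell).sum())
    raw = sym_diff * mask.pixel_size**2
    return raw, raw / measure_area(mask)


def morphometrics(
    image_or_mask: np.ndarray | BinaryMask,
    threshold_method: str | float = "otsu",
    min_size: float = 50.0,
    fill_holes: bool = True,
    pixel_size: float = 1.0,
    image_id: str | None = None,
) -> MorphometricRecord:
    """Full shape-scoring pipeline for one spheroid image or mask."""
    if isinstance(image_or_mask, BinaryMask):
        mask = image_or_mask
    elif np.asarray(image_or_mask).dtype == bool:
        mask = BinaryMask(image_or_mask, pixel_size=pixel_size)
    else:
        mask = segment_spheroid(
            image_or_mask,
            threshold_method=threshold_method,
            min_size=min_size,
            fill_holes=fill_holes,
            pixel_size=pixel_size,
        )
    area = measure_area(mask)
    perim = measure_perimeter(mask)
    circ = circularity(area, perim)
    ell = fit_ellipse(mask)
    rough_raw, rough_norm = roughness(mask, ell)
    return MorphometricRecord(
        area=area,
        perimeter=perim,
        circularity=circ,
        ellipse=ell,
        roughness_raw=rough_raw,
        roughness_norm=rough_norm,
        image_id=image_id,
    )
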