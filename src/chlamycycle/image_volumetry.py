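"""Cell volume from a single bright-field micrograph.

Chlamydomonas cells are axisymmetric about their long axis, so a single
cross-section determines the volume: the image is thresholded, the largest
connected component is taken as the cell, the principal axes of the mask give
the long (La) and short (Lb) full axis lengths, and the volume follows by
rotating the half-width profile h(x) about the long axis,

    V = pi * integral h(x)^2 dx   (disk integration),

with the prolate-spheroid closed form V = (4/3) pi (La/2) (Lb/2)^2 as the
analytic reference for elliptical contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "CellImage",
    "ContourResult",
    "NoCellDetectedError",
    "binarize",
    "extract_contour",
    "volume_of_revolution",
    "spheroid_volume",
    "measure_image",
]


class NoCellDetectedError(ValueError):
    """Raised when thresholding finds no foreground object."""


@dataclass
class CellImage:
    """Grayscale raster of one cell plus the pixel-size calibration."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ContourResult:
    """Geometry extracted from a binary cell mask (lengths in um)."""

    mask: np.ndarray
    area: float
    long_axis: float
    short_axis: float
    orientation: float
    #: (position along long axis, half-width) pairs at pixel resolution
    axis_profile: np.ndarray

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("area must be positive")
        if not self.short_axis > 0 or self.long_axis < self.short_axis:
            raise ValueError("need long_axis >= short_axis > 0")


def binarize(image: CellImage, threshold: float | str = "otsu") -> np.ndarray:
    """Threshold the raster and keep the largest foreground component.

    ``threshold`` is either a fixed intensity or ``"otsu"``.  Holes inside
    the component are filled; all other components are discarded.
    """
    arr = image.pixels
    if threshold == "otsu":
        if np.ptp(arr) == 0:
            raise NoCellDetectedError("uniform image: no cell contour found")
        thr = float(filters.threshold_otsu(arr))
    else:
        thr = float(threshold)
    fg = arr > thr
    if not fg.any():
        raise NoCellDetectedError(f"no pixels above threshold {thr:g}")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoCellDetectedError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    return ndimage.binary_fill_holes(mask)


def extract_contour(mask: np.ndarray, pixel_size: float) -> ContourResult:
    """Area, principal axes and half-width profile of a single-cell mask.

    The axes come from the second central moments of the mask (as for a
    regionprops ellipse); the half-width profile is built by projecting the
    foreground pixels onto the long axis and measuring the slab area per unit
    length, which is robust to rotation without resampling the raster.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must contain exactly one component, found {n}")
    props = measure.regionprops(labels.astype(int))[0]
    area = float(props.area) * pixel_size**2
    long_axis = float(props.axis_major_length) * pixel_size
    short_axis = float(props.axis_minor_length) * pixel_size
    orientation = float(props.orientation)

    # project pixel centres onto the principal (long) axis
    coords = np.argwhere(mask).astype(float)  # (row, col)
    centred = coords - coords.mean(axis=0)
    cov = np.cov(centred.T)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]  # unit vector of the long axis
    x = centred @ u * pixel_size  # position along long axis, um

    # bins one pixel wide, centred so that an axis-aligned pixel grid falls
    # on bin centres rather than edges (avoids aliasing at orientation 0)
    lo, hi = float(x.min()), float(x.max())
    nbins = max(1, int(round((hi - lo) / pixel_size)) + 1)
    edges = np.linspace(lo - pixel_size / 2, hi + pixel_size / 2, nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    dx = edges[1] - edges[0]
    # slab area per unit length = full width; half-width is half of it
    half_widths = counts * pixel_size**2 / (2.0 * dx)
    positions = 0.5 * (edges[:-1] + edges[1:])
    profile = np.column_stack([positions, half_widths])

    return ContourResult(
        mask=mask,
        area=area,
        long_axis=long_axis,
        short_axis=short_axis,
        orientation=orientation,
        axis_profile=profile,
    )


def volume_of_revolution(contour: ContourResult) -> float:
    """Disk-integrated volume: V = pi * trapz(h(x)^2, x) about the long axis."""
    profile = np.asarray(contour.axis_profile, dtype=float)
    if profile.size == 0:
        raise ValueError("axis profile is empty")
    x, h = profile[:, 0], profile[:, 1]
    if np.all(h == 0):
        raise ValueError("degenerate profile: all half-widths are zero")
    if x.size == 1:
        # single slab: treat as a disk of thickness one pixel
        return float(math.pi * h[0] ** 2 * (contour.long_axis))
    # extend to zero half-width at the tips so the caps are closed
    dx = x[1] - x[0]
    x_ext = np.concatenate([[x[0] - dx / 2], x, [x[-1] + dx / 2]])
    h_ext = np.concatenate([[0.0], h, [0.0]])
    return float(math.pi * np.trapezoid(h_ext**2, x_ext))


def spheroid_volume(La: float, Lb: float) -> float:
    """Prolate-spheroid volume from full axis lengths: (4/3)pi(La/2)(Lb/2)^2."""
    if not Lb > 0 or La < Lb:
        raise ValueError(f"need La >= Lb > 0, got La={La}, Lb={Lb}")
    return (4.0 / 3.0) * math.pi * (La / 2.0) * (Lb / 2.0) ** 2


def measure_image(
    image: CellImage, threshold: float | str = "otsu"
) -> dict:
    """End-to-end volumetry of one image.

    Returns a flat record with the mask area, full axis lengths, and both
    volume estimates (disk integration and spheroid closed form), all in um
    units.
    """
    mask = binarize(image, threshold)
    contour = extract_contour(mask, image.pixel_size)
    return {
        "area_um2": contour.area,
        "La_um": contour.long_axis,
        "Lb_um": contour.short_axis,
        "orientation_rad": contour.orientation,
        "volume_um3": volume_of_revolution(contour),
        "volume_spheroid_um3": spheroid_volume(
            contour.long_axis, contour.short_axis
        ),
    }
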