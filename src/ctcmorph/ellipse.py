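"""Shape pipeline: contrast stretch, contour tracing, best-fit ellipse, EF.

The elongation factor (EF) quantifies how far a cell departs from a circle:
it is the ratio of the major to the minor axis of the ellipse fitted to the
traced cell outline, so EF = 1 for a perfect circle and grows with
elongation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

from .errors import ContourError, DegenerateImageError, EllipseFitError
from .segmentation import cluster_threshold, label_particles, stabilized_threshold

_STRUCT_3x3 = np.ones((3, 3), dtype=bool)


def contrast_stretch(channel: np.ndarray, percentiles=(1.0, 99.0)) -> np.ndarray:
    """Linear stretch of the given intensity percentiles to [0, 255] (uint8)."""
    channel = np.asarray(channel)
    lo, hi = np.percentile(channel, percentiles)
    if hi <= lo:
        raise DegenerateImageError("constant image: contrast stretch undefined")
    out = (channel.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_for_contour(channel: np.ndarray, *, percentiles=(1.0, 99.0),
                           smooth: bool = True, erosions: int = 3,
                           dilations: int = 1, stabilize: bool = True) -> np.ndarray:
    """Binarize a channel for outline tracing.

    Contrast-enhances (percentile linear stretch), auto-thresholds with the
    same two-class histogram clustering used for area measurement
    (stabilized against tiny-object histograms unless ``stabilize=False``),
    then — by default — smooths edges with three 3x3 binary erosions
    followed by one dilation. Pass ``smooth=False`` to obtain the raw
    thresholded mask.
    """
    stretched = contrast_stretch(channel, percentiles)
    if stabilize:
        mask, _ = stabilized_threshold(stretched)
    else:
        mask, _ = cluster_threshold(stretched)
    if smooth:
        if erosions:
            mask = ndimage.binary_erosion(mask, structure=_STRUCT_3x3,
                                          iterations=erosions, border_value=0)
        if dilations and mask.any():
            mask = ndimage.binary_dilation(mask, structure=_STRUCT_3x3,
                                           iterations=dilations, border_value=0)
    return mask


# Moore neighborhood in clockwise order (row, col offsets), starting west.
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def _trace_moore(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace, clockwise, from a raster-first pixel.

    ``start`` must be the first foreground pixel of its particle in raster
    order (so the pixel to its west is background). The tracer is a
    deterministic automaton over (pixel, scan-start) states; it stops when a
    state repeats and returns the boundary cycle, rotated so the
    top-left-most cycle pixel comes first.
    """
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    # ``back`` = direction index such that the clockwise neighbor scan
    # starts at back + 1; initially the west neighbor (background).
    cur, back = start, 0
    seen: dict[tuple, int] = {}
    contour: list[tuple[int, int]] = []
    while (cur, back) not in seen:
        seen[(cur, back)] = len(contour)
        contour.append(cur)
        nxt = None
        for step in range(1, 9):
            d = (back + step) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                nxt = (nr, nc, d)
                break
        if nxt is None:
            return contour  # isolated pixel
        nr, nc, d = nxt
        cur = (nr, nc)
        # resume the clockwise scan one step past the pixel we came around:
        # first direction checked from the new pixel is (d + 6) % 8
        back = (d + 5) % 8
    cycle = contour[seen[(cur, back)]:]
    pivot = min(range(len(cycle)), key=lambda i: cycle[i])
    return cycle[pivot:] + cycle[:pivot]


def trace_longest_contour(mask: np.ndarray, *, min_points: int = 5) -> np.ndarray:
    """Trace every particle's boundary and return the longest contour.

    Boundaries are traced with clockwise Moore-neighbor tracing starting at
    each particle's top-left-most pixel. The contour with the most points
    wins; ties go to the particle appearing first in raster order. Returns
    an (N, 2) int array of (row, col) points.

    Raises
    ------
    ContourError
        if the mask is empty or the longest contour has fewer than
        ``min_points`` points.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContourError("empty mask: no contour to trace")
    lab = label_particles(mask, connectivity=8)
    best: list[tuple[int, int]] | None = None
    for k in range(1, lab.n + 1):
        pmask = lab.particle_mask(k)
        flat = int(np.flatnonzero(pmask)[0])
        start = (flat // mask.shape[1], flat % mask.shape[1])
        contour = _trace_moore(pmask, start)
        if best is None or len(contour) > len(best):
            best = contour
    assert best is not None
    if len(best) < min_points:
        raise ContourError(
            f"longest contour has {len(best)} point(s); need >= {min_points} for a fit")
    return np.asarray(best, dtype=np.int64)


@dataclass
class EllipseFit:
    """Best-fit ellipse: center (row, col), full axis lengths, orientation.

    ``theta_deg`` is the major-axis orientation in degrees, in [0, 180),
    measured from the image column axis toward increasing rows.
    """

    center: tuple[float, float]
    major_px: float
    minor_px: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not (self.major_px >= self.minor_px > 0):
            raise EllipseFitError(
                f"invalid axes: major={self.major_px}, minor={self.minor_px}")


def fit_best_ellipse(contour: np.ndarray,
                     boundary_offset: float = 0.0) -> EllipseFit:
    """Direct least-squares conic fit (ellipse-constrained) to contour points.

    Deterministic for a fixed contour; exact (to numerical precision) when
    the points lie on a true ellipse.

    When the contour is a chain of boundary *pixel centers* traced from a
    rasterized mask, the continuous object boundary lies on average about
    half a pixel outside those centers; pass ``boundary_offset=0.5`` to add
    that offset back onto both fitted semi-axes. Leave it at 0 for points
    that lie on the curve itself.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError("need >= 5 (row, col) contour points")
    # EllipseModel works in (x, y); use x = col, y = row so theta is measured
    # from the column axis.
    xy = pts[:, ::-1]
    model = EllipseModel.from_estimate(xy)
    if not model:
        raise EllipseFitError("direct conic fit failed (degenerate points?)")
    xc, yc = (float(v) for v in model.center)
    a, b = (float(v) for v in model.axis_lengths)  # semi-axes, major first
    if not (np.isfinite(a) and np.isfinite(b)) or b <= 0:
        raise EllipseFitError("fit returned non-positive axes")
    a += boundary_offset
    b += boundary_offset
    return EllipseFit(center=(yc, xc), major_px=2.0 * a, minor_px=2.0 * b,
                      theta_deg=math.degrees(float(model.theta)) % 180.0)


def fit_moments_ellipse(mask: np.ndarray) -> EllipseFit:
    """Moment-equivalent ellipse of a filled particle mask (fallback method).

    Axes are those of the ellipse with the same normalized second central
    moments as the foreground region.
    """
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size < 5:
        raise EllipseFitError("mask too small for a moments fit")
    cy, cx = rr.mean(), cc.mean()
    mrr = ((rr - cy) ** 2).mean()
    mcc = ((cc - cx) ** 2).mean()
    mrc = ((rr - cy) * (cc - cx)).mean()
    common = math.sqrt((mrr - mcc) ** 2 + 4 * mrc ** 2)
    lam1 = (mrr + mcc + common) / 2.0
    lam2 = (mrr + mcc - common) / 2.0
    if lam2 <= 0:
        raise EllipseFitError("degenerate moments (collinear mask)")
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    theta = 0.5 * math.atan2(2 * mrc, mcc - mrr)
    return EllipseFit(center=(cy, cx), major_px=major, minor_px=minor,
                      theta_deg=math.degrees(theta) % 180.0)


def elongation_factor(fit: EllipseFit) -> float:
    """EF = major axis / minor axis of the best-fit ellipse (>= 1)."""
    return fit.major_px / fit.minor_px
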