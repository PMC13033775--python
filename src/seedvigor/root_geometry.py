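"""Calibrated radicle length from instance segmentation masks.

The estimator: trace the outer boundary of the mask (8-connected Moore
boundary following on the largest connected component, interior holes
filled), sum Euclidean step lengths around the closed contour to get the
contour pixel length ``Sp``, convert to physical units with the scale
calibration ``r`` (mm/px), and report half the physical contour length as
the radicle length::

    perimeter = Sp * r        [mm]
    L         = Sp * r / 2    [mm]

For an elongated, curved structure such as an early radicle the outer
contour runs up one side and down the other, so half of it approximates the
centerline arc length (with a small additive excess of about half the tube
circumference at the two rounded ends, ~ pi * width / 2 pixels in total).
Unlike a straight-line tip-to-base measurement this follows the natural
curvature of the root, and unlike medial-axis skeletonization it needs no
pruning heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground pixels."""


@dataclass
class SegmentationMask:
    """One binary instance mask tied to a frame, dish, and instance id."""

    data: np.ndarray
    frame_index: int = 0
    dish: str = ""
    instance_id: int = 0
    cls: str = "radicle"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be a 2-D binary array")


@dataclass
class Contour:
    """Closed outer boundary as an ordered pixel path (row, col).

    Consecutive points are 8-neighbors; the last point connects back to the
    first.  ``degenerate`` marks contours with fewer than 3 points (a single
    pixel, or a mask too small to trace), for which the path length is 0.
    """

    points: np.ndarray
    closed: bool = True
    connectivity: int = 8
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical length per pixel, from a reference object of known size."""

    r: float  # mm per pixel
    reference_id: str = ""
    reference_length_mm: Optional[float] = None
    reference_pixels: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or self.r <= 0:
            raise ValueError(f"scale r must be positive, got {self.r}")


@dataclass(frozen=True)
class RootLengthMeasure:
    """Half-outer-contour length estimate for one instance."""

    Sp: float  # contour pixel path length (px)
    perimeter_mm: float  # Sp * r
    L_mm: float  # Sp * r / 2


def _as_array(mask: Union[SegmentationMask, np.ndarray]) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


# Moore neighborhood in clockwise order for image coordinates (row down):
# N, NE, E, SE, S, SW, W, NW
_CLOCKWISE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _trace_moore(grid: np.ndarray) -> np.ndarray:
    """Moore boundary following on a padded boolean grid.

    Starts at the first foreground pixel in raster order (whose west
    neighbor is guaranteed background) and walks the outer boundary
    clockwise, scanning each pixel's Moore neighborhood clockwise from the
    backtrack position.  Terminates when the initial (pixel, successor)
    transition repeats.
    """
    rows, cols = np.nonzero(grid)
    start = (int(rows[0]), int(cols[0]))
    prev = (start[0], start[1] - 1)  # west neighbor; background by raster order

    contour = [start]
    current = start
    second = None
    max_steps = 4 * grid.size + 8
    for _ in range(max_steps):
        neighbors = [(current[0] + dr, current[1] + dc) for dr, dc in _CLOCKWISE]
        i = neighbors.index(prev)
        nxt = None
        for j in range(1, 9):
            cand = neighbors[(i + j) % 8]
            if grid[cand]:
                nxt = cand
                # backtrack = last background pixel examined before nxt
                prev = neighbors[(i + j - 1) % 8]
                break
        if nxt is None:  # isolated single pixel
            return np.array(contour, dtype=float)
        if second is None:
            second = nxt
        elif current == start and nxt == second:
            return np.array(contour, dtype=float)
        contour.append(nxt)
        current = nxt
    raise RuntimeError("boundary tracing failed to terminate")  # pragma: no cover


def extract_outer_contour(mask: Union[SegmentationMask, np.ndarray]) -> Contour:
    """Outer boundary of the largest connected component of a mask.

    Smaller foreground fragments are discarded (their count is reported via
    a warning) and interior holes are filled before tracing, so the result
    is always the single outer boundary.

    Raises :class:`EmptyMaskError` for an all-background mask.
    """
    arr = _as_array(mask)
    if not arr.any():
        raise EmptyMaskError("mask has no foreground pixels")

    labeled, n = ndimage.label(arr, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(arr, labeled, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        arr = labeled == keep
        warnings.warn(
            f"mask has {n} components; kept largest, discarded {n - 1}",
            stacklevel=2,
        )
    arr = ndimage.binary_fill_holes(arr)

    padded = np.zeros((arr.shape[0] + 2, arr.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = arr
    pts = _trace_moore(padded) - 1.0
    degenerate = len(pts) < 3
    return Contour(points=pts, degenerate=degenerate)


def contour_pixel_length(contour: Contour) -> float:
    """Contour path length Sp: sum of Euclidean steps including the closing
    segment.  Axis steps contribute 1, diagonal steps sqrt(2).  Degenerate
    contours (< 3 points) have Sp = 0.
    """
    pts = contour.points
    if contour.degenerate or len(pts) < 3:
        if contour.degenerate:
            warnings.warn("degenerate contour: Sp set to 0", stacklevel=2)
        return 0.0
    diffs = np.diff(pts, axis=0)
    length = float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))
    if contour.closed:
        length += float(np.hypot(*(pts[0] - pts[-1])))
    return length


def calibrate_scale(
    reference_pixels: float,
    reference_length_mm: float,
    reference_id: str = "",
) -> ScaleCalibration:
    """Build a scale calibration from a reference object of known size."""
    if reference_pixels <= 0 or reference_length_mm <= 0:
        raise ValueError("reference pixels and length must both be positive")
    return ScaleCalibration(
        r=reference_length_mm / reference_pixels,
        reference_id=reference_id,
        reference_length_mm=reference_length_mm,
        reference_pixels=reference_pixels,
    )


def estimate_root_length(
    mask: Union[SegmentationMask, np.ndarray],
    calibration: ScaleCalibration,
) -> RootLengthMeasure:
    """Estimate radicle length as half the calibrated outer-contour length.

    Degenerate masks (single pixel, or tiny fragments that cannot be traced)
    yield L = 0.  A calibration is mandatory: lengths are always physical.
    """
    if not isinstance(calibration, ScaleCalibration):
        raise TypeError("calibration must be a ScaleCalibration (no implicit units)")
    contour = extract_outer_contour(mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp = contour_pixel_length(contour)
    perimeter = sp * calibration.r
    return RootLengthMeasure(Sp=sp, perimeter_mm=perimeter, L_mm=perimeter / 2.0)
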