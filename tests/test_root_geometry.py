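"""Contour tracing and the half-outer-contour length estimator, checked
against an independently written boundary-following oracle."""

import numpy as np
import pytest

from seedvigor.root_geometry import (
    Contour,
    EmptyMaskError,
    ScaleCalibration,
    SegmentationMask,
    calibrate_scale,
    contour_pixel_length,
    estimate_root_length,
    extract_outer_contour,
)
from seedvigor.synthetic import rasterize_centerline

CAL = ScaleCalibration(r=0.1)


# ---- independent oracle: counterclockwise radial-sweep boundary walk ---------

_CCW = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def oracle_contour_length(mask):
    """Boundary length by an independent counterclockwise Moore walk.

    Written separately from the package tracer (opposite orientation,
    different bookkeeping); path length is orientation-invariant, so both
    must agree exactly.
    """
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (np.argmax(sizes) + 1)
    mask = ndimage.binary_fill_holes(mask)
    g = np.pad(mask, 1)
    rs, cs = np.nonzero(g)
    start = (rs[0], cs[0])
    path = [start]
    cur = start
    # counterclockwise scan starting from the neighbor after the backtrack
    back = (start[0], start[1] - 1)
    second = None
    for _ in range(8 * g.size):
        idx = [(cur[0] + dr, cur[1] + dc) for dr, dc in _CCW].index(back)
        nxt = None
        for step in range(1, 9):
            cand_off = _CCW[(idx - step) % 8]  # walk the ring backwards => CCW
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if g[cand]:
                nxt = cand
                back = (cur[0] + _CCW[(idx - step + 1) % 8][0],
                        cur[1] + _CCW[(idx - step + 1) % 8][1])
                break
        if nxt is None:
            return 0.0  # single pixel
        if second is None:
            second = nxt
        elif cur == start and nxt == second:
            break
        path.append(nxt)
        cur = nxt
    pts = np.array(path, float)
    if len(pts) < 3:
        return 0.0
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _random_blob(rng, size=32):
    mask = rng.random((size, size)) < 0.25
    from scipy import ndimage

    mask = ndimage.binary_dilation(mask, iterations=rng.integers(1, 3))
    return mask


def test_tracer_matches_independent_oracle_on_random_masks(rng):
    checked = 0
    for _ in range(60):
        mask = _random_blob(rng, size=int(rng.integers(8, 33)))
        if not mask.any():
            continue
        with pytest.warns(UserWarning) if _n_components(mask) > 1 else _nullcontext():
            contour = extract_outer_contour(mask)
        sp = contour_pixel_length(contour) if not contour.degenerate else 0.0
        assert sp == pytest.approx(oracle_contour_length(mask), abs=1e-9)
        checked += 1
    assert checked >= 50


def _n_components(mask):
    from scipy import ndimage

    return ndimage.label(mask, structure=np.ones((3, 3)))[1]


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def test_filled_rectangle_contour_visits_exactly_the_border():
    mask = np.zeros((20, 30), bool)
    mask[4:14, 5:25] = True
    contour = extract_outer_contour(mask)
    visited = {tuple(p) for p in contour.points.astype(int)}
    border = {
        (r, c)
        for r in range(4, 14)
        for c in range(5, 25)
        if r in (4, 13) or c in (5, 24)
    }
    assert visited == border
    # 10 x 20 rectangle: Sp = 2*(10-1) + 2*(20-1)
    assert contour_pixel_length(contour) == pytest.approx(2 * 9 + 2 * 19)


def test_hole_is_ignored_by_outer_contour():
    mask = np.zeros((25, 25), bool)
    mask[3:22, 3:22] = True
    holed = mask.copy()
    holed[10:14, 10:14] = False
    a = contour_pixel_length(extract_outer_contour(mask))
    b = contour_pixel_length(extract_outer_contour(holed))
    assert a == pytest.approx(b)


def test_single_pixel_is_degenerate_with_zero_length():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    contour = extract_outer_contour(mask)
    assert contour.degenerate
    with pytest.warns(UserWarning, match="degenerate"):
        assert contour_pixel_length(contour) == 0.0
    assert estimate_root_length(mask, CAL).L_mm == 0.0


def test_unit_square_contour_has_length_four():
    contour = Contour(points=[(0, 0), (0, 1), (1, 1), (1, 0)])
    assert contour_pixel_length(contour) == pytest.approx(4.0)


def test_contour_length_is_direction_invariant():
    mask = np.zeros((30, 30), bool)
    mask[5:20, 8:26] = True
    contour = extract_outer_contour(mask)
    reversed_ = Contour(points=contour.points[::-1])
    assert contour_pixel_length(reversed_) == pytest.approx(contour_pixel_length(contour))


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        extract_outer_contour(np.zeros((10, 10), bool))


def test_missing_calibration_refused():
    mask = np.ones((5, 8), bool)
    with pytest.raises(TypeError):
        estimate_root_length(mask, 0.1)  # a bare float is not a calibration


def test_straight_dilated_polyline_estimate():
    """200 px centerline, 8 px width, r=0.1: half-perimeter lands within
    [20.0, 21.5] mm (the rounded tube ends add ~width/2 * pi * r / 2)."""
    pts = np.column_stack([np.full(201, 20.0), np.arange(201) + 10.0])
    inst = rasterize_centerline(pts, 8)
    L = estimate_root_length(inst.mask, CAL).L_mm
    assert 20.0 <= L <= 21.5


def test_length_is_linear_in_scale():
    pts = np.column_stack([np.full(101, 15.0), np.arange(101) + 5.0])
    mask = rasterize_centerline(pts, 7).mask
    L1 = estimate_root_length(mask, ScaleCalibration(r=0.1)).L_mm
    L2 = estimate_root_length(mask, ScaleCalibration(r=0.2)).L_mm
    assert L2 == pytest.approx(2 * L1)


@pytest.mark.parametrize("angle_deg", [0, 45, 90])
def test_rotation_robustness_of_bar_length(angle_deg):
    theta = np.deg2rad(angle_deg)
    t = np.arange(0, 150, 1.0)
    pts = np.column_stack([100 + t * np.sin(theta), 100 + t * np.cos(theta)])
    mask = rasterize_centerline(pts, 7).mask
    L = estimate_root_length(mask, CAL).L_mm
    # digitization tolerance: estimate within 10% of the 0-degree estimate
    pts0 = np.column_stack([np.full(150, 100.0), 100 + t])
    L0 = estimate_root_length(rasterize_centerline(pts0, 7).mask, CAL).L_mm
    assert abs(L - L0) / L0 < 0.10


def test_calibrate_scale():
    assert calibrate_scale(500, 50).r == pytest.approx(0.1)
    assert calibrate_scale(1, 1).r == 1.0
    with pytest.raises(ValueError):
        calibrate_scale(0, 10)
    with pytest.raises(ValueError):
        calibrate_scale(10, -1)


def test_reference_object_round_trip():
    """Measuring a straight ruler with its own calibration recovers its length."""
    pts = np.column_stack([np.full(501, 30.0), np.arange(501) + 10.0])
    mask = rasterize_centerline(pts, 9).mask
    cal = calibrate_scale(reference_pixels=500, reference_length_mm=50.0)
    L = estimate_root_length(mask, cal).L_mm
    assert L == pytest.approx(50.0, rel=0.05)


def test_fragments_discarded_with_warning():
    mask = np.zeros((40, 40), bool)
    mask[5:25, 5:12] = True  # large component
    mask[30:32, 30:32] = True  # fragment
    with pytest.warns(UserWarning, match="components"):
        contour = extract_outer_contour(mask)
    only = np.zeros_like(mask)
    only[5:25, 5:12] = True
    assert contour_pixel_length(contour) == pytest.approx(
        contour_pixel_length(extract_outer_contour(only))
    )


def test_validation_regression_property():
    """On 100+ synthetic radicles spanning 5-50 mm the estimator regresses
    onto truth with slope in [0.95, 1.10] and R^2 >= 0.978."""
    from seedvigor.stats_eval import validation_regression
    from seedvigor.synthetic import make_validation_radicles

    pairs = make_validation_radicles(100, seed=11)
    est = [estimate_root_length(m, CAL).L_mm for m, _ in pairs]
    ref = [t for _, t in pairs]
    fit = validation_regression(est, ref)
    assert 0.95 <= fit.slope <= 1.10
    assert fit.r2 >= 0.978
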