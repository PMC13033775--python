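"""Rasterization of tray frames: seed-body ellipses and dilated radicle
centerlines on noisy dark filter paper, plus per-instance masks and polygon
labels.  Also provides the standalone curved-radicle generator used for
validating the length estimator against known centerline arc lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .. import labels as lbl
from .growth import GrowthModel, SeedTrajectory, simulate_seed, substream
from .plan import Arm, TreatmentPlan

_MIN_RENDER_PX = 2.0  # radicles shorter than this stay sub-pixel: not drawn


@dataclass
class SeedPlacement:
    slot: int
    center: Tuple[float, float]  # (row, col) px
    axes: Tuple[float, float]  # ellipse semi-axes (px)
    orientation: float  # rad
    trajectory: SeedTrajectory


@dataclass
class DishState:
    dish_id: str
    arm: Arm
    replicate: int
    placements: List[SeedPlacement]
    image_size: Tuple[int, int]
    scale_r: float


@dataclass
class RenderedInstance:
    """One instance as a cropped mask plus its (row, col) origin."""

    cls: int  # lbl.CLASS_SEED or lbl.CLASS_RADICLE
    slot: int
    offset: Tuple[int, int]
    mask: np.ndarray  # bool crop

    def centroid(self) -> Tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return (float(rr.mean()) + self.offset[0], float(cc.mean()) + self.offset[1])

    def full_mask(self, image_size: Sequence[int]) -> np.ndarray:
        out = np.zeros(tuple(image_size[:2]), dtype=bool)
        r0, c0 = self.offset
        out[r0 : r0 + self.mask.shape[0], c0 : c0 + self.mask.shape[1]] = self.mask
        return out


@dataclass
class FrameRender:
    image: np.ndarray  # uint8 (H, W)
    instances: List[RenderedInstance]
    label_instances: List[lbl.LabelInstance]


def _ellipse_mask(center, axes, orientation, image_size) -> RenderedInstance:
    rr, cc = draw_ellipse(
        center[0], center[1], axes[0], axes[1], shape=tuple(image_size), rotation=orientation
    )
    r0, c0 = int(rr.min()), int(cc.min())
    crop = np.zeros((int(rr.max()) - r0 + 1, int(cc.max()) - c0 + 1), dtype=bool)
    crop[rr - r0, cc - c0] = True
    return RenderedInstance(cls=lbl.CLASS_SEED, slot=-1, offset=(r0, c0), mask=crop)


def rasterize_centerline(points_px: np.ndarray, width_px: int) -> RenderedInstance:
    """Dilate a centerline polyline (absolute (row, col) coords) into a tube mask."""
    radius = max(1, (int(width_px) - 1) // 2)
    r0 = int(np.floor(points_px[:, 0].min())) - radius - 1
    c0 = int(np.floor(points_px[:, 1].min())) - radius - 1
    h = int(np.ceil(points_px[:, 0].max())) - r0 + radius + 2
    w = int(np.ceil(points_px[:, 1].max())) - c0 + radius + 2
    crop = np.zeros((h, w), dtype=bool)
    rows = np.clip(np.round(points_px[:, 0]).astype(int) - r0, 0, h - 1)
    cols = np.clip(np.round(points_px[:, 1]).astype(int) - c0, 0, w - 1)
    crop[rows, cols] = True
    crop = ndimage.binary_dilation(crop, structure=disk(radius))
    return RenderedInstance(cls=lbl.CLASS_RADICLE, slot=-1, offset=(r0, c0), mask=crop)


def place_seeds(
    plan: TreatmentPlan,
    model: GrowthModel,
    arm: Arm,
    replicate: int,
    master_seed: int,
    jitter_px: float = 5.0,
    max_retries: int = 5,
) -> DishState:
    """Place the dish's seeds on the grid (with jitter) and simulate them.

    Placement is validated at full growth: if any two instances would ever
    overlap, the dish is re-jittered up to ``max_retries`` times and then
    fails loudly.  With the default coiled geometry the first attempt
    virtually always succeeds (each radicle is confined to its own cell).
    """
    centers = plan.slot_centers()
    dish_id = f"{arm.name}-r{replicate}"
    trajectories = [
        simulate_seed(model, arm, master_seed, replicate, slot, plan.frame_times_h, plan.scale_r)
        for slot in range(plan.seeds_per_dish)
    ]
    for attempt in range(max_retries):
        rng = substream(master_seed, arm.name, replicate, "placement", attempt)
        placements = []
        for slot in range(plan.seeds_per_dish):
            jitter = rng.uniform(-jitter_px, jitter_px, size=2)
            center = (centers[slot][0] + jitter[0], centers[slot][1] + jitter[1])
            axes = (rng.uniform(24.0, 29.0), rng.uniform(17.0, 21.0))
            placements.append(
                SeedPlacement(
                    slot=slot,
                    center=center,
                    axes=axes,
                    orientation=rng.uniform(0, np.pi),
                    trajectory=trajectories[slot],
                )
            )
        state = DishState(
            dish_id=dish_id,
            arm=arm,
            replicate=replicate,
            placements=placements,
            image_size=plan.image_size,
            scale_r=plan.scale_r,
        )
        if not _any_overlap(state):
            return state
    raise RuntimeError(
        f"dish {dish_id}: instances still overlap after {max_retries} re-jitters; "
        "reduce radicle width/length or enlarge the tray"
    )


def _frame_instances(state: DishState, frame_index: int) -> List[RenderedInstance]:
    out = []
    for p in state.placements:
        seed_inst = _ellipse_mask(p.center, p.axes, p.orientation, state.image_size)
        seed_inst.slot = p.slot
        out.append(seed_inst)
        length_px = p.trajectory.lengths_mm[frame_index] / state.scale_r
        if length_px >= _MIN_RENDER_PX:
            line = p.trajectory.centerline_at(length_px) + np.asarray(p.center)
            inst = rasterize_centerline(line, p.trajectory.width_px)
            inst.slot = p.slot
            out.append(inst)
    return out


def _any_overlap(state: DishState) -> bool:
    last = len(state.placements[0].trajectory.frame_times_h) - 1
    occupancy = np.zeros(state.image_size, dtype=np.uint8)
    for inst in _frame_instances(state, last):
        r0, c0 = inst.offset
        occupancy[r0 : r0 + inst.mask.shape[0], c0 : c0 + inst.mask.shape[1]] += inst.mask
    return bool((occupancy > 1).any())


def render_frame(
    state: DishState,
    frame_index: int,
    master_seed: int,
    background_level: float = 18.0,
    background_noise: float = 5.0,
) -> FrameRender:
    """Render one capture: image, per-instance masks, and polygon labels."""
    h, w = state.image_size
    noise_rng = substream(master_seed, state.arm.name, state.replicate, "noise", frame_index)
    img = noise_rng.normal(background_level, background_noise, size=(h, w))

    instances = _frame_instances(state, frame_index)
    label_instances = []
    for inst in instances:
        r0, c0 = inst.offset
        window = img[r0 : r0 + inst.mask.shape[0], c0 : c0 + inst.mask.shape[1]]
        if inst.cls == lbl.CLASS_SEED:
            level = noise_rng.normal(170.0, 8.0)
        else:
            level = noise_rng.normal(205.0, 5.0)
        texture = noise_rng.normal(0.0, 4.0, size=window.shape)
        window[inst.mask] = level + texture[inst.mask]
        label_instances.append(
            lbl.LabelInstance(
                cls=inst.cls,
                points=lbl.mask_to_polygon(inst.mask, (h, w), offset=inst.offset),
            )
        )
    return FrameRender(
        image=np.clip(img, 0, 255).astype(np.uint8),
        instances=instances,
        label_instances=label_instances,
    )


# ---- standalone validation radicles -----------------------------------------


def make_validation_radicles(
    n: int,
    seed: int,
    arc_range_mm: Tuple[float, float] = (5.0, 50.0),
    width_range_px: Tuple[int, int] = (5, 15),
    scale_r: float = 0.1,
) -> List[Tuple[np.ndarray, float]]:
    """Generate ``n`` smooth curved radicle masks with known arc lengths.

    Centerlines are ~1 px-step polylines whose curvature follows a bounded
    AR(1) process (gentle, non-self-intersecting bends); each is dilated to
    a random tube width.  Returns (mask, true centerline arc length in mm)
    pairs — the ground truth for validating the half-contour estimator.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x5EED,)))
    out = []
    for _ in range(n):
        target_mm = rng.uniform(*arc_range_mm)
        width = int(rng.integers(width_range_px[0], width_range_px[1] + 1))
        target_px = target_mm / scale_r
        heading = rng.uniform(0, 2 * np.pi)
        kappa = 0.0
        pt = np.zeros(2)
        pts = [pt.copy()]
        length = 0.0
        while length < target_px:
            kappa = 0.95 * kappa + rng.normal(0.0, 0.0025)
            kappa = float(np.clip(kappa, -0.02, 0.02))
            heading += kappa
            step = np.array([np.sin(heading), np.cos(heading)])
            pt = pt + step
            length += 1.0
            pts.append(pt.copy())
        path = np.asarray(pts)
        # trim to the exact target arc length (unit steps)
        excess = length - target_px
        if excess > 0:
            path[-1] = path[-2] + (path[-1] - path[-2]) * (1.0 - excess)
        steps = np.hypot(*np.diff(path, axis=0).T)
        true_mm = float(steps.sum()) * scale_r
        path -= path.min(axis=0)
        inst = rasterize_centerline(path + 2.0, width)
        out.append((inst.mask, true_mm))
    return out
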