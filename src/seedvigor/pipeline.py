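"""End-to-end orchestration: dataset -> per-instance measurements -> seed
tracks -> vigor summaries.  This is the programmatic form of the CLI's
simulate / measure / metrics chain, shared by both.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import labels as lbl
from . import vigor_metrics as vm
from .root_geometry import ScaleCalibration, estimate_root_length
from .synthetic.dataset import load_manifest

PathLike = Union[str, Path]


def measure_labels(
    instances,
    image_shape,
    calibration: ScaleCalibration,
) -> List[dict]:
    """Measure every radicle instance in one frame's label list.

    Each polygon is rasterized into its own bounding window and the
    half-outer-contour estimator applied; seed-body instances are skipped
    (they carry no length).  Returns one record per radicle with centroid
    (full-image px) and length.
    """
    from skimage.draw import polygon as draw_polygon

    h, w = image_shape[:2]
    out = []
    for k, inst in enumerate(instances):
        if inst.cls != lbl.CLASS_RADICLE:
            continue
        rc = inst.to_pixels((h, w))
        r0 = max(0, int(np.floor(rc[:, 0].min())) - 2)
        c0 = max(0, int(np.floor(rc[:, 1].min())) - 2)
        r1 = min(h, int(np.ceil(rc[:, 0].max())) + 3)
        c1 = min(w, int(np.ceil(rc[:, 1].max())) + 3)
        crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        rr, cc = draw_polygon(rc[:, 0] - r0, rc[:, 1] - c0, shape=crop.shape)
        crop[rr, cc] = True
        if not crop.any():
            continue
        measure = estimate_root_length(crop, calibration)
        rows, cols = np.nonzero(crop)
        out.append(
            {
                "instance": k,
                "cy": float(rows.mean()) + r0,
                "cx": float(cols.mean()) + c0,
                "Sp_px": measure.Sp,
                "length_mm": measure.L_mm,
            }
        )
    return out


def measure_dataset(
    dataset_dir: PathLike, calibration: Optional[ScaleCalibration] = None
) -> pd.DataFrame:
    """Per-instance measurement CSV contents for a generated dataset.

    Reads the polygon label files and the manifest (for the schedule and,
    unless one is supplied, the scale calibration); emits one row per
    radicle instance per frame: dish, frame_index, frame_time_h, instance,
    cx, cy, Sp_px, length_mm.
    """
    dataset_dir = Path(dataset_dir)
    manifest = load_manifest(dataset_dir)
    if calibration is None:
        calibration = ScaleCalibration(r=manifest["scale_r"], reference_id="manifest")
    image_shape = tuple(manifest["image_size"])
    frame_times = manifest["frame_times_h"]
    lab_dir = dataset_dir / "labels"
    rows = []
    for dish_meta in manifest["dishes"]:
        dish = dish_meta["dish"]
        for fi, t in enumerate(frame_times):
            path = lab_dir / f"{dish}_f{fi:03d}.txt"
            if not path.exists():
                raise FileNotFoundError(f"missing label file {path}")
            for rec in measure_labels(lbl.read_labels(path), image_shape, calibration):
                rec.update({"dish": dish, "frame_index": fi, "frame_time_h": t})
                rows.append(rec)
    columns = ["dish", "frame_index", "frame_time_h", "instance", "cx", "cy",
               "Sp_px", "length_mm"]
    return pd.DataFrame(rows, columns=columns)


def build_tracks(
    measurements: pd.DataFrame, manifest: dict
) -> Dict[str, List[vm.SeedTrack]]:
    """Assign measured radicles to seed slots, per dish."""
    frame_times = manifest["frame_times_h"]
    pitch = manifest["grid_pitch_px"]
    tracks_by_dish: Dict[str, List[vm.SeedTrack]] = {}
    for dish_meta in manifest["dishes"]:
        dish = dish_meta["dish"]
        slots = {int(s): tuple(c) for s, c in dish_meta["slot_centers"].items()}
        dets = measurements[measurements["dish"] == dish]
        tracks, _ = vm.assign_detections_to_seeds(
            dets, slots, frame_times, pitch, dish=dish
        )
        tracks_by_dish[dish] = tracks
    return tracks_by_dish


def summarize_dataset(
    measurements: pd.DataFrame,
    manifest: dict,
    threshold_mm: float = vm.DEFAULT_GERMINATION_MM,
    energy_h: float = vm.DEFAULT_ENERGY_H,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dish-level vigor summaries (tidy long table) and rate curves."""
    duration = max(manifest["frame_times_h"])
    tracks_by_dish = build_tracks(measurements, manifest)
    arm_of = {d["dish"]: (d["arm"], d["replicate"]) for d in manifest["dishes"]}
    summaries = []
    for dish, tracks in tracks_by_dish.items():
        arm, rep = arm_of[dish]
        summaries.append(
            vm.summarize_dish(tracks, dish, arm, rep, duration,
                              threshold_mm=threshold_mm, energy_h=energy_h)
        )
    return vm.tidy_summary(summaries), vm.rate_curves(tracks_by_dish, threshold_mm)


def arm_means(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric over replicate dishes, per arm."""
    return tidy.groupby(["arm", "metric"])["value"].mean().unstack()


def relative_increase(tidy: pd.DataFrame, metric: str, arm: str, control: str) -> float:
    """100 * (arm / control - 1) for a metric's replicate-averaged value."""
    means = arm_means(tidy)
    base = means.loc[control, metric]
    if base == 0:
        raise ZeroDivisionError(f"control arm {control!r} has zero {metric}")
    return 100.0 * (means.loc[arm, metric] / base - 1.0)
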