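"""On-disk dataset generation and the calibrated study preset.

A generated dataset is a directory of PNG frames, polygon label files (one
per frame), a ground-truth CSV covering every seed x frame, and a JSON
manifest recording the master seed, a config hash, the arm/dish layout and
slot centers — everything the downstream tracking stage needs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .. import labels as lbl
from .growth import DoseEffect, GrowthModel
from .plan import Arm, TreatmentPlan
from .render import DishState, place_seeds, render_frame

PathLike = Union[str, Path]

#: Headline relative effects the calibrated preset encodes: the optimal dose
#: raises germination probability by 28% and mean maximum radicle length by
#: 42% over the water control (0.70 probability, 40 mm mean maximum).
PAPER_CALIBRATED_EFFECTS = {"germination_rate": 0.28, "radicle_length": 0.42}

_PRESET_DOSES: Dict[str, DoseEffect] = {
    "CK": DoseEffect(1.00, 1.00),
    "ZnO200": DoseEffect(1.18, 1.28),
    "ZnO400": DoseEffect(1.22, 1.30),
    "ZnO600": DoseEffect(1.28, 1.42),
    "ZnO800": DoseEffect(1.00, 1.00),
    "ZnO1000": DoseEffect(0.80, 0.68),
}
_PRESET_CONC = {"CK": 0.0, "ZnO200": 200.0, "ZnO400": 400.0, "ZnO600": 600.0,
                "ZnO800": 800.0, "ZnO1000": 1000.0}

#: Arm with the strongest configured promotion (the "optimal dose").
OPTIMAL_ARM = "ZnO600"
CONTROL_ARM = "CK"


def paper_calibrated(
    arms: Optional[Sequence[str]] = None,
    capture_interval_min: int = 480,
    replicates: int = 3,
) -> Tuple[TreatmentPlan, GrowthModel]:
    """The calibrated dose-response preset: a water control at 0.70
    germination probability / 40 mm mean maximum radicle length, and dose
    arms whose multipliers encode the headline effects (optimal arm: +28%
    germination probability, +42% mean maximum length).

    The default schedule is deliberately coarse (one capture every 8 h, 12
    frames over 96 h): final rate and length plus coarse onset times are
    what the calibrated-recovery analyses consume.
    """
    names = list(arms) if arms is not None else list(_PRESET_DOSES)
    unknown = set(names) - set(_PRESET_DOSES)
    if unknown:
        raise ValueError(f"unknown preset arms: {sorted(unknown)}")
    plan = TreatmentPlan(
        arms=tuple(
            Arm(name=n, solution="ZnONPs" if n != "CK" else "deionized water",
                concentration=_PRESET_CONC[n], unit="mg/L")
            for n in names
        ),
        seeds_per_dish=36,
        replicates=replicates,
        capture_interval_min=capture_interval_min,
        duration_h=96.0,
        image_size=(1800, 1800),
        scale_r=0.1,
    )
    model = GrowthModel(
        germination_prob=0.70,
        dose_multipliers={n: _PRESET_DOSES[n] for n in names},
    )
    return plan, model


PRESETS = {"paper_calibrated": paper_calibrated}


def _config_hash(plan: TreatmentPlan, model: GrowthModel) -> str:
    blob = json.dumps({"plan": asdict(plan), "model": asdict(model)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def frame_name(dish_id: str, frame_index: int) -> str:
    return f"{dish_id}_f{frame_index:03d}"


def generate_dataset(
    plan: TreatmentPlan,
    model: GrowthModel,
    out_dir: PathLike,
    master_seed: int,
    write_images: bool = True,
) -> Path:
    """Generate the full dataset under ``out_dir`` (created if needed).

    Deterministic: a pure function of (plan, model, master_seed).  On any
    failure, files created by this call are removed before re-raising.
    ``write_images=False`` skips the PNG frames (labels and ground truth
    are enough for the measurement stages and much faster to produce).
    """
    out = Path(out_dir)
    created_root = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    lab_dir = out / "labels"
    try:
        img_dir.mkdir(exist_ok=True)
        lab_dir.mkdir(exist_ok=True)
        gt_rows: List[dict] = []
        dishes_meta = []
        for arm in plan.arms:
            for rep in range(1, plan.replicates + 1):
                state = place_seeds(plan, model, arm, rep, master_seed)
                for fi, t in enumerate(plan.frame_times_h):
                    frame = render_frame(state, fi, master_seed)
                    name = frame_name(state.dish_id, fi)
                    lbl.write_labels(frame.label_instances, lab_dir / f"{name}.txt")
                    if write_images:
                        iio.imwrite(img_dir / f"{name}.png", frame.image)
                for p in state.placements:
                    for fi, t in enumerate(plan.frame_times_h):
                        gt_rows.append(
                            {
                                "dish": state.dish_id,
                                "slot": p.slot,
                                "frame_time_h": round(t, 4),
                                "germinated": int(p.trajectory.germinated),
                                "germination_time_h": (
                                    round(p.trajectory.germination_time_h, 4)
                                    if p.trajectory.germinated
                                    else ""
                                ),
                                "length_mm": round(float(p.trajectory.lengths_mm[fi]), 4),
                            }
                        )
                dishes_meta.append(
                    {
                        "dish": state.dish_id,
                        "arm": arm.name,
                        "replicate": rep,
                        "slot_centers": {
                            str(p.slot): [round(p.center[0], 2), round(p.center[1], 2)]
                            for p in state.placements
                        },
                    }
                )
        pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
        manifest = {
            "master_seed": int(master_seed),
            "config_hash": _config_hash(plan, model),
            "scale_r": plan.scale_r,
            "image_size": list(plan.image_size),
            "frame_times_h": [round(t, 6) for t in plan.frame_times_h],
            "grid_pitch_px": plan.grid_pitch_px,
            "seeds_per_dish": plan.seeds_per_dish,
            "arms": [asdict(a) for a in plan.arms],
            "dishes": dishes_meta,
            "images_written": bool(write_images),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except BaseException:
        if created_root:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for sub in (img_dir, lab_dir):
                shutil.rmtree(sub, ignore_errors=True)
            for f in ("ground_truth.csv", "manifest.json"):
                (out / f).unlink(missing_ok=True)
        raise
    return out


def load_manifest(dataset_dir: PathLike) -> dict:
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {dataset_dir}; not a dataset directory")
    return json.loads(path.read_text())
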