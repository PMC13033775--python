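"""Experiment planning: treatment arms, dishes, seed slots, and the capture
schedule (interval x duration x dishes -> image counts)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple


@dataclass(frozen=True)
class Arm:
    """One treatment arm: a solution at a concentration."""

    name: str
    solution: str = "deionized water"
    concentration: float = 0.0
    unit: str = "mg/L"


@dataclass(frozen=True)
class TreatmentPlan:
    """Arms, replicate dishes, seed slots, and the shared capture schedule.

    Every arm shares the schedule: frames are captured at
    ``capture_interval_min, 2*interval, ..., duration_h*60`` after sowing,
    so a dish yields ``duration * 60 / interval`` images.  Replicate dishes
    are the biological replicates (one dish = one replicate of an arm).
    """

    arms: Tuple[Arm, ...]
    seeds_per_dish: int = 36
    replicates: int = 3
    capture_interval_min: int = 20
    duration_h: float = 96.0
    image_size: Tuple[int, int] = (1800, 1800)  # (H, W) px
    scale_r: float = 0.1  # mm per pixel

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("plan needs at least one arm")
        if self.seeds_per_dish < 1:
            raise ValueError("seeds_per_dish must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.capture_interval_min <= 0 or self.duration_h <= 0:
            raise ValueError("interval and duration must be positive")
        total_min = round(self.duration_h * 60)
        if total_min % self.capture_interval_min:
            raise ValueError(
                f"capture interval ({self.capture_interval_min} min) does not divide "
                f"the incubation duration ({self.duration_h} h) into whole frames"
            )
        if self.scale_r <= 0:
            raise ValueError("scale_r must be positive")

    # ---- schedule arithmetic -------------------------------------------------

    @property
    def frames_per_dish(self) -> int:
        return round(self.duration_h * 60) // self.capture_interval_min

    @property
    def frame_times_h(self) -> List[float]:
        step = self.capture_interval_min / 60.0
        return [step * (k + 1) for k in range(self.frames_per_dish)]

    @property
    def dishes_per_arm(self) -> int:
        return self.replicates

    @property
    def n_dishes(self) -> int:
        return len(self.arms) * self.replicates

    @property
    def n_capture_events(self) -> int:
        return self.n_dishes * self.frames_per_dish

    @property
    def n_seeds(self) -> int:
        return self.n_dishes * self.seeds_per_dish

    def dish_ids(self) -> List[Tuple[str, int, str]]:
        """All (arm name, replicate index, dish id) triples."""
        out = []
        for arm in self.arms:
            for rep in range(1, self.replicates + 1):
                out.append((arm.name, rep, f"{arm.name}-r{rep}"))
        return out

    def capture_events(self) -> Iterator[Tuple[str, float]]:
        """Every (dish id, frame time in hours) capture event."""
        for _, _, dish in self.dish_ids():
            for t in self.frame_times_h:
                yield dish, t

    # ---- seed grid -----------------------------------------------------------

    @property
    def grid_shape(self) -> Tuple[int, int]:
        n = self.seeds_per_dish
        rows = int(math.ceil(math.sqrt(n)))
        cols = int(math.ceil(n / rows))
        return rows, cols

    @property
    def grid_pitch_px(self) -> float:
        rows, cols = self.grid_shape
        h, w = self.image_size
        return min(h / rows, w / cols)

    def slot_centers(self) -> Dict[int, Tuple[float, float]]:
        """Nominal (row, col) pixel center of every seed slot, row-major."""
        rows, cols = self.grid_shape
        h, w = self.image_size
        pitch = self.grid_pitch_px
        top = (h - rows * pitch) / 2.0
        left = (w - cols * pitch) / 2.0
        centers = {}
        for slot in range(self.seeds_per_dish):
            r, c = divmod(slot, cols)
            centers[slot] = (top + (r + 0.5) * pitch, left + (c + 0.5) * pitch)
        return centers


def make_experiment_plan(config: Mapping) -> TreatmentPlan:
    """Build a :class:`TreatmentPlan` from a plain config mapping.

    ``config['arms']`` is a list of arm names or of mappings with keys
    ``name``, ``solution``, ``concentration``, ``unit``; remaining keys map
    directly onto plan fields.
    """
    arms = []
    for spec in config["arms"]:
        if isinstance(spec, str):
            arms.append(Arm(name=spec))
        else:
            arms.append(
                Arm(
                    name=str(spec["name"]),
                    solution=str(spec.get("solution", "deionized water")),
                    concentration=float(spec.get("concentration", 0.0)),
                    unit=str(spec.get("unit", "mg/L")),
                )
            )
    kwargs = {}
    for key in (
        "seeds_per_dish",
        "replicates",
        "capture_interval_min",
        "duration_h",
        "scale_r",
    ):
        if key in config:
            kwargs[key] = config[key]
    if "image_size" in config:
        kwargs["image_size"] = tuple(int(v) for v in config["image_size"])
    return TreatmentPlan(arms=tuple(arms), **kwargs)
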