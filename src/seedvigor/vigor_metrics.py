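"""Per-seed tracking across the time series and germination vigor metrics.

A seed germinates, by convention, when its measured radicle length first
reaches a threshold (default 2 mm, a common laboratory rule).  From the
per-seed tracks the standard vigor indicators follow:

* germination rate   — % of seeds germinated by time t (usually test end);
* germination energy — the rate at an early cutoff (default 72 h), a
  speed-of-germination indicator (also called germination vigor/potential);
* germination index  — GI = sum over days of (seeds newly germinated on day
  t / day number t), weighting early germination more heavily;
* total root length  — summed (and mean) radicle length at time t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_GERMINATION_MM = 2.0
DEFAULT_ENERGY_H = 72.0
GAP_EXCLUDE_FRACTION = 0.25


@dataclass
class SeedTrack:
    """One seed's calibrated length time series."""

    dish: str
    slot: int
    times_h: np.ndarray
    lengths_mm: np.ndarray
    gaps: np.ndarray = field(default=None)  # True where carried forward
    germination_time_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        if self.gaps is None:
            self.gaps = np.zeros_like(self.times_h, dtype=bool)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)
        if len(self.times_h) != len(self.lengths_mm):
            raise ValueError("times and lengths must align")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def gap_fraction(self) -> float:
        return float(self.gaps.mean()) if len(self.gaps) else 0.0

    def length_at(self, t_h: float) -> float:
        idx = np.searchsorted(self.times_h, t_h, side="right") - 1
        return float(self.lengths_mm[idx]) if idx >= 0 else 0.0


def assign_detections_to_seeds(
    detections: pd.DataFrame,
    slots: Mapping[int, Tuple[float, float]],
    frame_times_h: Sequence[float],
    pitch_px: float,
    dish: str = "",
) -> Tuple[List[SeedTrack], pd.DataFrame]:
    """Assign per-frame radicle detections to seed grid slots.

    ``detections`` needs columns ``frame_index``, ``cy``, ``cx``,
    ``length_mm``.  Per frame, instance-slot pairs within half the grid
    pitch are assigned greedily by distance, one-to-one; a farther instance
    contesting an occupied slot is left unassigned and reported.  A slot
    with no detection at a frame keeps length 0 until its first detection;
    afterwards a missing frame carries the last observed length forward
    with a gap flag.

    Returns the 36 (or however many) tracks plus a table of unassigned
    detections.
    """
    times = np.asarray(list(frame_times_h), dtype=float)
    n_frames = len(times)
    cap = pitch_px / 2.0
    observed: Dict[int, Dict[int, float]] = {s: {} for s in slots}
    leftovers = []

    for fi, grp in detections.groupby("frame_index"):
        pairs = []
        for det_idx, row in grp.iterrows():
            for slot, (sy, sx) in slots.items():
                d = math.hypot(row["cy"] - sy, row["cx"] - sx)
                if d <= cap:
                    pairs.append((d, det_idx, slot))
        pairs.sort()
        used_det, used_slot = set(), set()
        for d, det_idx, slot in pairs:
            if det_idx in used_det or slot in used_slot:
                continue
            used_det.add(det_idx)
            used_slot.add(slot)
            observed[slot][int(fi)] = float(grp.loc[det_idx, "length_mm"])
        for det_idx, row in grp.iterrows():
            if det_idx not in used_det:
                leftovers.append(
                    {"frame_index": int(fi), "cy": row["cy"], "cx": row["cx"],
                     "length_mm": row["length_mm"]}
                )

    tracks = []
    for slot in sorted(slots):
        lengths = np.zeros(n_frames)
        gaps = np.zeros(n_frames, dtype=bool)
        seen = False
        last = 0.0
        for fi in range(n_frames):
            if fi in observed[slot]:
                last = observed[slot][fi]
                seen = True
                lengths[fi] = last
            elif seen:
                lengths[fi] = last  # carry forward
                gaps[fi] = True
            # else: not yet germinated, stays 0
        tracks.append(SeedTrack(dish=dish, slot=slot, times_h=times,
                                lengths_mm=lengths, gaps=gaps))
    return tracks, pd.DataFrame(leftovers)


def detect_germination(
    track: SeedTrack, threshold_mm: float = DEFAULT_GERMINATION_MM
) -> Optional[float]:
    """First frame time at which the radicle length reaches the threshold.

    With threshold 0 this is the first frame showing any radicle at all.
    Returns None if the threshold is never reached.
    """
    hit = (track.lengths_mm >= threshold_mm) & (track.lengths_mm > 0)
    idx = np.flatnonzero(hit)
    return float(track.times_h[idx[0]]) if len(idx) else None


def _germination_times(
    tracks: Sequence[SeedTrack], threshold_mm: float
) -> List[Optional[float]]:
    out = []
    for tr in tracks:
        if tr.germination_time_h is not None:
            out.append(tr.germination_time_h)
        else:
            out.append(detect_germination(tr, threshold_mm))
    return out


def germination_rate(
    tracks: Sequence[SeedTrack],
    t_h: float,
    threshold_mm: float = DEFAULT_GERMINATION_MM,
) -> float:
    """Percentage of seeds germinated by time ``t_h``."""
    if not tracks:
        raise ValueError("germination rate is undefined for an empty track set")
    times = _germination_times(tracks, threshold_mm)
    count = sum(1 for g in times if g is not None and g <= t_h)
    return 100.0 * count / len(tracks)


def germination_energy(
    tracks: Sequence[SeedTrack],
    t_e_h: float = DEFAULT_ENERGY_H,
    threshold_mm: float = DEFAULT_GERMINATION_MM,
) -> float:
    """Germination rate at the early cutoff ``t_e_h`` (default 72 h)."""
    return germination_rate(tracks, t_e_h, threshold_mm)


def germination_index(
    tracks: Sequence[SeedTrack],
    threshold_mm: float = DEFAULT_GERMINATION_MM,
    day_h: float = 24.0,
) -> float:
    """GI = sum over days of (newly germinated count on day t / day number t).

    Days are 24 h bins from sowing; a germination at hour h falls on day
    ceil(h / 24) (a partial final day counts as a full day number).
    """
    gi = 0.0
    for g in _germination_times(tracks, threshold_mm):
        if g is not None:
            day = max(1, math.ceil(g / day_h))
            gi += 1.0 / day
    return gi


def total_root_length(
    tracks: Sequence[SeedTrack], t_h: float
) -> Tuple[float, float]:
    """(sum, mean) radicle length in mm at the last frame at or before t."""
    lengths = [tr.length_at(t_h) for tr in tracks]
    if not lengths:
        return 0.0, 0.0
    return float(np.sum(lengths)), float(np.mean(lengths))


@dataclass
class VigorSummary:
    """Vigor indicators for one dish (one biological replicate)."""

    dish: str
    arm: str
    replicate: int
    n_seeds: int
    n_excluded: int
    germination_rate: float  # %
    germination_energy: float  # %
    germination_index: float
    total_root_length_mm: float
    mean_root_length_mm: float  # over all seeds
    mean_germinated_length_mm: float  # over germinated seeds only

    def to_row(self) -> dict:
        return self.__dict__.copy()


def summarize_dish(
    tracks: Sequence[SeedTrack],
    dish: str,
    arm: str,
    replicate: int,
    duration_h: float,
    threshold_mm: float = DEFAULT_GERMINATION_MM,
    energy_h: float = DEFAULT_ENERGY_H,
) -> VigorSummary:
    """Dish-level vigor summary.  Tracks with more than 25% carried-forward
    frames are excluded from the summary (their count is reported)."""
    kept = [tr for tr in tracks if tr.gap_fraction <= GAP_EXCLUDE_FRACTION]
    n_excluded = len(tracks) - len(kept)
    if not kept:
        raise ValueError(f"dish {dish}: no usable tracks after gap exclusion")
    times = _germination_times(kept, threshold_mm)
    for tr, g in zip(kept, times):
        tr.germination_time_h = g
    total, mean_all = total_root_length(kept, duration_h)
    germ_lengths = [
        tr.length_at(duration_h) for tr, g in zip(kept, times) if g is not None
    ]
    return VigorSummary(
        dish=dish,
        arm=arm,
        replicate=replicate,
        n_seeds=len(kept),
        n_excluded=n_excluded,
        germination_rate=germination_rate(kept, duration_h, threshold_mm),
        germination_energy=germination_energy(kept, energy_h, threshold_mm),
        germination_index=germination_index(kept, threshold_mm),
        total_root_length_mm=total,
        mean_root_length_mm=mean_all,
        mean_germinated_length_mm=float(np.mean(germ_lengths)) if germ_lengths else 0.0,
    )


def tidy_summary(summaries: Sequence[VigorSummary]) -> pd.DataFrame:
    """Long-format table: one row per (arm, replicate, metric)."""
    rows = []
    for s in summaries:
        for metric in (
            "germination_rate",
            "germination_energy",
            "germination_index",
            "total_root_length_mm",
            "mean_root_length_mm",
            "mean_germinated_length_mm",
        ):
            rows.append(
                {"arm": s.arm, "replicate": s.replicate, "dish": s.dish,
                 "metric": metric, "value": getattr(s, metric)}
            )
    return pd.DataFrame(rows)


def rate_curves(
    tracks_by_dish: Mapping[str, Sequence[SeedTrack]],
    threshold_mm: float = DEFAULT_GERMINATION_MM,
) -> pd.DataFrame:
    """Time-resolved cumulative germination rate per dish."""
    rows = []
    for dish, tracks in tracks_by_dish.items():
        for t in tracks[0].times_h:
            rows.append(
                {"dish": dish, "time_h": float(t),
                 "germination_rate": germination_rate(tracks, t, threshold_mm)}
            )
    return pd.DataFrame(rows)
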