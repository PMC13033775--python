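"""Stochastic radicle growth model for the synthetic trays.

Each seed germinates with an arm-specific probability; germination time
follows a truncated lognormal law; after germination the radicle elongates
along a logistic curve and its centerline coils outward around the seed
body (radicles confined to a dish curl rather than run straight, and the
coil keeps every instance inside its own grid cell so neighbors never
overlap and the tube never self-intersects).

Randomness: one master seed spawns per-(replicate, slot, channel)
substreams.  Channels that drive the biology (germination draw, timing,
length factor, shape, width) are keyed *without* the treatment arm, so the
same seed position experiences common random numbers across arms — paired
arm comparisons on synthetic data then estimate treatment effects with much
less sampling noise, and dose effects are monotonically coupled (raising
the germination probability can only add germinating seeds, never remove
one).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .plan import Arm, TreatmentPlan


def substream(master_seed: int, *key) -> np.random.Generator:
    """Deterministic child generator for a hierarchical key.

    String key parts are hashed with CRC-32 (stable across processes and
    platforms), so regenerating any one seed, dish, or channel reproduces
    exactly the same draws regardless of iteration order.
    """
    parts = tuple(
        int(k) if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=parts))


@dataclass(frozen=True)
class GerminationTimeLaw:
    """Lognormal germination onset (hours), truncated by resampling."""

    median_h: float = 36.0
    sigma: float = 0.30
    min_h: float = 12.0
    max_h: float = 96.0

    def __post_init__(self) -> None:
        if self.median_h <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")
        if not 0 < self.min_h < self.max_h:
            raise ValueError("need 0 < min_h < max_h")

    def sample(self, rng: np.random.Generator) -> float:
        mu = np.log(self.median_h)
        for _ in range(1000):
            t = float(rng.lognormal(mu, self.sigma))
            if self.min_h <= t <= self.max_h:
                return t
        return float(np.clip(t, self.min_h, self.max_h))  # pragma: no cover


@dataclass(frozen=True)
class ElongationLaw:
    """Logistic elongation after germination.

    Length at time t (for t >= germination time tg) is
    ``Lmax * sigmoid(rate * (t - tg - midpoint))`` — exactly half the
    maximum at ``tg + midpoint``.  Per-seed maxima vary lognormally around
    the arm mean with coefficient of variation ``length_cv``.
    """

    max_length_mm: float = 40.0
    rate_per_h: float = 0.15
    midpoint_h: float = 30.0
    length_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.max_length_mm <= 0 or self.rate_per_h <= 0 or self.midpoint_h <= 0:
            raise ValueError("elongation parameters must be positive")
        if self.length_cv < 0:
            raise ValueError("length_cv must be >= 0")

    def length_at(self, t_h: float, tg_h: float, lmax_mm: float) -> float:
        if t_h < tg_h:
            return 0.0
        z = self.rate_per_h * (t_h - tg_h - self.midpoint_h)
        return float(lmax_mm / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class RadicleShapeLaw:
    """Coiled-centerline geometry (Archimedean spiral around the seed)."""

    start_radius_px: float = 37.0
    coil_spacing_px: float = 26.0
    radial_noise_px: float = 1.2
    max_radius_px: float = 125.0

    def __post_init__(self) -> None:
        if self.start_radius_px <= 0 or self.coil_spacing_px <= 0:
            raise ValueError("radii and spacing must be positive")


@dataclass(frozen=True)
class DoseEffect:
    """Multiplicative dose modifiers for one arm."""

    prob: float = 1.0
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.prob < 0 or self.length <= 0:
            raise ValueError("dose multipliers must be nonnegative (length > 0)")


@dataclass(frozen=True)
class GrowthModel:
    germination_prob: float = 0.70
    germination_time_law: GerminationTimeLaw = field(default_factory=GerminationTimeLaw)
    elongation_law: ElongationLaw = field(default_factory=ElongationLaw)
    shape_law: RadicleShapeLaw = field(default_factory=RadicleShapeLaw)
    width_range_px: Tuple[int, int] = (7, 11)
    dose_multipliers: Mapping[str, DoseEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.germination_prob <= 1.0:
            raise ValueError("germination_prob must lie in [0, 1]")
        lo, hi = self.width_range_px
        if lo < 3 or hi < lo:
            raise ValueError("radicle widths must be >= 3 px and ordered")

    def arm_prob(self, arm_name: str) -> float:
        mult = self.dose_multipliers.get(arm_name, DoseEffect()).prob
        return float(np.clip(self.germination_prob * mult, 0.0, 1.0))

    def arm_max_length_mm(self, arm_name: str) -> float:
        mult = self.dose_multipliers.get(arm_name, DoseEffect()).length
        return self.elongation_law.max_length_mm * mult


@dataclass
class SeedTrajectory:
    """Ground-truth growth of a single seed across the capture schedule."""

    slot: int
    germinated: bool
    germination_time_h: Optional[float]
    max_length_mm: float
    frame_times_h: np.ndarray
    lengths_mm: np.ndarray  # per frame; 0 before germination
    width_px: int
    centerline_px: np.ndarray  # (N, 2) local (row, col) offsets from seed center
    arc_cumsum_px: np.ndarray  # cumulative polyline length, arc_cumsum[0] = 0

    def centerline_at(self, length_px: float) -> np.ndarray:
        """Centerline prefix of the given arc length (last point interpolated)."""
        if length_px <= 0:
            return np.empty((0, 2))
        cum = self.arc_cumsum_px
        if length_px >= cum[-1]:
            return self.centerline_px
        i = int(np.searchsorted(cum, length_px))
        frac = (length_px - cum[i - 1]) / (cum[i] - cum[i - 1])
        tip = self.centerline_px[i - 1] + frac * (self.centerline_px[i] - self.centerline_px[i - 1])
        return np.vstack([self.centerline_px[:i], tip])


def _coil_path(
    rng: np.random.Generator, law: RadicleShapeLaw, target_len_px: float
) -> np.ndarray:
    """Archimedean spiral polyline (~1 px steps) of at least the target length."""
    b = law.coil_spacing_px / (2.0 * np.pi)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    chirality = 1.0 if rng.uniform() < 0.5 else -1.0
    pts = []
    theta = 0.0
    noise = 0.0
    length = 0.0
    prev = None
    while length < target_len_px + 2.0:
        radius = law.start_radius_px + b * theta
        if radius > law.max_radius_px:
            raise RuntimeError(
                f"radicle of {target_len_px:.0f} px cannot coil within "
                f"{law.max_radius_px:.0f} px; enlarge the grid cell or coil spacing"
            )
        noise = 0.95 * noise + rng.normal(0.0, 0.2 * law.radial_noise_px)
        ang = theta0 + chirality * theta
        pt = ((radius + noise) * np.sin(ang), (radius + noise) * np.cos(ang))
        if prev is not None:
            length += float(np.hypot(pt[0] - prev[0], pt[1] - prev[1]))
        pts.append(pt)
        prev = pt
        theta += 1.0 / radius  # ~1 px arc step
    return np.asarray(pts)


def simulate_seed(
    model: GrowthModel,
    arm: Arm,
    master_seed: int,
    replicate: int,
    slot: int,
    frame_times_h: Sequence[float],
    scale_r: float,
) -> SeedTrajectory:
    """Simulate one seed: germination draw, onset time, per-frame lengths,
    and the full-growth centerline polyline (local coordinates).

    Reproducible: a pure function of (model, arm, master seed, replicate,
    slot, schedule).  Biology channels are arm-independent (common random
    numbers); the arm enters only through its probability and length
    multipliers.
    """
    times = np.asarray(list(frame_times_h), dtype=float)
    u = substream(master_seed, replicate, slot, "germination").uniform()
    germinated = bool(u < model.arm_prob(arm.name))

    width = int(
        substream(master_seed, replicate, slot, "width").integers(
            model.width_range_px[0], model.width_range_px[1] + 1
        )
    )
    if not germinated:
        return SeedTrajectory(
            slot=slot,
            germinated=False,
            germination_time_h=None,
            max_length_mm=0.0,
            frame_times_h=times,
            lengths_mm=np.zeros_like(times),
            width_px=width,
            centerline_px=np.empty((0, 2)),
            arc_cumsum_px=np.zeros(1),
        )

    tg = model.germination_time_law.sample(substream(master_seed, replicate, slot, "time"))
    law = model.elongation_law
    factor_rng = substream(master_seed, replicate, slot, "length")
    sigma = np.sqrt(np.log1p(law.length_cv**2))
    factor = float(np.exp(factor_rng.normal(-0.5 * sigma**2, sigma)))  # mean 1
    lmax = model.arm_max_length_mm(arm.name) * factor
    lengths = np.array([law.length_at(t, tg, lmax) for t in times])

    path = _coil_path(
        substream(master_seed, replicate, slot, "shape"),
        model.shape_law,
        target_len_px=lmax / scale_r,
    )
    steps = np.hypot(*np.diff(path, axis=0).T)
    return SeedTrajectory(
        slot=slot,
        germinated=True,
        germination_time_h=tg,
        max_length_mm=lmax,
        frame_times_h=times,
        lengths_mm=lengths,
        width_px=width,
        centerline_px=path,
        arc_cumsum_px=np.concatenate([[0.0], np.cumsum(steps)]),
    )
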