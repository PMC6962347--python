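"""Group-velocity estimation by linear-fit time-to-peak with RANSAC.

The group velocity - the speed of the wave-packet envelope, the
conventional clinical SWE output - is estimated from a space-time map by
(1) locating, per lateral position, the time at which particle velocity
peaks (time-to-peak, TTP), and (2) fitting a line t = x/v + b to the
(position, peak-time) points with a random-sample-consensus filter to
reject arrival-time outliers. The fit is parameterised as t(x) because
TTP noise lives in time; velocity is the reciprocal slope.

Quality gating follows the inlier ratio of the consensus fit: estimates
with ratio at or below 0.5 are flagged as failed. A second flag records
fits whose inlier span covers less than half the available lateral
extent, replacing a visual "does the fit pertain to the main wave"
check with a reproducible rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .datatypes import SpaceTimeMap

__all__ = [
    "CropWindow",
    "RansacConfig",
    "GroupVelocityEstimate",
    "time_to_peak",
    "fit_group_velocity",
    "estimate_group_velocity",
    "combine_directional_estimates",
]


@dataclass(frozen=True)
class CropWindow:
    """Rectangular crop of a space-time map, in physical units."""

    lateral_range: tuple[float, float]
    time_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.lateral_range[0] < self.lateral_range[1]:
            raise ValueError("lateral_range must have min < max")
        if not self.time_range[0] < self.time_range[1]:
            raise ValueError("time_range must have min < max")


@dataclass(frozen=True)
class RansacConfig:
    n_iter: int = 200
    residual_threshold: float = 0.5e-3  # seconds
    min_samples: int = 2
    seed: int = 0
    quality_gate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.min_samples < 2:
            raise ValueError("n_iter >= 1 and min_samples >= 2 required")
        if not self.residual_threshold > 0:
            raise ValueError("residual_threshold must be positive")


@dataclass(frozen=True)
class GroupVelocityEstimate:
    velocity: float  # m/s (nan when failed)
    intercept: float  # s
    inlier_ratio: float
    n_points: int
    passed_quality: bool
    direction: str = "rightward"
    crop_used: Optional[CropWindow] = None
    spans_roi: bool = True  # inlier span covers >= 50% of the lateral extent


def time_to_peak(
    stmap: SpaceTimeMap, crop: Optional[CropWindow] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per lateral position, the time of the maximum map value.

    Ties are broken toward the earliest time. Returns
    ``(lateral_positions, peak_times)`` restricted to the crop window if
    one is given. At least 3 lateral positions must survive the crop.
    """
    x = stmap.lateral_positions
    t = stmap.times
    v = stmap.values
    if crop is not None:
        xi = (x >= crop.lateral_range[0]) & (x <= crop.lateral_range[1])
        ti = (t >= crop.time_range[0]) & (t <= crop.time_range[1])
        if not ti.any():
            raise ValueError("crop window excludes all time samples")
        x, t, v = x[xi], t[ti], v[np.ix_(xi, ti)]
    if x.size < 3:
        raise ValueError("need at least 3 lateral positions inside the crop")
    peak_idx = np.argmax(v, axis=1)  # argmax returns the first maximum
    return x, t[peak_idx]


def _candidate_pairs(n: int, cfg: RansacConfig) -> np.ndarray:
    all_pairs = n * (n - 1) // 2
    if all_pairs <= cfg.n_iter:
        # Small problems are searched exhaustively; RANSAC then equals
        # brute force over all 2-point models.
        return np.array(list(combinations(range(n), 2)))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA45AC]))
    draws = np.empty((cfg.n_iter, 2), dtype=int)
    for i in range(cfg.n_iter):
        draws[i] = rng.choice(n, size=2, replace=False)
    return draws


def fit_group_velocity(
    points: tuple[np.ndarray, np.ndarray] | Sequence[tuple[float, float]],
    ransac: RansacConfig = RansacConfig(),
) -> GroupVelocityEstimate:
    """RANSAC line fit t = x/v + b to TTP points; velocity = 1/slope.

    Candidate lines are drawn through point pairs (all pairs when there
    are no more than ``n_iter`` of them, seeded random pairs otherwise);
    inliers are points within ``residual_threshold`` seconds of the
    line. The best candidate maximises the inlier count, ties broken by
    smaller inlier residual RMS; the final velocity comes from an
    ordinary least-squares refit on the best inlier set. The estimate
    passes quality when the inlier ratio exceeds the gate (default 0.5)
    and the fitted velocity is finite and positive.
    """
    if isinstance(points, tuple) and len(points) == 2 and np.ndim(points[0]) == 1:
        x = np.asarray(points[0], dtype=float)
        t = np.asarray(points[1], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, t = arr[:, 0], arr[:, 1]
    n = x.size
    if n < ransac.min_samples:
        raise ValueError(f"need at least min_samples = {ransac.min_samples} points")

    best = None  # (count, -rms, inlier_mask)
    for i, j in _candidate_pairs(n, ransac):
        dx = x[j] - x[i]
        if dx == 0:
            continue
        slope = (t[j] - t[i]) / dx
        icpt = t[i] - slope * x[i]
        resid = np.abs(t - (slope * x + icpt))
        inl = resid <= ransac.residual_threshold
        count = int(inl.sum())
        rms = float(np.sqrt(np.mean(resid[inl] ** 2)))
        key = (count, -rms)
        if best is None or key > best[0]:
            best = (key, inl)

    failure = GroupVelocityEstimate(
        velocity=float("nan"),
        intercept=float("nan"),
        inlier_ratio=0.0,
        n_points=n,
        passed_quality=False,
    )
    if best is None:
        return failure

    inl = best[1]
    slope, icpt = np.polyfit(x[inl], t[inl], 1)
    velocity = 1.0 / slope if slope != 0 else float("inf")
    ratio = float(inl.sum()) / n
    passed = (
        ratio > ransac.quality_gate and np.isfinite(velocity) and velocity > 0
    )
    span = float(x[inl].max() - x[inl].min())
    full = float(x.max() - x.min())
    return GroupVelocityEstimate(
        velocity=float(velocity),
        intercept=float(icpt),
        inlier_ratio=ratio,
        n_points=n,
        passed_quality=bool(passed),
        spans_roi=bool(full == 0 or span >= 0.5 * full),
    )


def estimate_group_velocity(
    stmap: SpaceTimeMap,
    crop: Optional[CropWindow] = None,
    ransac: RansacConfig = RansacConfig(),
) -> GroupVelocityEstimate:
    """TTP extraction followed by the RANSAC fit, direction-aware.

    Leftward maps are mirrored along the lateral axis before fitting so
    that a well-formed wave always yields a positive velocity.
    """
    x, t = time_to_peak(stmap, crop)
    if stmap.direction == "leftward":
        x = -x[::-1]
        t = t[::-1]
    est = fit_group_velocity((x, t), ransac)
    return GroupVelocityEstimate(
        velocity=est.velocity,
        intercept=est.intercept,
        inlier_ratio=est.inlier_ratio,
        n_points=est.n_points,
        passed_quality=est.passed_quality,
        direction=stmap.direction,
        crop_used=crop,
        spans_roi=est.spans_roi,
    )


def combine_directional_estimates(
    estimates: Sequence[GroupVelocityEstimate],
) -> Optional[float]:
    """Single per-acquisition velocity: mean of the passing directional
    estimates; ``None`` when no direction passes (the acquisition is
    then excluded from further analysis)."""
    passing = [e.velocity for e in estimates if e.passed_quality]
    if not passing:
        return None
    return float(np.mean(passing))
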