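"""Core in-memory containers shared across the pipeline.

Axis order convention is (depth, lateral, slow_time) everywhere; all
quantities are SI (metres, seconds, Hz, m/s) unless a name says otherwise.
The velocity sign convention is positive toward the transducer
(decreasing depth), the usual Doppler convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Direction = Literal["leftward", "rightward"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Sampling geometry and tracking parameters of one SWE acquisition.

    Defaults follow a clinical carotid plane-wave tracking setup: 0.3 mm
    pixel pitch in both axes, a 10 kHz slow-time frame rate (0.1 ms frame
    interval) over an 18 ms record, and a 5 MHz tracking frequency.

    Parameters
    ----------
    n_depth, n_lateral : int
        Pixel counts along depth and lateral axes.
    n_frames : int
        Number of slow-time frames in the particle-velocity movie.
    depth_spacing, lateral_spacing : float
        Pixel pitch in metres.
    frame_interval : float
        Slow-time sampling interval in seconds (reciprocal of the
        tracking pulse-repetition frequency).
    center_frequency : float
        Tracking-pulse centre frequency in Hz.
    sound_speed : float
        Assumed bulk sound speed in m/s.
    """

    n_depth: int = 40
    n_lateral: int = 128
    n_frames: int = 180
    depth_spacing: float = 0.3e-3
    lateral_spacing: float = 0.3e-3
    frame_interval: float = 1e-4
    center_frequency: float = 5e6
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        for name in ("n_depth", "n_lateral", "n_frames"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in (
            "depth_spacing",
            "lateral_spacing",
            "frame_interval",
            "center_frequency",
            "sound_speed",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def duration(self) -> float:
        """Record length in seconds (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def depth_positions(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.depth_spacing

    @property
    def lateral_positions(self) -> np.ndarray:
        return np.arange(self.n_lateral) * self.lateral_spacing

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def aliasing_limit(self) -> float:
        """Largest unambiguous axial particle velocity (m/s).

        Set by phase wrapping of the slow-time Doppler phase:
        sound_speed / (4 * center_frequency * frame_interval).
        """
        return self.sound_speed / (4.0 * self.center_frequency * self.frame_interval)

    def to_attrs(self) -> dict:
        """Flat dict of all fields, for HDF5 attributes."""
        return {
            "n_depth": self.n_depth,
            "n_lateral": self.n_lateral,
            "n_frames": self.n_frames,
            "depth_spacing": self.depth_spacing,
            "lateral_spacing": self.lateral_spacing,
            "frame_interval": self.frame_interval,
            "center_frequency": self.center_frequency,
            "sound_speed": self.sound_speed,
        }

    @classmethod
    def from_attrs(cls, attrs) -> "AcquisitionGrid":
        return cls(
            n_depth=int(attrs["n_depth"]),
            n_lateral=int(attrs["n_lateral"]),
            n_frames=int(attrs["n_frames"]),
            depth_spacing=float(attrs["depth_spacing"]),
            lateral_spacing=float(attrs["lateral_spacing"]),
            frame_interval=float(attrs["frame_interval"]),
            center_frequency=float(attrs["center_frequency"]),
            sound_speed=float(attrs["sound_speed"]),
        )


@dataclass(frozen=True)
class ROIMask:
    """Boolean plaque segmentation mask over (depth, lateral).

    The lateral extent (columns containing any true pixel) must be
    contiguous so the depth-averaged space-time map has a gap-free
    lateral axis.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D (depth, lateral)")
        if not m.any():
            raise ValueError("ROI mask must contain at least one true pixel")
        cols = np.flatnonzero(m.any(axis=0))
        if not np.array_equal(cols, np.arange(cols[0], cols[-1] + 1)):
            raise ValueError("ROI lateral extent must be contiguous")

    @property
    def lateral_columns(self) -> np.ndarray:
        """Indices of lateral columns containing at least one masked pixel."""
        return np.flatnonzero(self.mask.any(axis=0))

    @classmethod
    def box(
        cls,
        grid: AcquisitionGrid,
        depth_slice: slice | None = None,
        lateral_slice: slice | None = None,
    ) -> "ROIMask":
        """Rectangular ROI; defaults to the central half in depth and the
        central region (8-pixel lateral margins) in lateral."""
        if depth_slice is None:
            depth_slice = slice(grid.n_depth // 4, 3 * grid.n_depth // 4)
        if lateral_slice is None:
            lateral_slice = slice(8, grid.n_lateral - 8)
        m = np.zeros((grid.n_depth, grid.n_lateral), dtype=bool)
        m[depth_slice, lateral_slice] = True
        return cls(m)


@dataclass(frozen=True)
class IQEnsemble:
    """Complex baseband (in-phase/quadrature) echo samples.

    Tissue motion appears as a frame-to-frame phase shift of
    4*pi*f0*v*dt/c radians at each pixel.
    """

    samples: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if not np.iscomplexobj(s):
            raise ValueError("IQ samples must be complex")
        if s.ndim != 3:
            raise ValueError("IQ samples must be (depth, lateral, slow_time)")
        if s.shape[2] < 2:
            raise ValueError("IQ ensemble needs at least 2 slow-time frames")
        if not np.all(np.isfinite(s.view(float))):
            raise ValueError("IQ samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[2]


@dataclass(frozen=True)
class ParticleVelocityField:
    """Axial tissue particle velocity movie v(z, x, t) in m/s."""

    values: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("velocity values must be (depth, lateral, slow_time)")
        if v.shape[0] != self.grid.n_depth or v.shape[1] != self.grid.n_lateral:
            raise ValueError("velocity array does not match grid extents")
        if not np.all(np.isfinite(v)):
            raise ValueError("velocity values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.grid.frame_interval


@dataclass(frozen=True)
class SpaceTimeMap:
    """Depth-averaged particle velocity v(x, t) within the ROI, for one
    propagation direction."""

    values: np.ndarray
    lateral_positions: np.ndarray
    times: np.ndarray
    direction: Direction

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        x = np.asarray(self.lateral_positions, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.ndim != 2 or v.shape != (x.size, t.size):
            raise ValueError("map values must be (lateral, slow_time)")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise ValueError("lateral_positions must be strictly increasing")
        dt = np.diff(t)
        if t.size > 1 and (not np.all(dt > 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if self.direction not in ("leftward", "rightward"):
            raise ValueError("direction must be 'leftward' or 'rightward'")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lateral_positions", x)
        object.__setattr__(self, "times", t)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def dx(self) -> float:
        return float(self.lateral_positions[1] - self.lateral_positions[0])
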