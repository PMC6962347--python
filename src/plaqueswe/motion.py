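"""Axial particle-velocity estimation from IQ ensembles.

Implements the 2-D autocorrelation (Doppler) estimator: the lag-one
slow-time autocorrelation is averaged over a small spatial/temporal
kernel and its phase angle converted to velocity through

    v = c / (4 * pi * f0 * dt) * angle(R1)

The averaging is implicitly amplitude-weighted (brighter speckle
contributes more to the complex sum), which is what makes the estimator
robust on real data. The default kernel averages 5 depth pixels and a
single lateral column and applies no slow-time smoothing: each lag-one
pair is already a two-frame estimate, and temporal windows longer than
one pair low-pass the movie (attenuation 0.5 + 0.5*cos(2*pi*f*dt) for a
centred 2-pair window), which measurably distorts packets with content
near the tracking bandwidth. Wider kernels remain available for noisy
data.

No phase unwrapping is attempted: velocities beyond the aliasing limit
wrap by construction of the principal-value angle.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import IQEnsemble, ParticleVelocityField

__all__ = ["estimate_particle_velocity"]


def estimate_particle_velocity(
    iq: IQEnsemble,
    kernel_depth: int = 5,
    kernel_lateral: int = 1,
    kernel_time: int = 1,
) -> ParticleVelocityField:
    """Estimate the axial particle-velocity movie from an IQ ensemble.

    Parameters
    ----------
    iq : IQEnsemble
        Complex baseband ensemble with at least two slow-time frames.
    kernel_depth, kernel_lateral, kernel_time : int
        Extents of the averaging kernel applied to the lag-one
        autocorrelation before taking its angle. ``kernel_time`` counts
        correlation pairs (ensemble frames minus one). Each must be at
        least 1 and no larger than the corresponding data extent; edges
        are handled by nearest replication.

    Returns
    -------
    ParticleVelocityField
        Movie with one frame fewer than the ensemble.
    """
    s = iq.samples
    n_pairs = s.shape[2] - 1
    extents = (s.shape[0], s.shape[1], n_pairs)
    kernel = (int(kernel_depth), int(kernel_lateral), int(kernel_time))
    for k, n, name in zip(kernel, extents, ("depth", "lateral", "time")):
        if k < 1:
            raise ValueError(f"kernel_{name} must be >= 1")
        if k > n:
            raise ValueError(f"kernel_{name} = {k} exceeds data extent {n}")

    r1 = s[:, :, 1:] * np.conj(s[:, :, :-1])
    for axis, k in enumerate(kernel):
        if k == 1:
            continue
        # Even extents use a centred window with half-weight endpoints so
        # the average stays phase-centred on the output sample (a plain
        # even moving average would shift the movie by half a sample).
        if k % 2:
            w = np.full(k, 1.0 / k)
        else:
            w = np.ones(k + 1)
            w[0] = w[-1] = 0.5
            w /= k
        r1 = ndimage.correlate1d(r1.real, w, axis=axis, mode="nearest") + 1j * (
            ndimage.correlate1d(r1.imag, w, axis=axis, mode="nearest")
        )

    g = iq.grid
    scale = g.sound_speed / (4.0 * np.pi * g.center_frequency * g.frame_interval)
    return ParticleVelocityField(values=scale * np.angle(r1), grid=g)
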