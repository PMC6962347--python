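import numpy as np
import pytest

from plaqueswe import (
    AcquisitionGrid,
    DispersionLaw,
    ParticleVelocityField,
    WaveSimConfig,
    simulate_wavefield,
)


@pytest.fixture(scope="session")
def default_grid():
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def small_grid():
    return AcquisitionGrid(n_depth=8, n_lateral=64, n_frames=64)


@pytest.fixture(scope="session")
def constant_field_5ms():
    """Noise-free dual-push field at a constant 5 m/s, default grid."""
    cfg = WaveSimConfig(dispersion=DispersionLaw.constant(5.0), snr_db=None, seed=1)
    return simulate_wavefield(cfg), cfg


@pytest.fixture(scope="session")
def plate_field():
    """Noise-free dual-push field with plate-A0 dispersion (h=3mm, cT=4)."""
    law = DispersionLaw.plate_a0(h=3e-3, c_T=4.0)
    cfg = WaveSimConfig(dispersion=law, snr_db=None, seed=2)
    return simulate_wavefield(cfg), cfg, law


def make_plane_wave_field(grid, f_cycles=6, k_cycles=8, envelope_alpha=0.6, leftward=False):
    """Bin-aligned plane wave under a Tukey envelope, uniform over depth."""
    from scipy.signal.windows import tukey

    x = grid.lateral_positions
    t = grid.times
    f0 = f_cycles / (grid.n_frames * grid.frame_interval)
    k0 = k_cycles / (grid.n_lateral * grid.lateral_spacing)
    sign = +1 if leftward else -1
    env = np.outer(tukey(grid.n_lateral, envelope_alpha), tukey(grid.n_frames, envelope_alpha))
    v = env * np.cos(2 * np.pi * (f0 * t[None, :] + sign * k0 * x[:, None]))
    values = np.broadcast_to(v[None], (grid.n_depth, grid.n_lateral, grid.n_frames)).copy()
    return ParticleVelocityField(values=values, grid=grid), f0, k0
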