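"""Synthetic dispersive shear-wave fields and speckle IQ ensembles.

The generator emulates a dual-sided acoustic-radiation-force experiment:
two focused pushes are fired simultaneously on the left and right flanks
of the plaque ROI, launching a rightward- and a leftward-travelling
dispersive wave packet that cross inside the ROI. Each packet is built
by frequency-domain synthesis so that its component at frequency f
travels at exactly the phase velocity prescribed by the configured
dispersion law - the analysis stages therefore have an exact recovery
target.

The source waveform is a Gaussian-windowed tone burst (default centre
400 Hz, -6 dB bandwidth 500 Hz, so all three analysis bands in
200-500 Hz contain energy), additionally low-pass shaped by the finite
push duration (sinc factor of a 400 us boxcar). The field is uniform
over depth; depth structure in real data is handled by the ROI mask and
depth averaging downstream, not by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .datatypes import AcquisitionGrid, IQEnsemble, ParticleVelocityField, ROIMask
from .dispersion import DispersionLaw, evaluate_dispersion

__all__ = ["WaveSimConfig", "simulate_wavefield", "modulate_to_iq", "tone_burst_sigma"]

#: -6 dB (half-amplitude) full bandwidth of the source tone burst, Hz.
DEFAULT_BANDWIDTH = 500.0
#: Centre frequency of the source tone burst, Hz.
DEFAULT_CENTER = 400.0


def tone_burst_sigma(bandwidth: float) -> float:
    """Gaussian envelope time constant (s) for a -6 dB full *bandwidth* (Hz).

    The Fourier magnitude of exp(-t^2 / (2 sigma^2)) falls to one half at
    f = sqrt(ln 2) / (sqrt(2) * pi * sigma); solving for sigma with
    f = bandwidth / 2 gives the returned value.
    """
    return np.sqrt(np.log(2.0)) / (np.sqrt(2.0) * np.pi * (bandwidth / 2.0))


@dataclass(frozen=True)
class WaveSimConfig:
    """Configuration for one simulated dual-push acquisition.

    ``push_positions`` are the lateral coordinates (m) of the left and
    right push beams; they must lie on or outside the opposite lateral
    edges of the ROI so both packets traverse it. ``push_time`` is the
    burst centre time at the push location. ``snr_db`` sets additive
    white Gaussian noise relative to the RMS of the clean field;
    ``None`` disables noise.
    """

    grid: AcquisitionGrid = field(default_factory=AcquisitionGrid)
    dispersion: DispersionLaw = field(default_factory=lambda: DispersionLaw.constant(5.0))
    push_positions: Optional[tuple[float, float]] = None
    push_time: float = 2.5e-3
    push_duration: float = 400e-6
    amplitude: float = 0.01
    burst_center: float = DEFAULT_CENTER
    burst_bandwidth: float = DEFAULT_BANDWIDTH
    snr_db: Optional[float] = 20.0
    seed: int = 0
    roi: Optional[ROIMask] = None

    def __post_init__(self) -> None:
        if not self.push_duration > 0:
            raise ValueError("push_duration must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        roi = self.roi if self.roi is not None else ROIMask.box(self.grid)
        object.__setattr__(self, "roi", roi)
        if roi.mask.shape != (self.grid.n_depth, self.grid.n_lateral):
            raise ValueError("ROI mask does not match the acquisition grid")
        x = self.grid.lateral_positions
        cols = roi.lateral_columns
        roi_left, roi_right = x[cols[0]], x[cols[-1]]
        if self.push_positions is None:
            object.__setattr__(self, "push_positions", (float(x[2]), float(x[-3])))
        x_l, x_r = self.push_positions
        if x_l > roi_left or x_r < roi_right:
            raise ValueError(
                "push positions must lie on or outside opposite lateral edges of the ROI"
            )


def _source_signal(cfg: WaveSimConfig, times: np.ndarray) -> np.ndarray:
    sigma = tone_burst_sigma(cfg.burst_bandwidth)
    env = np.exp(-((times - cfg.push_time) ** 2) / (2.0 * sigma**2))
    return env * np.cos(2.0 * np.pi * cfg.burst_center * (times - cfg.push_time))


def simulate_wavefield(config: WaveSimConfig) -> ParticleVelocityField:
    """Simulate the axial particle-velocity movie of a dual-push acquisition.

    Returns a field of shape (n_depth, n_lateral, n_frames) whose peak
    clean amplitude equals ``config.amplitude``. Identical configs
    (including seed) produce bit-identical fields.
    """
    grid = config.grid
    t = grid.times
    x = grid.lateral_positions
    n_t = t.size

    s = _source_signal(config, t)
    spec = np.fft.rfft(s)
    freqs = np.fft.rfftfreq(n_t, grid.frame_interval)
    # Finite push duration low-pass shapes the source spectrum.
    spec = spec * np.sinc(freqs * config.push_duration)

    pos = freqs > 0
    c = np.ones_like(freqs)
    c[pos] = evaluate_dispersion(config.dispersion, freqs[pos])
    k_cyc = np.zeros_like(freqs)
    k_cyc[pos] = freqs[pos] / c[pos]
    spec = spec.copy()
    spec[~pos] = 0.0  # mean removal; c(f) undefined at f = 0

    x_l, x_r = config.push_positions
    # irfft basis is exp(+2*pi*i*f*t): a rightward wave needs phase
    # exp(-2*pi*i*k*(x - x_l)), a leftward one exp(+2*pi*i*k*(x - x_r)).
    phase_r = np.exp(-2.0j * np.pi * np.outer(x - x_l, k_cyc))
    phase_l = np.exp(+2.0j * np.pi * np.outer(x - x_r, k_cyc))
    v_xt = np.fft.irfft(spec[None, :] * (phase_r + phase_l), n=n_t, axis=1)

    peak = np.max(np.abs(v_xt))
    if peak <= 0 or not np.isfinite(peak):
        raise ValueError("simulated packet amplitude vanished; check configuration")
    v_xt *= config.amplitude / peak

    values = np.broadcast_to(v_xt[None, :, :], (grid.n_depth, grid.n_lateral, n_t)).copy()

    if config.snr_db is not None:
        rms = np.sqrt(np.mean(v_xt**2))
        sigma_n = rms * 10.0 ** (-config.snr_db / 20.0)
        if sigma_n > 0 and not np.isfinite(sigma_n):
            raise ValueError("noise level is not finite")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x57E]))
        values = values + rng.normal(0.0, sigma_n, size=values.shape)

    return ParticleVelocityField(values=values, grid=grid)


def modulate_to_iq(
    field: ParticleVelocityField,
    grid: AcquisitionGrid | None = None,
    scatter_seed: int = 0,
) -> IQEnsemble:
    """Encode a particle-velocity movie into a synthetic speckle IQ ensemble.

    Each pixel carries a random speckle reflector (Rayleigh amplitude of
    unit mean, uniform phase, constant over slow time) whose phase
    advances by 4*pi*f0*v*dt/c per frame. A field with T frames yields
    an ensemble with T+1 frames, so that lag-one autocorrelation of the
    ensemble recovers exactly T velocity frames.

    Raises
    ------
    ValueError
        If any |v| reaches the aliasing limit c/(4*f0*dt), where the
        per-frame phase shift would wrap.
    """
    grid = grid if grid is not None else field.grid
    limit = grid.aliasing_limit
    vmax = float(np.max(np.abs(field.values)))
    if vmax >= limit:
        raise ValueError(
            f"particle velocity {vmax:.4g} m/s reaches the aliasing limit "
            f"sound_speed/(4*center_frequency*frame_interval) = {limit:.4g} m/s"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(scatter_seed), 0x1C]))
    shape = field.values.shape[:2]
    # Rayleigh(sigma) has mean sigma*sqrt(pi/2); sigma below gives unit mean.
    amp = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
    phi0 = rng.uniform(-np.pi, np.pi, size=shape)

    dphi = (
        4.0
        * np.pi
        * grid.center_frequency
        * field.values
        * grid.frame_interval
        / grid.sound_speed
    )
    phase = np.concatenate(
        [np.zeros(shape + (1,)), np.cumsum(dphi, axis=2)], axis=2
    )
    samples = amp[..., None] * np.exp(1j * (phi0[..., None] + phase))
    return IQEnsemble(samples=samples, grid=grid)
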