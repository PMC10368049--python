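"""Synthetic RF A-line generation for fibre-probe ultrasound experiments.

Two experiment geometries are emulated:

* **M-mode** (:func:`simulate_mmode`): the probe is fixed and A-lines are
  acquired at the pulse repetition frequency while a thermal lesion of
  increased echogenicity grows bidirectionally from the ablation-fibre tip.
  Heated tissue scatters more strongly (stiffness changes and bubble
  formation), which the generator models as a multiplicative echogenicity
  gain on the scatterers inside the current lesion interval.
* **B-mode scan** (:func:`simulate_bmode_scan`): the probe is translated
  laterally in uniform steps over a static scene of point targets; each
  position yields one monostatic pulse-echo A-line.

The generative model is deliberately simple — band-limited pulse convolved
with a sparse reflectivity train, plus static cross-talk / reverberation and
white noise — because the analysis chain only assumes this statistical
structure, not full wave physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve, gausspulse

from .records import RFRecord, GroundTruth, MM_PER_M

#: Upper edge of the analysis band (Hz); the sampling rate must stay
#: Nyquist-safe for content up to this frequency.
ANALYSIS_BAND_TOP_HZ = 40e6

#: Duration of the static transmitter-receiver cross-talk waveform (s).
CROSSTALK_DURATION_S = 0.5e-6

#: Needle-lumen reverberation: echo spacing (mm) and per-echo decay.
REVERB_SPACING_MM = 0.8
REVERB_DECAY = 0.6
N_REVERB_ECHOES = 4


@dataclass
class SimulationConfig:
    """Full generative description of a simulated acquisition.

    Depths are in mm, times in s, frequencies in Hz.  ``fibre_tip_depth``
    is measured below the tissue surface, so the tip sits at absolute depth
    ``surface_depth + fibre_tip_depth``.  The lesion extent at time ``t``
    follows a saturating exponential during ablation,

    ``E(t) = lesion_max_extent * (1 - exp(-(t - laser_on_time) / lesion_growth_tau))``,

    is zero beforehand and frozen at its switch-off value afterwards.
    Identical config and seed give bit-identical output.
    """

    sampling_rate: float = 125e6
    prf: float = 100.0                    # A-line repetition rate
    sound_speed: float = 1540.0           # soft tissue
    pulse_center_freq: float = 15e6
    pulse_frac_bandwidth: float = 0.6     # -6 dB fractional bandwidth
    surface_depth: float = 1.0
    fibre_tip_depth: float = 7.0          # below the tissue surface
    laser_on_time: float = 10.0           # imaging lead-in before ablation
    laser_duration: float = 60.0
    post_laser_time: float = 10.0         # imaging tail after switch-off
    lesion_max_extent: float = 5.8
    lesion_growth_tau: float = 15.0
    lesion_echogenicity_gain: float = 2.5
    scatterer_density: float = 20.0       # speckle scatterers per mm
    speckle_amplitude: float = 0.1        # scatterer amplitude std (surface echo = 1)
    surface_amplitude: float = 1.0
    crosstalk_amplitude: float = 0.5
    reverb_amplitude: float = 0.05
    noise_std: float = 0.002
    n_samples: int = 2200
    n_acquisitions: Optional[int] = None  # default: prf * total imaging time
    lateral_step: Optional[float] = None  # mm, B-mode scans only
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * ANALYSIS_BAND_TOP_HZ:
            raise ValueError(
                f"sampling_rate {self.sampling_rate:g} Hz is not Nyquist-safe for "
                f"{ANALYSIS_BAND_TOP_HZ / 1e6:g} MHz analysis content"
            )
        if self.lesion_echogenicity_gain <= 1:
            raise ValueError("lesion_echogenicity_gain must be > 1")
        if self.lesion_max_extent < 0:
            raise ValueError("lesion_max_extent must be >= 0")
        for name in ("laser_on_time", "laser_duration", "post_laser_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.prf <= 0 or self.sound_speed <= 0 or self.n_samples < 1:
            raise ValueError("prf, sound_speed and n_samples must be positive")
        if self.lesion_growth_tau <= 0:
            raise ValueError("lesion_growth_tau must be > 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def fibre_tip_depth_abs(self) -> float:
        """Fibre-tip depth below the probe (mm)."""
        return self.surface_depth + self.fibre_tip_depth

    @property
    def total_time(self) -> float:
        return self.laser_on_time + self.laser_duration + self.post_laser_time

    @property
    def axial_pitch_mm(self) -> float:
        return self.sound_speed * MM_PER_M / (2.0 * self.sampling_rate)

    @property
    def max_depth_mm(self) -> float:
        return (self.n_samples - 1) * self.axial_pitch_mm

    def resolve_n_acquisitions(self) -> int:
        if self.n_acquisitions is not None:
            return int(self.n_acquisitions)
        return int(round(self.prf * self.total_time))

    def lesion_extent_at(self, t: np.ndarray) -> np.ndarray:
        """Vertical lesion extent (mm) at acquisition times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        t_on = self.laser_on_time
        t_off = self.laser_on_time + self.laser_duration
        t_eff = np.clip(t, t_on, t_off) - t_on
        extent = self.lesion_max_extent * (1.0 - np.exp(-t_eff / self.lesion_growth_tau))
        return np.where(t < t_on, 0.0, extent)

    def to_dict(self) -> dict:
        return asdict(self)


def _pulse_kernel(config: SimulationConfig) -> np.ndarray:
    """Symmetric Gaussian-modulated sinusoid sampled at the RF rate."""
    tc = gausspulse(
        "cutoff", fc=config.pulse_center_freq, bw=config.pulse_frac_bandwidth, tpr=-60
    )
    n = int(np.ceil(tc * config.sampling_rate))
    t = np.arange(-n, n + 1) / config.sampling_rate
    return gausspulse(t, fc=config.pulse_center_freq, bw=config.pulse_frac_bandwidth)


def _deposit(refl: np.ndarray, depths_mm: np.ndarray, amps: np.ndarray,
             config: SimulationConfig) -> None:
    """Scatter reflector amplitudes into ``refl`` (in place).

    Fractional sample positions are split linearly between the two adjacent
    bins so echo times are accurate to well below one sample.  ``amps`` may
    be 1-D (static, broadcast over acquisitions when ``refl`` is 2-D) or 2-D
    ``(n_reflectors, n_acquisitions)``.
    """
    pos = np.asarray(depths_mm, float) / config.axial_pitch_mm
    keep = (pos >= 0) & (pos <= config.n_samples - 1)
    pos, amps = pos[keep], np.asarray(amps, float)[keep]
    if pos.size == 0:
        return
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    i1 = np.minimum(i0 + 1, config.n_samples - 1)
    if refl.ndim == 1:
        np.add.at(refl, i0, amps * (1 - frac))
        np.add.at(refl, i1, amps * frac)
    else:
        if amps.ndim == 1:
            amps = amps[:, None]
        np.add.at(refl, i0, amps * (1 - frac)[:, None])
        np.add.at(refl, i1, amps * frac[:, None])


def _crosstalk_waveform(config: SimulationConfig) -> Tuple[np.ndarray, int]:
    """Static early-time cross-talk: a damped oscillation at the pulse
    centre frequency occupying the first ~``CROSSTALK_DURATION_S`` of every
    A-line (direct transmitter-to-receiver propagation)."""
    n_ct = int(round(CROSSTALK_DURATION_S * config.sampling_rate))
    n_ct = min(n_ct, config.n_samples)
    t = np.arange(n_ct) / config.sampling_rate
    wave = np.zeros(config.n_samples)
    wave[:n_ct] = (
        config.crosstalk_amplitude
        * np.sin(2 * np.pi * config.pulse_center_freq * t)
        * np.exp(-t / (CROSSTALK_DURATION_S / 3.0))
    )
    return wave, n_ct


def _static_reflectivity(config: SimulationConfig) -> np.ndarray:
    """Surface echo plus needle-lumen reverberation (identical every shot)."""
    refl = np.zeros(config.n_samples)
    _deposit(refl, np.array([config.surface_depth]),
             np.array([config.surface_amplitude]), config)
    if config.reverb_amplitude > 0:
        k = np.arange(1, N_REVERB_ECHOES + 1)
        _deposit(refl, k * REVERB_SPACING_MM,
                 config.reverb_amplitude * REVERB_DECAY ** (k - 1), config)
    return refl


def simulate_mmode(config: SimulationConfig) -> Tuple[RFRecord, GroundTruth]:
    """Simulate a fixed-probe M-mode acquisition during laser ablation.

    Each A-line is a band-limited pulse convolved with a reflectivity train:
    a strong surface reflector, random speckle scatterers, and — inside the
    current lesion interval, centred on the fibre tip — scatterer amplitudes
    multiplied by ``lesion_echogenicity_gain``.  A static cross-talk
    waveform, static reverberation echoes and white Gaussian noise are added.

    Returns the RF record and the exact per-acquisition ground truth.

    Raises
    ------
    ValueError
        If the fully grown lesion would extend beyond the sampled depth
        window (the truth would not be measurable).
    """
    lesion_bottom = config.fibre_tip_depth_abs + config.lesion_max_extent / 2.0
    if lesion_bottom > config.max_depth_mm:
        raise ValueError(
            f"lesion would reach {lesion_bottom:.2f} mm but the sampled window "
            f"ends at {config.max_depth_mm:.2f} mm"
        )
    if config.fibre_tip_depth_abs > config.max_depth_mm:
        raise ValueError("fibre tip lies beyond the sampled depth window")

    rng = np.random.default_rng(config.rng_seed)
    n_acq = config.resolve_n_acquisitions()
    t_acq = np.arange(n_acq) / config.prf
    extent = config.lesion_extent_at(t_acq)

    # speckle scatterers: fixed positions/base amplitudes for the whole run
    span = max(config.max_depth_mm - config.surface_depth, 0.0)
    n_scat = int(round(config.scatterer_density * span))
    scat_depth = rng.uniform(config.surface_depth, config.max_depth_mm, n_scat)
    scat_amp = rng.normal(0.0, config.speckle_amplitude, n_scat)

    refl = np.zeros((config.n_samples, n_acq))
    refl += _static_reflectivity(config)[:, None]
    if n_scat:
        in_lesion = (
            np.abs(scat_depth[:, None] - config.fibre_tip_depth_abs)
            <= extent[None, :] / 2.0
        )
        amps = scat_amp[:, None] * np.where(
            in_lesion, config.lesion_echogenicity_gain, 1.0
        )
        _deposit(refl, scat_depth, amps, config)

    rf = fftconvolve(refl, _pulse_kernel(config)[:, None], mode="same", axes=0)

    crosstalk, n_ct = _crosstalk_waveform(config)
    rf += crosstalk[:, None]
    if config.noise_std > 0:
        rf += rng.normal(0.0, config.noise_std, rf.shape)

    record = RFRecord(
        data=rf,
        sampling_rate=config.sampling_rate,
        sound_speed=config.sound_speed,
        prf=config.prf,
    )
    truth = GroundTruth(
        time_s=t_acq,
        lesion_extent_mm=extent,
        fibre_tip_depth_mm=config.fibre_tip_depth_abs,
        laser_on_index=int(np.searchsorted(t_acq, config.laser_on_time)),
        laser_off_index=int(
            np.searchsorted(t_acq, config.laser_on_time + config.laser_duration)
        ),
        crosstalk_n_samples=n_ct,
    )
    return record, truth


def simulate_bmode_scan(
    config: SimulationConfig,
    point_targets: Sequence[Tuple[float, float, float]],
) -> RFRecord:
    """Simulate a stepwise lateral scan over static point targets.

    The probe occupies positions ``x_p = p * lateral_step`` for
    ``p = 0 .. n_acquisitions-1``.  A target at ``(x_t, z_t)`` with amplitude
    ``a`` contributes, in the A-line at position ``x_p``, an echo at two-way
    time ``2 * sqrt(z_t^2 + (x_p - x_t)^2) / c`` with ``a / r`` spherical
    amplitude decay.  Speckle background scatterers are added when
    ``scatterer_density > 0``.

    Raises
    ------
    ValueError
        If ``lateral_step`` is unset/non-positive or a target's closest
        approach lies outside the sampled depth window.
    """
    if config.lateral_step is None or config.lateral_step <= 0:
        raise ValueError("B-mode scans require lateral_step > 0")
    if config.n_acquisitions is None:
        raise ValueError("B-mode scans require an explicit n_acquisitions (scan positions)")

    rng = np.random.default_rng(config.rng_seed)
    n_pos = int(config.n_acquisitions)
    x_probe = np.arange(n_pos) * config.lateral_step

    for (xt, zt, amp) in point_targets:
        if not (0.0 < zt <= config.max_depth_mm):
            raise ValueError(
                f"point target at depth {zt:g} mm lies outside the sampled "
                f"window (0, {config.max_depth_mm:.2f}] mm"
            )

    refl = np.zeros((config.n_samples, n_pos))

    def add_scene(xs: np.ndarray, zs: np.ndarray, amps: np.ndarray) -> None:
        # (n_targets, n_pos) two-way ranges; hyperbola tails beyond the
        # window are clipped by _deposit
        dx = x_probe[None, :] - xs[:, None]
        r = np.hypot(zs[:, None], dx)                     # mm
        a = amps[:, None] / np.maximum(r, 1e-6)
        for p in range(n_pos):
            _deposit(refl[:, p], r[:, p], a[:, p], config)

    if point_targets:
        xs, zs, amps = (np.asarray(v, float) for v in zip(*point_targets))
        add_scene(xs, zs, amps)

    if config.scatterer_density > 0:
        span = max(config.max_depth_mm - config.surface_depth, 0.0)
        n_scat = int(round(config.scatterer_density * span))
        sx = rng.uniform(x_probe[0], x_probe[-1], n_scat)
        sz = rng.uniform(config.surface_depth, config.max_depth_mm, n_scat)
        sa = rng.normal(0.0, config.speckle_amplitude, n_scat)
        add_scene(sx, sz, sa)

    rf = fftconvolve(refl, _pulse_kernel(config)[:, None], mode="same", axes=0)
    if config.crosstalk_amplitude > 0:
        rf += _crosstalk_waveform(config)[0][:, None]
    if config.noise_std > 0:
        rf += rng.normal(0.0, config.noise_std, rf.shape)

    return RFRecord(
        data=rf,
        sampling_rate=config.sampling_rate,
        sound_speed=config.sound_speed,
        lateral_step=config.lateral_step,
    )
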