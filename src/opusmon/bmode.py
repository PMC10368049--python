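"""B-mode synthetic-aperture reconstruction from laterally scanned data.

The production reconstructor is Stolt (f-k) migration under the
exploding-reflector model: a monostatic pulse-echo section recorded at speed
``c`` is equivalent to a one-way section at ``c/2``, whose 2-D spectrum over
(time, lateral) can be remapped from temporal frequency ``f`` to vertical
wavenumber ``k_z`` via the dispersion relation ``f = v * sqrt(k_x^2 + k_z^2)``
(``v = c/2``), with the Jacobian ``v * |k_z| / sqrt(k_x^2 + k_z^2)``
weighting the resampled spectrum.  Evanescent components
(``|f| < v |k_x|``) are never sampled by the remap and therefore vanish.

A brute-force delay-and-sum beamformer is provided as an independent
reference: it focuses each image pixel by summing, across scan positions,
the RF sample at the two-way travel time to that pixel.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import fft as sfft
from scipy.signal import hilbert

from .records import RFRecord, BModeImage, MM_PER_M
from .preprocess import FilterSpec, bandpass, envelope_logcompress, tgc, fit_crosstalk_glm, remove_crosstalk

MIN_SCAN_POSITIONS = 4


def _check_scan(record: RFRecord, positions_mm: Optional[np.ndarray]) -> np.ndarray:
    if record.is_mmode:
        raise ValueError("record is an M-mode record, not a lateral scan")
    if record.n_acquisitions < MIN_SCAN_POSITIONS:
        raise ValueError(
            f"need at least {MIN_SCAN_POSITIONS} scan positions, "
            f"got {record.n_acquisitions}"
        )
    if positions_mm is None:
        positions_mm = record.acquisition_axis
    positions_mm = np.asarray(positions_mm, float)
    steps = np.diff(positions_mm)
    if positions_mm.size != record.n_acquisitions:
        raise ValueError("positions do not match the number of acquisitions")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12) or steps[0] <= 0:
        raise ValueError("non-uniform lateral spacing — f-k migration requires a uniform scan")
    return positions_mm


def kspace_reconstruct(
    record: RFRecord,
    sound_speed: Optional[float] = None,
    pad_factor: int = 2,
    positions_mm: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stolt f-k migration of a uniform monostatic scan.

    Returns the complex migrated image on the native (axial sample, scan
    position) grid; the physical depth of row ``i`` equals the record's
    ``depth_axis_mm[i]``.  Linear interpolation is used for the spectral
    remap and the section is zero-padded by ``pad_factor`` in both axes to
    reduce wrap-around.
    """
    _check_scan(record, positions_mm)
    c = sound_speed if sound_speed is not None else record.sound_speed
    v = c / 2.0  # exploding-reflector (one-way) speed for pulse-echo data

    nt, nx = record.data.shape
    dt = 1.0 / record.sampling_rate
    dx = record.lateral_step / MM_PER_M  # m
    ntp = sfft.next_fast_len(pad_factor * nt)
    nxp = sfft.next_fast_len(pad_factor * nx)

    spec = sfft.fft2(record.data, s=(ntp, nxp), axes=(0, 1))
    f = sfft.fftfreq(ntp, dt)            # Hz
    kx = sfft.fftfreq(nxp, dx)           # cycles / m
    # output depth grid keeps the native pitch dz = v * dt
    kz = sfft.fftfreq(ntp, v * dt)       # cycles / m

    # frequency each (kz, kx) pair maps from, and the Stolt Jacobian
    kmag = np.sqrt(kz[:, None] ** 2 + kx[None, :] ** 2)
    f_map = v * np.sign(kz)[:, None] * kmag
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = v * np.abs(kz)[:, None] / np.where(kmag > 0, kmag, np.inf)

    f_sorted = np.sort(f)
    order = np.argsort(f)
    migrated = np.empty_like(spec)
    for j in range(nxp):
        col = spec[order, j]
        re = np.interp(f_map[:, j], f_sorted, col.real, left=0.0, right=0.0)
        im = np.interp(f_map[:, j], f_sorted, col.imag, left=0.0, right=0.0)
        migrated[:, j] = (re + 1j * im) * jac[:, j]

    img = sfft.ifft2(migrated, axes=(0, 1))
    return img[:nt, :nx]


def delay_and_sum(
    record: RFRecord,
    sound_speed: Optional[float] = None,
    grid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Reference delay-and-sum beamformer on an explicit pixel grid.

    ``grid`` is ``(depth_axis_mm, lateral_axis_mm)``; the default is the
    record's native grid.  For every pixel the RF sample at two-way time
    ``2 sqrt(dx^2 + z^2) / c`` is gathered from each scan position with
    linear interpolation and summed (no apodization).
    """
    positions = _check_scan(record, None)
    c = sound_speed if sound_speed is not None else record.sound_speed
    c_mm = c * MM_PER_M  # mm/s
    if grid is None:
        z_mm, x_mm = record.depth_axis_mm, positions
    else:
        z_mm, x_mm = (np.asarray(g, float) for g in grid)

    fs, t0 = record.sampling_rate, record.t0
    n = record.n_samples
    out = np.zeros((z_mm.size, x_mm.size))
    for p, xp in enumerate(positions):
        r = np.hypot(z_mm[:, None], x_mm[None, :] - xp)      # mm
        idx = (2.0 * r / c_mm - t0) * fs
        i0 = np.floor(idx).astype(int)
        frac = idx - i0
        valid = (i0 >= 0) & (i0 < n - 1)
        i0c = np.clip(i0, 0, n - 2)
        col = record.data[:, p]
        out += np.where(valid, col[i0c] * (1 - frac) + col[i0c + 1] * frac, 0.0)
    return out


def full_bmode_pipeline(
    record: RFRecord,
    filter_spec: Optional[FilterSpec] = None,
    tgc_attenuation_db_per_cm_mhz: Optional[float] = None,
    tgc_ref_freq: float = 15e6,
    crosstalk_reference: Optional[str] = "all",
    sound_speed: Optional[float] = None,
    dynamic_range_db: float = 40.0,
) -> BModeImage:
    """B-mode chain: band-pass, TGC, cross-talk removal, f-k migration,
    envelope and log compression — in that order.

    Any preprocessing stage can be disabled by passing ``None`` for its
    parameter, in which case the pipeline reduces to migration plus
    envelope/log display.  The B-mode GLM reference is the whole scan
    (``crosstalk_reference="all"``): only signal content static across every
    lateral position — cross-talk and reverberation — survives averaging.
    """
    rec = record
    if filter_spec is not None:
        rec = bandpass(rec, filter_spec)
    if tgc_attenuation_db_per_cm_mhz is not None:
        rec = tgc(rec, tgc_attenuation_db_per_cm_mhz, tgc_ref_freq)
    if crosstalk_reference is not None:
        if crosstalk_reference != "all":
            raise ValueError("crosstalk_reference must be 'all' or None")
        model = fit_crosstalk_glm(rec, range(rec.n_acquisitions))
        rec = remove_crosstalk(rec, model)

    migrated = kspace_reconstruct(rec, sound_speed=sound_speed)
    rf_image = rec.copy_with(np.real(migrated))
    pixels = envelope_logcompress(rf_image, dynamic_range_db)
    return BModeImage(
        pixels=pixels,
        depth_axis_mm=record.depth_axis_mm,
        lateral_axis_mm=record.acquisition_axis,
        dynamic_range_db=dynamic_range_db,
    )
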