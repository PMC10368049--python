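"""Shared RF signal-conditioning chain.

Order of operations for M-mode monitoring: band-pass filtering (1.5–40 MHz
Butterworth), general-linear-model (GLM) removal of static cross-talk /
reverberation / unablated-tissue signal, then Hilbert envelope and log
compression.  B-mode adds time gain compensation (TGC) between filtering and
cross-talk removal.

Filtering is zero-phase (forward-backward second-order sections) so envelope
timing is not skewed.  The GLM regresses every A-line onto a static template
— the mean of a set of reference acquisitions, plus ±1-sample shifted copies
to absorb timing jitter — and subtracts the fitted component; anything
unchanged over time is cancelled while time-varying (lesion) signal passes
through essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt, sosfreqz, hilbert

from .records import RFRecord


@dataclass
class FilterSpec:
    """Band-pass filter description (Butterworth only)."""

    low_cut: float = 1.5e6
    high_cut: float = 40e6
    order: int = 4
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.family != "butterworth":
            raise ValueError(f"unsupported filter family: {self.family!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")

    def validate_for(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if self.high_cut >= nyquist:
            raise ValueError(
                f"high_cut {self.high_cut:g} Hz is at/above Nyquist ({nyquist:g} Hz)"
            )

    def sos(self, sampling_rate: float) -> np.ndarray:
        self.validate_for(sampling_rate)
        return butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass",
            fs=sampling_rate, output="sos",
        )

    def response_db(self, sampling_rate: float, freqs_hz: Sequence[float],
                    zero_phase: bool = True) -> np.ndarray:
        """Magnitude response in dB at the given frequencies.

        ``zero_phase=True`` reports the forward-backward (applied) response,
        i.e. twice the single-pass attenuation.
        """
        _, h = sosfreqz(self.sos(sampling_rate), worN=np.asarray(freqs_hz, float),
                        fs=sampling_rate)
        db = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))
        return 2.0 * db if zero_phase else db


@dataclass
class CrosstalkModel:
    """Static-template GLM: ``fitted = regressors @ coefficients``."""

    regressors: np.ndarray   # (n_samples, k)
    coefficients: np.ndarray  # (k, n_acquisitions)

    def __post_init__(self) -> None:
        if self.regressors.ndim != 2 or self.coefficients.ndim != 2:
            raise ValueError("regressors and coefficients must be 2-D")
        if self.regressors.shape[1] != self.coefficients.shape[0]:
            raise ValueError("regressor/coefficient shapes do not chain")


def bandpass(record: RFRecord, spec: FilterSpec) -> RFRecord:
    """Zero-phase band-pass filter along the sample axis, per acquisition."""
    sos = spec.sos(record.sampling_rate)
    return record.copy_with(sosfiltfilt(sos, record.data, axis=0))


def _shifted(template: np.ndarray, shift: int) -> np.ndarray:
    out = np.zeros_like(template)
    if shift == 0:
        out[:] = template
    elif shift > 0:
        out[shift:] = template[:-shift]
    else:
        out[:shift] = template[-shift:]
    return out


def fit_crosstalk_glm(
    record: RFRecord,
    reference_acquisitions: Iterable[int],
    n_shifts: int = 1,
    fit_samples: Optional[np.ndarray] = None,
) -> CrosstalkModel:
    """Fit the static-template GLM.

    The regressor set is the mean A-line over ``reference_acquisitions``
    (typically all pre-ablation acquisitions) and its sample-shifted copies
    ``±1 .. ±n_shifts``; per-acquisition coefficients are the ordinary
    least-squares solution for every column of the record.

    ``fit_samples`` restricts the least-squares fit to a subset of sample
    indices (the subtraction still spans the whole A-line).  Estimating the
    coefficients on the shallow block — cross-talk, needle reverberation and
    the tissue-surface echo, where no lesion can appear — prevents
    time-varying lesion signal from biasing the template gain and leaking
    uncancelled static signal across the whole record.  The default (all
    samples) is the plain whole-record OLS.
    """
    ref_idx = np.asarray(list(reference_acquisitions), dtype=int)
    if ref_idx.size == 0:
        raise ValueError("reference acquisition set is empty")
    k = 2 * n_shifts + 1
    if ref_idx.size < k:
        raise ValueError(
            f"need at least {k} reference acquisitions for {k} regressors, "
            f"got {ref_idx.size}"
        )
    template = record.data[:, ref_idx].mean(axis=1)
    regressors = np.column_stack(
        [_shifted(template, s) for s in range(-n_shifts, n_shifts + 1)]
    )
    if fit_samples is None:
        rows = slice(None)
    else:
        rows = np.asarray(fit_samples, dtype=int)
        if rows.size < k:
            raise ValueError("fit window smaller than the number of regressors")
    coefficients, *_ = np.linalg.lstsq(regressors[rows], record.data[rows], rcond=None)
    return CrosstalkModel(regressors=regressors, coefficients=coefficients)


def remove_crosstalk(record: RFRecord, model: CrosstalkModel) -> RFRecord:
    """Subtract the fitted static component from every acquisition."""
    return record.copy_with(record.data - model.regressors @ model.coefficients)


def tgc(
    record: RFRecord,
    attenuation_db_per_cm_mhz: float,
    ref_freq: float,
    max_gain_db: float = 40.0,
) -> RFRecord:
    """Time gain compensation for frequency-dependent attenuation.

    Sample ``i`` at depth ``d_i`` (cm) is multiplied by
    ``10 ** (alpha * f_ref_MHz * 2 * d_i / 20)`` — the two-way attenuation at
    the reference frequency — with the gain capped at ``max_gain_db``.
    """
    if attenuation_db_per_cm_mhz < 0:
        raise ValueError("attenuation must be >= 0")
    depth_cm = record.depth_axis_mm / 10.0
    gain_db = attenuation_db_per_cm_mhz * (ref_freq / 1e6) * 2.0 * depth_cm
    gain_db = np.minimum(gain_db, max_gain_db)
    return record.copy_with(record.data * (10.0 ** (gain_db / 20.0))[:, None])


def envelope_logcompress(record: RFRecord, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Hilbert envelope followed by log compression.

    Per acquisition the envelope is the magnitude of the analytic signal;
    the image is ``20 log10(envelope / global_max)`` floored at
    ``-dynamic_range_db``, so all pixels lie in ``[-dynamic_range_db, 0]``
    with the global maximum at exactly 0 dB.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    env = np.abs(hilbert(record.data, axis=0))
    peak = env.max()
    if peak == 0:
        return np.full(env.shape, -dynamic_range_db)
    with np.errstate(divide="ignore"):
        img = 20.0 * np.log10(env / peak)
    return np.maximum(img, -dynamic_range_db)
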