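"""In-memory containers for RF data and derived images.

The pipeline's native data object is the :class:`RFRecord`: a real-valued
``(n_samples, n_acquisitions)`` matrix of pulse-echo A-lines plus the sampling
metadata needed to turn sample indices into depths.  A record is either an
M-mode record (fixed probe, columns indexed by acquisition time via ``prf``)
or a B-mode scan record (translated probe, columns indexed by lateral
position via ``lateral_step``) — exactly one of the two fields is set.

Depth convention: sample ``i`` was received at time ``t0 + i / sampling_rate``
after pulse emission, so under the pulse-echo (two-way) convention its depth is
``sound_speed * (t0 + i / sampling_rate) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MM_PER_M = 1e3


@dataclass
class RFRecord:
    """Raw RF A-line matrix with sampling metadata.

    Parameters
    ----------
    data:
        Real matrix of shape ``(n_samples, n_acquisitions)``.
    sampling_rate:
        Axial sampling rate in Hz.
    sound_speed:
        Speed of sound in m/s used for the depth mapping.
    prf:
        Pulse repetition frequency in Hz (M-mode records only).
    lateral_step:
        Probe translation step in mm between columns (B-mode records only).
    t0:
        Time of sample 0 after pulse emission, in seconds.
    """

    data: np.ndarray
    sampling_rate: float
    sound_speed: float
    prf: Optional[float] = None
    lateral_step: Optional[float] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RF data must be a 2-D (samples x acquisitions) matrix")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("RF data must contain at least one sample and one acquisition")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RF data must be finite")
        if (self.prf is None) == (self.lateral_step is None):
            raise ValueError("exactly one of prf (M-mode) or lateral_step (B-mode) must be set")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[1]

    @property
    def is_mmode(self) -> bool:
        return self.prf is not None

    @property
    def sample_times(self) -> np.ndarray:
        """Receive time of each sample after pulse emission (s)."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    @property
    def depth_axis_mm(self) -> np.ndarray:
        """Two-way depth of each sample in mm."""
        return self.sound_speed * MM_PER_M * self.sample_times / 2.0

    @property
    def axial_pitch_mm(self) -> float:
        """Depth spacing between consecutive samples in mm."""
        return self.sound_speed * MM_PER_M / (2.0 * self.sampling_rate)

    @property
    def acquisition_axis(self) -> np.ndarray:
        """Time (s) per column for M-mode, lateral position (mm) for B-mode."""
        idx = np.arange(self.n_acquisitions)
        if self.is_mmode:
            return idx / self.prf
        return idx * self.lateral_step

    def depth_to_sample(self, depth_mm: float) -> int:
        """Nearest sample index for a given two-way depth in mm."""
        t = 2.0 * depth_mm / (self.sound_speed * MM_PER_M)
        return int(round((t - self.t0) * self.sampling_rate))

    def max_depth_mm(self) -> float:
        return float(self.depth_axis_mm[-1])

    def copy_with(self, data: np.ndarray) -> "RFRecord":
        """New record sharing this record's metadata with replaced data."""
        return RFRecord(
            data=data,
            sampling_rate=self.sampling_rate,
            sound_speed=self.sound_speed,
            prf=self.prf,
            lateral_step=self.lateral_step,
            t0=self.t0,
        )


@dataclass
class MModeImage:
    """Log-compressed envelope image: depth (rows, mm) x acquisition time (s).

    ``laser_on_index``/``laser_off_index`` mark the columns at which the
    ablation laser was switched on and off.
    """

    pixels: np.ndarray
    depth_axis_mm: np.ndarray
    time_axis_s: np.ndarray
    laser_on_index: int
    laser_off_index: int
    dynamic_range_db: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.depth_axis_mm = np.asarray(self.depth_axis_mm, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.pixels.shape != (self.depth_axis_mm.size, self.time_axis_s.size):
            raise ValueError("pixel matrix does not match axes")
        if np.any(np.diff(self.depth_axis_mm) <= 0) or np.any(np.diff(self.time_axis_s) <= 0):
            raise ValueError("axes must be strictly increasing")

    @property
    def axial_pitch_mm(self) -> float:
        return float(self.depth_axis_mm[1] - self.depth_axis_mm[0])


@dataclass
class BModeImage:
    """Log-compressed B-mode image: depth (rows, mm) x lateral position (mm)."""

    pixels: np.ndarray
    depth_axis_mm: np.ndarray
    lateral_axis_mm: np.ndarray
    dynamic_range_db: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.depth_axis_mm.size, self.lateral_axis_mm.size):
            raise ValueError("pixel matrix does not match axes")

    @property
    def lateral_span_mm(self) -> float:
        """Imaging aperture: number of scan lines times the lateral step."""
        step = float(self.lateral_axis_mm[1] - self.lateral_axis_mm[0])
        return step * self.lateral_axis_mm.size


@dataclass
class LesionMask:
    """Binary lesion segmentation aligned to an M-mode image.

    ``membership`` holds the fuzzy memberships (n_pixels x c, row-stochastic)
    and ``centroids`` the cluster intensity centroids; ``lesion_cluster`` is
    the index of the brightest (lesion) cluster.
    """

    mask: np.ndarray
    membership: np.ndarray
    centroids: np.ndarray
    lesion_cluster: int
    n_iter: int = 0
    cost_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def copy_with_mask(self, mask: np.ndarray) -> "LesionMask":
        return LesionMask(
            mask=mask,
            membership=self.membership,
            centroids=self.centroids,
            lesion_cluster=self.lesion_cluster,
            n_iter=self.n_iter,
            cost_history=self.cost_history,
        )


@dataclass
class DepthTrace:
    """Per-column lesion depth in mm and the reported post-ablation depth."""

    time_s: np.ndarray
    depth_mm: np.ndarray
    final_depth_mm: float


@dataclass
class GroundTruth:
    """Exact generative state recorded by the M-mode simulator.

    ``lesion_extent_mm[j]`` is the vertical lesion extent used for
    acquisition ``j``; the lesion occupies
    ``[fibre_tip_depth_mm - extent/2, fibre_tip_depth_mm + extent/2]``
    (absolute depth below the probe).  ``crosstalk_n_samples`` labels the
    static early-sample block occupied by transmitter-receiver cross-talk.
    """

    time_s: np.ndarray
    lesion_extent_mm: np.ndarray
    fibre_tip_depth_mm: float
    laser_on_index: int
    laser_off_index: int
    crosstalk_n_samples: int

    @property
    def final_extent_mm(self) -> float:
        return float(self.lesion_extent_mm[-1])
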