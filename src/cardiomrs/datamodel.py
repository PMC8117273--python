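"""Shared data types for single-voxel cardiac MRS processing.

The pipeline operates on series of complex free-induction decays (FIDs)
acquired shot by shot (one shot per heartbeat) on a multi-channel receive
array.  Everything downstream — coil combination, retrospective gating,
model fitting, quantification — consumes the containers defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np


class Sequence(str, enum.Enum):
    """Single-voxel localization sequence."""

    PRESS = "PRESS"
    SLASER = "SLASER"
    STEAM = "STEAM"


class ValidationError(ValueError):
    """An invariant of a data container was violated."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata attached to every FID series.

    Parameters
    ----------
    sequence
        Localization sequence (PRESS, sLASER or STEAM).
    te_s, tr_s, tm_s
        Echo time, repetition period and (STEAM only) mixing time, seconds.
        ``tr_s`` is the *effective* repetition period: when ECG triggering
        forces one excitation every second heartbeat it equals 2 x RR.
    f0_mhz
        Transmitter (Larmor) frequency in MHz; 123.2 MHz at 3 T for protons.
    dwell_s
        Sampling interval of the FID in seconds.
    n_points, n_channels, n_shots
        Samples per FID, receive channels, acquired averages.
    refocus_bw_hz
        Bandwidth of the slice-selective refocusing pulse (Hz); sets the
        chemical-shift displacement error.
    voxel_mm
        Three spatial voxel extents in mm.
    water_suppressed
        Whether water suppression was played out.
    reference_ppm
        Chemical shift assigned to the carrier frequency (water, 4.7 ppm).
    """

    sequence: Sequence = Sequence.PRESS
    te_s: float = 0.02396
    tr_s: float = 1.1
    tm_s: float = 0.0
    f0_mhz: float = 123.2
    dwell_s: float = 0.0004
    n_points: int = 2048
    n_channels: int = 1
    n_shots: int = 1
    refocus_bw_hz: float = 1150.0
    voxel_mm: tuple[float, float, float] = (15.0, 20.0, 30.0)
    water_suppressed: bool = True
    reference_ppm: float = 4.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", Sequence(self.sequence))
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))
        if self.te_s < 0:
            raise ValidationError(f"te_s must be >= 0, got {self.te_s}")
        if self.tr_s <= self.te_s:
            raise ValidationError(
                f"tr_s ({self.tr_s}) must exceed te_s ({self.te_s})"
            )
        if self.sequence is not Sequence.STEAM and self.tm_s != 0.0:
            raise ValidationError("tm_s must be 0 unless sequence is STEAM")
        if self.tm_s < 0:
            raise ValidationError("tm_s must be >= 0")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.dwell_s <= 0:
            raise ValidationError("dwell_s must be > 0")
        if self.refocus_bw_hz <= 0:
            raise ValidationError("refocus_bw_hz must be > 0")
        if self.f0_mhz <= 0:
            raise ValidationError("f0_mhz must be > 0")
        if self.n_channels < 1 or self.n_shots < 1:
            raise ValidationError("n_channels and n_shots must be >= 1")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValidationError("voxel_mm must be three positive extents")

    @property
    def bandwidth_hz(self) -> float:
        """Spectral (sampling) bandwidth 1/dwell, Hz."""
        return 1.0 / self.dwell_s

    @property
    def time_axis_s(self) -> np.ndarray:
        """Sample times t_k = k * dwell, seconds."""
        return np.arange(self.n_points) * self.dwell_s

    def with_(self, **kw) -> "AcquisitionParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class FIDSeries:
    """A stack of complex FIDs indexed (shot, channel, time).

    ``data`` must have shape ``(acq.n_shots, acq.n_channels, acq.n_points)``
    and contain only finite samples.  ``shot_index`` carries the original
    heartbeat counter so rejected shots remain traceable after gating.
    """

    data: np.ndarray
    acq: AcquisitionParams
    shot_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        expected = (self.acq.n_shots, self.acq.n_channels, self.acq.n_points)
        if self.data.shape != expected:
            raise ValidationError(
                f"data shape {self.data.shape} does not match metadata {expected}"
            )
        if not np.isfinite(self.data.real).all() or not np.isfinite(self.data.imag).all():
            raise ValidationError("FID data contains non-finite samples")
        if self.shot_index is None:
            self.shot_index = np.arange(self.acq.n_shots)
        else:
            self.shot_index = np.asarray(self.shot_index, dtype=np.int64)
            if self.shot_index.shape != (self.acq.n_shots,):
                raise ValidationError("shot_index length must equal n_shots")

    @property
    def n_shots(self) -> int:
        return self.acq.n_shots

    @property
    def n_channels(self) -> int:
        return self.acq.n_channels

    def subset_shots(self, mask: np.ndarray) -> "FIDSeries":
        """Series restricted to the shots selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.acq.n_shots,):
            raise ValidationError("mask length must equal n_shots")
        n_kept = int(mask.sum())
        if n_kept == 0:
            raise ValidationError("subset would be empty: all shots rejected")
        return FIDSeries(
            data=self.data[mask],
            acq=self.acq.with_(n_shots=n_kept),
            shot_index=self.shot_index[mask],
        )


@dataclass
class Spectrum:
    """Frequency-domain view of a FID on a descending ppm axis.

    Point ``k`` maps to ``ppm = reference_ppm + f_k / f0_mhz`` with ``f_k``
    the DFT frequency in Hz; the axis is stored left-to-right in descending
    ppm (NMR convention), so water sits at 4.7 ppm and lipid methylene at
    1.3 ppm to its right.
    """

    values: np.ndarray
    ppm_axis: np.ndarray
    hz_per_ppm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=np.float64)
        if self.values.shape != self.ppm_axis.shape:
            raise ValidationError("values and ppm_axis must have equal length")
        d = np.diff(self.ppm_axis)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValidationError("ppm_axis must be strictly monotonic")

    @property
    def hz_per_point(self) -> float:
        return abs(float(self.ppm_axis[1] - self.ppm_axis[0])) * self.hz_per_ppm

    def index_of_ppm(self, ppm: float) -> int:
        """Grid index closest to a chemical shift."""
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def window(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask selecting lo_ppm <= axis <= hi_ppm."""
        return (self.ppm_axis >= lo_ppm) & (self.ppm_axis <= hi_ppm)
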