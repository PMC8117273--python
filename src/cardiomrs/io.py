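"""On-disk container for FID series.

Layout (HDF5):

    /series/real     float64, shape (n_shots, n_channels, n_points)
    /series/imag     float64, same shape
    /series/shot_index  int64, shape (n_shots,)
    /series attrs    one scalar attribute per acquisition-metadata field

Complex data is stored as paired real/imag float arrays rather than a
compound dtype so any HDF5 reader can open the file.  The attribute names
match :class:`~cardiomrs.datamodel.AcquisitionParams` fields one-to-one;
``to_nifti_mrs_header``/``from_nifti_mrs_header`` translate the subset that
has a NIfTI-MRS standard-header counterpart.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .datamodel import AcquisitionParams, FIDSeries, Sequence, ValidationError

_GROUP = "series"

_SCALAR_FIELDS = (
    "te_s",
    "tr_s",
    "tm_s",
    "f0_mhz",
    "dwell_s",
    "n_points",
    "n_channels",
    "n_shots",
    "refocus_bw_hz",
    "reference_ppm",
)


def write_series(series: FIDSeries, path: str | os.PathLike) -> str:
    """Write a validated :class:`FIDSeries` to an HDF5 container.

    The round trip ``read_series(write_series(s))`` is bit-exact for the
    complex payload and every metadata field.
    """
    if not isinstance(series, FIDSeries):
        raise TypeError("series must be a FIDSeries")
    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        g = f.create_group(_GROUP)
        g.create_dataset("real", data=series.data.real)
        g.create_dataset("imag", data=series.data.imag)
        g.create_dataset("shot_index", data=series.shot_index)
        acq = series.acq
        g.attrs["sequence"] = acq.sequence.value
        for name in _SCALAR_FIELDS:
            g.attrs[name] = getattr(acq, name)
        g.attrs["voxel_mm"] = np.asarray(acq.voxel_mm, dtype=np.float64)
        g.attrs["water_suppressed"] = bool(acq.water_suppressed)
    return path


def read_series(path: str | os.PathLike) -> FIDSeries:
    """Read a container written by :func:`write_series`.

    Raises
    ------
    ValidationError
        If a metadata attribute is missing (the message names the field) or
        the array shape disagrees with the stored metadata.
    """
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        if _GROUP not in f:
            raise ValidationError(f"container has no '/{_GROUP}' group: {path}")
        g = f[_GROUP]
        missing = [
            n
            for n in ("sequence", *_SCALAR_FIELDS, "voxel_mm", "water_suppressed")
            if n not in g.attrs
        ]
        if missing:
            raise ValidationError(
                "container missing metadata field(s): " + ", ".join(missing)
            )
        acq = AcquisitionParams(
            sequence=Sequence(str(g.attrs["sequence"])),
            te_s=float(g.attrs["te_s"]),
            tr_s=float(g.attrs["tr_s"]),
            tm_s=float(g.attrs["tm_s"]),
            f0_mhz=float(g.attrs["f0_mhz"]),
            dwell_s=float(g.attrs["dwell_s"]),
            n_points=int(g.attrs["n_points"]),
            n_channels=int(g.attrs["n_channels"]),
            n_shots=int(g.attrs["n_shots"]),
            refocus_bw_hz=float(g.attrs["refocus_bw_hz"]),
            voxel_mm=tuple(np.asarray(g.attrs["voxel_mm"], dtype=float)),
            water_suppressed=bool(g.attrs["water_suppressed"]),
            reference_ppm=float(g.attrs["reference_ppm"]),
        )
        real = np.asarray(g["real"])
        imag = np.asarray(g["imag"])
        if real.shape != imag.shape:
            raise ValidationError(
                f"real/imag shape mismatch: {real.shape} vs {imag.shape}"
            )
        shot_index = np.asarray(g["shot_index"]) if "shot_index" in g else None
    data = real + 1j * imag
    # FIDSeries.__post_init__ raises if the array disagrees with metadata
    return FIDSeries(data=data, acq=acq, shot_index=shot_index)


# NIfTI-MRS standard-header key <-> AcquisitionParams field (units differ:
# NIfTI-MRS uses ms for times and MHz for the transmitter frequency).
_NIFTI_MRS_MAP = {
    "SpectrometerFrequency": ("f0_mhz", 1.0),
    "EchoTime": ("te_s", 1000.0),
    "RepetitionTime": ("tr_s", 1000.0),
    "MixingTime": ("tm_s", 1000.0),
    "DwellTime": ("dwell_s", 1000.0),
}


def to_nifti_mrs_header(acq: AcquisitionParams) -> dict:
    """NIfTI-MRS-style header dict for the fields with a standard key.

    Converter stub for interoperability; geometry and sequence details
    outside the standard keys are carried under ``cardiomrs_*`` entries.
    """
    hdr = {key: getattr(acq, f) * scale for key, (f, scale) in _NIFTI_MRS_MAP.items()}
    hdr["ResonantNucleus"] = "1H"
    hdr["cardiomrs_sequence"] = acq.sequence.value
    hdr["cardiomrs_refocus_bw_hz"] = acq.refocus_bw_hz
    hdr["cardiomrs_voxel_mm"] = list(acq.voxel_mm)
    hdr["cardiomrs_water_suppressed"] = acq.water_suppressed
    return hdr


def from_nifti_mrs_header(hdr: dict, **overrides) -> AcquisitionParams:
    """Build :class:`AcquisitionParams` from a NIfTI-MRS-style header.

    Fields without a standard key (array sizes, reference ppm) must be
    supplied via ``overrides``.
    """
    kw = {}
    for key, (f, scale) in _NIFTI_MRS_MAP.items():
        if key in hdr:
            kw[f] = float(hdr[key]) / scale
    if "cardiomrs_sequence" in hdr:
        kw["sequence"] = Sequence(hdr["cardiomrs_sequence"])
    if "cardiomrs_refocus_bw_hz" in hdr:
        kw["refocus_bw_hz"] = float(hdr["cardiomrs_refocus_bw_hz"])
    if "cardiomrs_voxel_mm" in hdr:
        kw["voxel_mm"] = tuple(hdr["cardiomrs_voxel_mm"])
    if "cardiomrs_water_suppressed" in hdr:
        kw["water_suppressed"] = bool(hdr["cardiomrs_water_suppressed"])
    kw.update(overrides)
    return AcquisitionParams(**kw)
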