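"""PET volume handling and body-weight SUV conversion.

The standardized uptake value normalizes measured activity concentration
to the injected dose per unit body mass:

    SUV = C [Bq/mL] * weight [g] / decayed dose [Bq]

with the injected dose decay-corrected from injection to scan start using
the radionuclide half-life (F-18 by default).  Only the body-weight SUV
variant is implemented; lean-body-mass scaling is out of scope.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

#: F-18 half-life in seconds (EANM reference value).
F18_HALF_LIFE_S = 6586.2

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def _parse_time(value) -> _dt.datetime:
    if isinstance(value, _dt.datetime):
        return value
    return _dt.datetime.fromisoformat(str(value))


@dataclasses.dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition bookkeeping needed for SUV normalization.

    Parameters
    ----------
    injected_dose_mbq : float
        Net injected activity in MBq (assay-time activity).
    injection_time, scan_time : datetime or ISO-8601 string
        Injection and scan-start timestamps; scan must not precede injection.
    body_weight_kg : float
        Patient body weight in kg.
    half_life_s : float
        Radionuclide half-life in seconds; defaults to F-18.
    """

    injected_dose_mbq: float
    injection_time: _dt.datetime
    scan_time: _dt.datetime
    body_weight_kg: float
    half_life_s: float = F18_HALF_LIFE_S

    def __post_init__(self):
        object.__setattr__(self, "injection_time", _parse_time(self.injection_time))
        object.__setattr__(self, "scan_time", _parse_time(self.scan_time))
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected_dose_mbq must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be positive")
        if self.scan_time < self.injection_time:
            raise ValueError("scan_time precedes injection_time")

    @property
    def uptake_seconds(self) -> float:
        return (self.scan_time - self.injection_time).total_seconds()

    def to_json_dict(self) -> dict:
        return {
            "injected_dose_mbq": self.injected_dose_mbq,
            "injection_time": self.injection_time.strftime(_TIME_FMT),
            "scan_time": self.scan_time.strftime(_TIME_FMT),
            "body_weight_kg": self.body_weight_kg,
            "half_life_s": self.half_life_s,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AcquisitionMeta":
        required = [
            "injected_dose_mbq",
            "injection_time",
            "scan_time",
            "body_weight_kg",
        ]
        missing = [k for k in required if k not in d or d[k] is None]
        if missing:
            raise ValueError(f"acquisition metadata missing fields: {missing}")
        return cls(
            injected_dose_mbq=float(d["injected_dose_mbq"]),
            injection_time=d["injection_time"],
            scan_time=d["scan_time"],
            body_weight_kg=float(d["body_weight_kg"]),
            half_life_s=float(d.get("half_life_s", F18_HALF_LIFE_S)),
        )


@dataclasses.dataclass
class ActivityVolume:
    """3-D activity-concentration grid in Bq/mL with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("activity concentration must be non-negative")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclasses.dataclass
class SuvVolume:
    """3-D dimensionless body-weight SUV grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: AcquisitionMeta | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def suv_max(self) -> float:
        return float(self.voxels.max())


def decay_corrected_dose(meta: AcquisitionMeta) -> float:
    """Injected dose decayed to scan time, in Bq.

    D = dose[Bq] * 2**(-dt / half_life), dt = scan - injection (seconds).
    """
    dt = meta.uptake_seconds
    if dt < 0:
        raise ValueError("scan_time precedes injection_time")
    dose_bq = meta.injected_dose_mbq * 1e6
    return dose_bq * 2.0 ** (-dt / meta.half_life_s)


def to_suv(vol: ActivityVolume, meta: AcquisitionMeta, *, already_suv: bool = False) -> SuvVolume:
    """Convert an activity volume to body-weight SUV.

    SUV = C[Bq/mL] * weight[g] / decay_corrected_dose[Bq], voxel-wise.
    With ``already_suv=True`` the voxel values are passed through unchanged
    (vendor images that are pre-scaled to SUV).
    """
    if already_suv:
        return SuvVolume(vol.voxels.copy(), vol.spacing, provenance=meta, affine=vol.affine)
    dose = decay_corrected_dose(meta)
    if dose <= 0:
        raise ValueError("decay-corrected dose must be positive")
    weight_g = meta.body_weight_kg * 1000.0
    suv = vol.voxels * (weight_g / dose)
    return SuvVolume(suv, vol.spacing, provenance=meta, affine=vol.affine)


# ---------------------------------------------------------------------------
# IO: NIfTI-1 primary, DICOM PET series optional
# ---------------------------------------------------------------------------

def write_volume(vol: ActivityVolume | SuvVolume, path: str | os.PathLike,
                 meta: AcquisitionMeta | None = None) -> None:
    """Write a volume as NIfTI-1; metadata, if given, as a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    if meta is not None:
        sidecar = path.with_suffix("").with_suffix(".json") if path.name.endswith(".nii.gz") \
            else path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta.to_json_dict(), indent=2))


def _read_nifti(path: Path) -> tuple[ActivityVolume, AcquisitionMeta | None]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = ActivityVolume(data, spacing, affine=np.asarray(img.affine))
    sidecar = path.with_suffix("").with_suffix(".json") if path.name.endswith(".nii.gz") \
        else path.with_suffix(".json")
    meta = None
    if sidecar.exists():
        meta = AcquisitionMeta.from_json_dict(json.loads(sidecar.read_text()))
    return vol, meta


_DICOM_REQUIRED = {
    "PatientWeight": "body weight",
    "PixelSpacing": "in-plane pixel spacing",
    "SliceThickness": "slice thickness",
}


def _read_dicom_series(path: Path) -> tuple[ActivityVolume, AcquisitionMeta]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    first = slices[0]

    missing = [f"{tag} ({desc})" for tag, desc in _DICOM_REQUIRED.items()
               if getattr(first, tag, None) in (None, "")]
    rph = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if not rph:
        missing.append("RadiopharmaceuticalInformationSequence (dose/times)")
        rph_item = None
    else:
        rph_item = rph[0]
        for tag, desc in [("RadionuclideTotalDose", "injected dose"),
                          ("RadiopharmaceuticalStartDateTime", "injection time")]:
            if getattr(rph_item, tag, None) in (None, ""):
                missing.append(f"{tag} ({desc})")
    if getattr(first, "AcquisitionDateTime", None) in (None, "") and \
            getattr(first, "SeriesDate", None) in (None, ""):
        missing.append("AcquisitionDateTime (scan time)")
    if missing:
        raise ValueError("DICOM series missing mandatory metadata: " + "; ".join(missing))

    def _dcm_datetime(val: str) -> _dt.datetime:
        val = str(val).split(".")[0]
        return _dt.datetime.strptime(val, "%Y%m%d%H%M%S")

    arrays = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    data = np.stack(arrays, axis=-1)  # (row, col, slice)

    dy, dx = (float(v) for v in first.PixelSpacing)
    dz = float(first.SliceThickness)
    spacing = (dy, dx, dz)

    injection = _dcm_datetime(rph_item.RadiopharmaceuticalStartDateTime)
    scan_raw = getattr(first, "AcquisitionDateTime", None) or \
        (str(first.SeriesDate) + str(first.SeriesTime))
    scan = _dcm_datetime(scan_raw)
    half_life = float(getattr(rph_item, "RadionuclideHalfLife", F18_HALF_LIFE_S))
    meta = AcquisitionMeta(
        injected_dose_mbq=float(rph_item.RadionuclideTotalDose) / 1e6,
        injection_time=injection,
        scan_time=scan,
        body_weight_kg=float(first.PatientWeight),
        half_life_s=half_life,
    )
    return ActivityVolume(data, spacing), meta


def read_volume(path: str | os.PathLike, format: str = "nifti"):
    """Read a PET volume.

    Parameters
    ----------
    path : path to a ``.nii``/``.nii.gz`` file (``format="nifti"``) or a
        directory of ``.dcm`` slices (``format="dicom-series"``).

    Returns
    -------
    (ActivityVolume, AcquisitionMeta or None)
        NIfTI returns metadata only when a JSON sidecar is present; a DICOM
        series must carry the standard radiopharmaceutical tags and raises a
        ``ValueError`` naming any missing field.
    """
    path = Path(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")
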