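"""NIfTI read/write, DICOM metadata import, ROI handling, and map export.

Images, ROI masks and parametric maps all travel as NIfTI; fit provenance is
written to JSON sidecars next to each map. DICOM is read-only and only for
acquisition metadata — conversion of pixel data to NIfTI is delegated to an
external converter. Voxel indexing is 0-based throughout and spatial
orientation is taken from the NIfTI affine, never reordered.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .types import AcquisitionMeta, MetadataError

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSeries4D",
    "ROIMask",
    "ParametricMap",
    "read_nifti_series",
    "read_roi_mask",
    "write_map",
    "read_map",
    "extract_dicom_meta",
]

#: DICOM b-value tags: public Enhanced-MR tag plus the three common vendor
#: private tags (Siemens, GE, Philips).
_BVALUE_TAGS = [(0x0018, 0x9087), (0x0019, 0x100C), (0x0043, 0x1039), (0x2001, 0x1003)]


@dataclass
class ImageSeries4D:
    """A 3-D spatial grid of signal intensities over one varying dimension
    (time, b-value, flip angle, or echo time)."""

    data: np.ndarray  # (nx, ny, nz, n_frames)
    affine: np.ndarray  # 4x4
    meta: AcquisitionMeta
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite intensities")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def validate_frames(self, kind: str) -> None:
        expected = self.meta.n_frames_for(kind)
        if expected != self.n_frames:
            raise MetadataError(
                f"series has {self.n_frames} frames but metadata lists {expected}"
            )

    def voxel_curves(self, mask: Optional[np.ndarray] = None):
        """Flatten to (n_voxels, n_frames) plus the index array to re-embed."""
        if mask is None:
            mask = np.ones(self.shape3d, dtype=bool)
        idx = np.flatnonzero(mask.ravel())
        X = self.data.reshape(-1, self.n_frames)[idx]
        return X, idx


@dataclass
class ROIMask:
    """Integer label volume aligned to a parent series; label 0 = background."""

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.round(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("ROI mask voxels must be integer labels")
            self.labels = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)

    def check_aligned(self, series: ImageSeries4D, atol: float = 1e-4) -> None:
        """Reject (never resample) masks that do not share the parent grid."""
        if self.labels.shape != series.shape3d:
            raise ValueError(
                f"ROI shape {self.labels.shape} != series shape {series.shape3d}"
            )
        if not np.allclose(self.affine, series.affine, atol=atol):
            raise ValueError("ROI affine does not match series affine")

    def binary(self, label: Optional[int] = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label


@dataclass
class ParametricMap:
    """A fitted 3-D parameter volume plus its provenance."""

    values: np.ndarray
    affine: np.ndarray
    parameter_name: str
    model_name: str
    units: str = ""
    mask_applied: bool = False
    fit_settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)


def read_nifti_series(path, meta: AcquisitionMeta, kind: Optional[str] = None) -> ImageSeries4D:
    """Load a 4-D NIfTI series; frame count must match the metadata.

    Intensities are returned as stored (beyond the NIfTI scl_slope/scl_inter
    scaling that nibabel applies).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata())
    zooms = img.header.get_zooms()[:3]
    series = ImageSeries4D(data=data, affine=img.affine, meta=meta,
                           spacing=tuple(float(z) for z in zooms))
    if kind is not None:
        series.validate_frames(kind)
    return series


def read_roi_mask(path, parent: Optional[ImageSeries4D] = None,
                  label_names: Optional[dict] = None) -> ROIMask:
    img = nib.load(str(path))
    mask = ROIMask(labels=np.asanyarray(img.dataobj), affine=img.affine,
                   label_names=label_names or {})
    if parent is not None:
        mask.check_aligned(parent)
    return mask


def write_map(pmap: ParametricMap, path) -> Path:
    """Write a parametric map as float32 NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(pmap.values.astype(np.float32), pmap.affine)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "parameter_name": pmap.parameter_name,
                "model_name": pmap.model_name,
                "units": pmap.units,
                "mask_applied": pmap.mask_applied,
                "fit_settings": pmap.fit_settings,
            },
            fh, indent=2, default=str,
        )
    return path


def read_map(path) -> ParametricMap:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    info = {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
    return ParametricMap(
        values=img.get_fdata(), affine=img.affine,
        parameter_name=info.get("parameter_name", ""),
        model_name=info.get("model_name", ""),
        units=info.get("units", ""),
        mask_applied=info.get("mask_applied", False),
        fit_settings=info.get("fit_settings", {}),
    )


def _parse_bvalue(ds) -> Optional[float]:
    import pydicom

    for group, elem in _BVALUE_TAGS:
        if (group, elem) in ds:
            value = ds[(group, elem)].value
            if value is None:
                continue
            if isinstance(value, (bytes, str)):
                try:
                    value = float(str(value).strip().split()[0])
                except (ValueError, IndexError):
                    continue
            elif isinstance(value, (list, pydicom.multival.MultiValue)):
                if len(value) == 0:
                    continue
                value = float(value[0])
                # GE packs the b-value into the first element, sometimes
                # offset by 1e9 as a vendor convention
                if value >= 1e9:
                    value -= 1e9
            return float(value)
    return None


def extract_dicom_meta(dicom_dir) -> AcquisitionMeta:
    """Scan a directory of DICOM files and collect acquisition metadata.

    TR/TE are converted from DICOM milliseconds to seconds. b-values are read
    from the public diffusion tag (0018,9087) with fall-back to the Siemens,
    GE and Philips private tags. Frame timing uses TriggerTime when present,
    else per-file AcquisitionTime, referenced to the earliest frame. Missing
    optional fields are left empty with a warning.
    """
    import pydicom

    dicom_dir = Path(dicom_dir)
    files = sorted(p for p in dicom_dir.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p), stop_before_pixels=True))
        except Exception:
            continue
    if not datasets:
        raise IOError(f"no readable DICOM files in {dicom_dir}")

    trs = {float(ds.RepetitionTime) for ds in datasets if "RepetitionTime" in ds}
    if len(trs) > 1:
        raise MetadataError(f"conflicting TR values across slices: {sorted(trs)}")
    tr = trs.pop() / 1000.0 if trs else None

    fas = sorted({float(ds.FlipAngle) for ds in datasets if "FlipAngle" in ds})
    tes = sorted({float(ds.EchoTime) / 1000.0 for ds in datasets if "EchoTime" in ds})

    bvals = sorted({b for b in (_parse_bvalue(ds) for ds in datasets) if b is not None})

    times = []
    for ds in datasets:
        if "TriggerTime" in ds:
            times.append(float(ds.TriggerTime) / 1000.0)
        elif "AcquisitionTime" in ds:
            t = str(ds.AcquisitionTime)
            hh, mm, ss = float(t[:2]), float(t[2:4]), float(t[4:])
            times.append(hh * 3600 + mm * 60 + ss)
    frame_times = None
    if times:
        uniq = np.unique(np.asarray(times))
        if len(uniq) > 1:
            frame_times = list(uniq - uniq[0])

    for name, val in [("TR", tr), ("flip angles", fas), ("echo times", tes),
                      ("b-values", bvals), ("frame times", frame_times)]:
        if not val:
            logger.warning("DICOM metadata: no %s found in %s", name, dicom_dir)

    return AcquisitionMeta(
        tr=tr,
        flip_angles_deg=fas or None,
        echo_times=tes or None,
        b_values=bvals or None,
        frame_times=frame_times,
    )
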