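"""CT volume and artery-mask data model with NIfTI (and optional DICOM) I/O.

Axis convention is ``(slice, row, col)`` with the slice index increasing
along the scan axis.  In-plane physical coordinates are given in mm with
the origin at the volume's in-plane center (x along columns, y along rows).
HU values are stored as floats throughout; nothing is quantized to integer
HU until report output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

__all__ = [
    "Protocol",
    "CTVolume",
    "ArteryMask",
    "ARTERY_LABELS",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "voxel_geometry",
    "GeometryError",
    "FormatError",
]

#: Artery label integers used in :class:`ArteryMask` volumes.
ARTERY_LABELS = {1: "RCA", 2: "LAD", 3: "LCX", 4: "LM"}
ARTERY_NAMES = ("RCA", "LAD", "LCX", "LM")


class Protocol(str, enum.Enum):
    """Acquisition/processing protocol tag carried by a :class:`CTVolume`.

    ``CSCT`` is the ECG-gated calcium-scoring reference protocol, ``LDCT``
    the low-dose (spectrally shaped) chest protocol, ``cLDCT`` an LDCT
    volume after voxel-wise HU calibration onto the CSCT scale, and
    ``TRUTH`` a noiseless simulator ground-truth volume.
    """

    CSCT = "CSCT"
    LDCT = "LDCT"
    CLDCT = "cLDCT"
    TRUTH = "TRUTH"


class GeometryError(ValueError):
    """Raised when voxel geometry is missing, invalid, or inconsistent."""


class FormatError(ValueError):
    """Raised when an on-disk image is not a readable 3-D CT volume."""


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units plus its voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, floating point.
    pixel_spacing : tuple of float
        In-plane (row_mm, col_mm) spacing.
    slice_thickness : float
        Slice thickness in mm.
    protocol : Protocol
        Acquisition protocol tag.
    meta : dict
        Free-form metadata (patient id, heart rate, curve provenance, ...).
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    protocol: Protocol = Protocol.LDCT
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"CTVolume requires a 3-D array, got ndim={self.voxels.ndim}"
            )
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.slice_thickness = float(self.slice_thickness)
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise GeometryError(
                f"non-positive geometry: spacing={self.pixel_spacing}, "
                f"thickness={self.slice_thickness}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume voxels contain NaN/Inf")
        self.protocol = Protocol(self.protocol)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy_with(self, voxels: np.ndarray | None = None,
                  protocol: Protocol | None = None,
                  extra_meta: dict[str, Any] | None = None) -> "CTVolume":
        """Return a new volume sharing this one's geometry."""
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return CTVolume(
            voxels=self.voxels.copy() if voxels is None else voxels,
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            protocol=self.protocol if protocol is None else protocol,
            meta=meta,
        )

    def inplane_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y_mm, x_mm) coordinate grids of voxel centers.

        Origin at the in-plane center; y along rows, x along columns.
        """
        _, n_rows, n_cols = self.shape
        row_mm, col_mm = self.pixel_spacing
        y = (np.arange(n_rows) - (n_rows - 1) / 2.0) * row_mm
        x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * col_mm
        return np.meshgrid(y, x, indexing="ij")


@dataclass
class ArteryMask:
    """Integer label volume pairing a CTVolume with coronary-artery regions.

    Labels: 0 background, 1 RCA, 2 LAD, 3 LCX, 4 LM.
    """

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(ARTERY_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("ArteryMask requires a 3-D label array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("mask labels must be integers")
            self.labels = rounded.astype(np.int16)
        bad = set(np.unique(self.labels)) - ({0} | set(self.label_map))
        if bad:
            raise ValueError(f"unexpected mask labels: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def check_congruent(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise GeometryError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )


def voxel_geometry(v: CTVolume) -> tuple[float, float]:
    """Return ``(pixel_area_mm2, voxel_volume_mm3)`` for a volume.

    pixel_area = row_mm * col_mm; voxel_volume = pixel_area * slice_thickness.
    """
    pixel_area = v.pixel_spacing[0] * v.pixel_spacing[1]
    return pixel_area, pixel_area * v.slice_thickness


# ---------------------------------------------------------------------------
# NIfTI I/O.  On disk the array keeps the in-memory (slice, row, col) order;
# the affine encodes (slice_thickness, row_mm, col_mm) voxel sizes so the
# header zooms round-trip the geometry exactly.
# ---------------------------------------------------------------------------

def _affine(pixel_spacing: tuple[float, float], slice_thickness: float) -> np.ndarray:
    return np.diag([slice_thickness, pixel_spacing[0], pixel_spacing[1], 1.0])


def save_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CTVolume to NIfTI (float32), recording the protocol tag."""
    path = Path(path)
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32),
        _affine(volume.pixel_spacing, volume.slice_thickness),
    )
    img.header["descrip"] = f"protocol={volume.protocol.value}".encode()
    nib.save(img, str(path))
    return path


def load_volume(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    protocol: Protocol | str | None = None,
) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        A ``.nii``/``.nii.gz`` file, or a directory containing one DICOM
        series (rescale slope/intercept applied).
    spacing_override : (slice_thickness, row_mm, col_mm), optional
        Geometry used in place of (or in absence of) header spacing.
    protocol : Protocol or str, optional
        Protocol tag to attach.  If omitted, a tag recorded by
        :func:`save_volume` in the NIfTI header is used; otherwise LDCT.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _load_dicom_series(path, spacing_override, protocol)

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D image, got shape {data.shape}")

    if spacing_override is not None:
        thickness, row_mm, col_mm = spacing_override
    else:
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise GeometryError(
                f"non-positive header spacing {zooms}; pass spacing_override"
            )
        thickness, row_mm, col_mm = (float(z) for z in zooms)

    if protocol is None:
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
        protocol = descrip.split("protocol=", 1)[1] if "protocol=" in descrip else Protocol.LDCT

    return CTVolume(
        voxels=data.astype(float),
        pixel_spacing=(row_mm, col_mm),
        slice_thickness=thickness,
        protocol=Protocol(protocol),
        meta={"source": str(path)},
    )


def _load_dicom_series(
    directory: Path,
    spacing_override: tuple[float, float, float] | None,
    protocol: Protocol | str | None,
) -> CTVolume:
    """Read a single-series DICOM directory (input-only convenience)."""
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM images found in {directory}")

    def _z(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=_z)
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    data = np.stack(arrays, axis=0)

    if spacing_override is not None:
        thickness, row_mm, col_mm = spacing_override
    else:
        ds0 = slices[0]
        if not hasattr(ds0, "PixelSpacing"):
            raise GeometryError("DICOM series lacks PixelSpacing; pass spacing_override")
        row_mm, col_mm = (float(v) for v in ds0.PixelSpacing)
        if len(slices) > 1:
            thickness = abs(_z(slices[1]) - _z(slices[0]))
        else:
            thickness = float(getattr(ds0, "SliceThickness", 0.0))
        if thickness <= 0:
            raise GeometryError("cannot determine slice thickness; pass spacing_override")

    return CTVolume(
        voxels=data,
        pixel_spacing=(row_mm, col_mm),
        slice_thickness=thickness,
        protocol=Protocol(protocol) if protocol is not None else Protocol.LDCT,
        meta={"source": str(directory)},
    )


def save_mask(mask: ArteryMask, path: str | Path,
              pixel_spacing: tuple[float, float] = (1.0, 1.0),
              slice_thickness: float = 1.0) -> Path:
    """Write an ArteryMask to NIfTI as int16 labels."""
    path = Path(path)
    img = nib.Nifti1Image(
        mask.labels.astype(np.int16), _affine(pixel_spacing, slice_thickness)
    )
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> ArteryMask:
    """Load an artery label mask from a NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D label image, got shape {data.shape}")
    return ArteryMask(labels=np.rint(data).astype(np.int16))
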