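"""Reading CT series and radiotherapy structure sets (RTSTRUCT) into the domain model.

A patient in a Lung1-style archive is a directory of axial CT slices (one DICOM
file each) plus one RTSTRUCT file whose ROIs ("GTV-1", "Lung-Left", ...) hold
per-slice contour polygons in patient-coordinate millimetres.  Contours point
back at CT slices through the referenced SOP Instance UID; intersecting those
UIDs with the series' own UIDs yields the set of tumour-bearing slices.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError


class DicomReadError(ValueError):
    """A DICOM file could not be used; carries the offending tag and file."""

    def __init__(self, message: str, *, tag: str | None = None, path: str | None = None):
        self.tag = tag
        self.path = path
        super().__init__(message)


class MissingROIError(KeyError):
    """A required ROI (typically "GTV-1") is absent from the structure set."""


@dataclass(frozen=True)
class SliceMeta:
    """Geometry and pixel payload of a single axial CT slice."""

    sop_instance_uid: str
    z_position: float
    rescale_slope: float
    rescale_intercept: float
    slice_thickness: float
    pixel_spacing: tuple[float, float]  # (row, col) mm/px
    image_position: tuple[float, float, float]  # (x0, y0, z0) mm
    pixel_array: np.ndarray  # raw stored values; HU = slope*raw + intercept

    def __post_init__(self) -> None:
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if self.slice_thickness <= 0:
            raise ValueError(f"slice_thickness must be positive, got {self.slice_thickness}")
        if self.pixel_array.ndim != 2:
            raise ValueError("pixel_array must be a 2-D matrix")

    def hounsfield(self) -> np.ndarray:
        """Stored values converted to Hounsfield units."""
        return self.rescale_slope * self.pixel_array.astype(np.float64) + self.rescale_intercept


@dataclass
class CTSeries:
    patient_id: str
    slices: list[SliceMeta]

    def __post_init__(self) -> None:
        zs = [s.z_position for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slices must be strictly sorted by z_position")

    @property
    def uids(self) -> list[str]:
        return [s.sop_instance_uid for s in self.slices]

    def slice_by_uid(self, uid: str) -> SliceMeta:
        for s in self.slices:
            if s.sop_instance_uid == uid:
                return s
        raise KeyError(uid)


@dataclass(frozen=True)
class Contour:
    """One closed planar contour in patient millimetres."""

    referenced_sop_uid: str
    points_mm: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=np.float64)
        object.__setattr__(self, "points_mm", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points_mm must be (n, 3)")

    @property
    def z_mm(self) -> float:
        return float(self.points_mm[0, 2])


@dataclass
class StructureSet:
    patient_id: str
    rois: dict[str, list[Contour]] = field(default_factory=dict)


_CT_REQUIRED = {
    "SOPInstanceUID": "SOP Instance UID",
    "ImagePositionPatient": "Image Position (Patient)",
    "PixelSpacing": "Pixel Spacing",
    "SliceThickness": "Slice Thickness",
}


def read_ct_series(directory: str | Path, patient_id: str | None = None) -> CTSeries:
    """Read every CT DICOM file in *directory* into a z-sorted :class:`CTSeries`.

    Non-DICOM files are skipped with a warning.  Rescale slope/intercept are
    stored but not applied; ties in z are broken by SOP UID so ordering is
    deterministic.
    """
    directory = Path(directory)
    slices: list[SliceMeta] = []
    seen: set[str] = set()
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            warnings.warn(f"skipping non-DICOM file {path.name}", stacklevel=2)
            continue
        if getattr(ds, "Modality", "CT") == "RTSTRUCT":
            continue
        for attr, tag_name in _CT_REQUIRED.items():
            if attr not in ds:
                raise DicomReadError(
                    f"missing required tag {tag_name!r} in {path.name}",
                    tag=tag_name, path=str(path),
                )
        if "PixelData" not in ds:
            raise DicomReadError(
                f"missing required tag 'Pixel Data' in {path.name}",
                tag="Pixel Data", path=str(path),
            )
        uid = str(ds.SOPInstanceUID)
        if uid in seen:
            raise DicomReadError(f"duplicate SOP Instance UID {uid} at {path.name}",
                                 tag="SOP Instance UID", path=str(path))
        seen.add(uid)
        pos = tuple(float(v) for v in ds.ImagePositionPatient)
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        slices.append(SliceMeta(
            sop_instance_uid=uid,
            z_position=pos[2],
            rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
            rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
            slice_thickness=float(ds.SliceThickness),
            pixel_spacing=(spacing[0], spacing[1]),
            image_position=pos,  # type: ignore[arg-type]
            pixel_array=ds.pixel_array,
        ))
    if not slices:
        raise DicomReadError(f"no CT DICOM files found in {directory}", path=str(directory))
    slices.sort(key=lambda s: (s.z_position, s.sop_instance_uid))
    pid = patient_id or directory.name
    return CTSeries(patient_id=pid, slices=slices)


def read_structure_set(rtstruct_file: str | Path, patient_id: str | None = None) -> StructureSet:
    """Parse an RTSTRUCT DICOM into named ROIs with their mm contours.

    ROIs declared in StructureSetROISequence but carrying no contours appear
    with an empty list (with a warning) so the inventory is complete.  Each
    contour's slice reference is the ReferencedSOPInstanceUID of the first
    ContourImageSequence item; contours without one get an empty reference and
    are matched to slices by z later.
    """
    path = Path(rtstruct_file)
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise DicomReadError(f"{path.name} is not an RTSTRUCT file", path=str(path))

    names: dict[int, str] = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName).strip()

    rois: dict[str, list[Contour]] = {name: [] for name in names.values()}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number)
        if name is None:
            warnings.warn(f"contour for undeclared ROI number {number}; skipped", stacklevel=2)
            continue
        for cs in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray([float(v) for v in cs.ContourData], dtype=np.float64)
            pts = data.reshape(-1, 3)
            ref = ""
            cis = getattr(cs, "ContourImageSequence", None)
            if cis:
                ref = str(cis[0].ReferencedSOPInstanceUID)
            rois[name].append(Contour(referenced_sop_uid=ref, points_mm=pts))
    for name, contours in rois.items():
        if not contours:
            warnings.warn(f"ROI {name!r} declared but has no contours", stacklevel=2)
    pid = patient_id or str(getattr(ds, "PatientID", path.stem))
    return StructureSet(patient_id=pid, rois=rois)


def resolve_roi(ss: StructureSet, name: str = "GTV-1", *, regex: str | None = None) -> list[Contour]:
    """Look up an ROI by exact (whitespace-stripped) name, or by regex.

    Real structure sets drift in naming ("GTV-1" vs "GTV 1"); the regex escape
    hatch handles that without loosening the default exact match.
    """
    if regex is not None:
        pat = re.compile(regex)
        hits = [n for n in ss.rois if pat.fullmatch(n)]
        if len(hits) > 1:
            raise MissingROIError(f"regex {regex!r} matches multiple ROIs: {hits}")
        if hits:
            return ss.rois[hits[0]]
        raise MissingROIError(f"no ROI matching {regex!r} in patient {ss.patient_id}")
    key = name.strip()
    if key not in ss.rois:
        raise MissingROIError(f"ROI {name!r} absent from patient {ss.patient_id}")
    return ss.rois[key]


def _match_contour_uids(series: CTSeries, contours: Iterable[Contour]) -> list[str]:
    """Resolve each contour to a series slice UID, falling back to nearest z."""
    series_uids = set(series.uids)
    half_dz = series.slices[0].slice_thickness / 2.0
    out: list[str] = []
    for c in contours:
        if c.referenced_sop_uid and c.referenced_sop_uid in series_uids:
            out.append(c.referenced_sop_uid)
            continue
        if c.referenced_sop_uid:
            warnings.warn(
                f"contour references UID {c.referenced_sop_uid} not in series; dropped",
                stacklevel=3,
            )
            continue
        # geometry-only contour: nearest slice within half a slice thickness
        dz = [abs(s.z_position - c.z_mm) for s in series.slices]
        i = int(np.argmin(dz))
        if dz[i] <= half_dz:
            warnings.warn("contour matched to slice by z fallback", stacklevel=3)
            out.append(series.slices[i].sop_instance_uid)
        else:
            warnings.warn("contour has no slice within half a slice thickness; dropped",
                          stacklevel=3)
    return out


def gtv1_slice_uids(series: CTSeries, ss: StructureSet, *,
                    roi_name: str = "GTV-1", roi_regex: str | None = None) -> list[str]:
    """UIDs of series slices carrying at least one GTV-1 contour, in z order.

    The intersection of the series' SOP UIDs with the UIDs referenced by the
    GTV-1 contours, deduplicated (two contours on one slice count once).
    Raises :class:`MissingROIError` if the ROI is absent — such patients are
    excluded from the cohort.
    """
    contours = resolve_roi(ss, roi_name, regex=roi_regex)
    matched = _match_contour_uids(series, contours)
    order = {uid: i for i, uid in enumerate(series.uids)}
    return sorted(set(matched), key=order.__getitem__)


def structure_inventory(ss: StructureSet) -> pd.DataFrame:
    """Per-ROI contour counts as a table (roi_name, contour_count)."""
    rows = [(name, len(contours)) for name, contours in ss.rois.items()]
    return pd.DataFrame(rows, columns=["roi_name", "contour_count"])


def write_inventory_tsv(inventories: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Concatenate per-patient inventories into one TSV."""
    frames = []
    for pid, inv in inventories.items():
        df = inv.copy()
        df.insert(0, "patient_id", pid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
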