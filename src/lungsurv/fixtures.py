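"""Self-contained synthetic patients mirroring a Lung1-style archive.

Each synthetic patient is an axial CT series (DICOM Part-10 files) plus an
RTSTRUCT whose ROIs are 32-vertex polygon contours of simple anatomy: an
ellipsoidal primary tumour (GTV-1), two lung ellipses, a spinal-cord circle
and optionally a small GTV-2.  A clinical CSV (Lung1 column names) and a
ground-truth manifest accompany the cohort, so every pipeline stage can be
verified offline against known geometry, injected segmentation errors and a
known survival-generating process.

Everything derives from one integer seed and fixed UID roots, so a cohort is
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .dicom_io import Contour, CTSeries, SliceMeta, StructureSet

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_UID_ROOT = "1.2.826.0.1.3680043.10.424"
_IMPL_UID = _UID_ROOT + ".0.1"

DEFAULT_ROIS = ("GTV-1", "Lung-Left", "Lung-Right", "Spinal-Cord")


@dataclass
class TumorModel:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]  # (a=x, b=y, c=z)
    n_vertices: int = 32


@dataclass
class FixtureSpec:
    """Generation parameters for a synthetic cohort."""

    n_patients: int = 5
    slices_range: tuple[int, int] = (18, 30)  # desk-scale stand-in for 75–297
    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: float = 0.977  # mm/px, the Lung1 in-plane spacing
    slice_thickness: float = 3.0  # mm, the Lung1 slice thickness
    tumor_semi_axes_xy: tuple[float, float] = (8.0, 22.0)  # mm range for a, b
    tumor_semi_axis_z: tuple[float, float] = (4.0, 28.0)  # mm range for c
    rois: tuple[str, ...] = DEFAULT_ROIS
    n_vertices: int = 32
    inject_area_jump_rate: float = 0.0
    inject_multi_tumor_rate: float = 0.0
    inject_mislabel_rate: float = 0.0
    # survival process: log-scale linear in GTV-1 slice count (Weibull)
    survival_scale_days: float = 1400.0
    survival_shape: float = 1.3
    slice_count_coef: float = -0.09  # per extra GTV-1 slice, on the log scale
    censoring_rate: float = 0.114  # the Lung1 censored fraction
    seed: int = 0


@dataclass
class PatientFixture:
    """In-memory synthetic patient: geometry, pixels, contours, truth."""

    patient_id: str
    rows: int
    cols: int
    pixel_spacing: float
    slice_thickness: float
    origin: tuple[float, float, float]  # (x0, y0, z of first slice)
    slice_uids: list[str]
    z_positions: list[float]
    pixel_arrays: np.ndarray  # (n_slices, rows, cols) int16 stored values
    rois: dict[str, list[tuple[int, np.ndarray]]]  # name -> [(slice_idx, (n,3) mm)]
    tumor: TumorModel
    injected: list[dict] = field(default_factory=list)
    geometry_only: bool = False  # drop ContourImageSequence when writing

    @property
    def n_slices(self) -> int:
        return len(self.slice_uids)

    def gtv1_slice_indices(self) -> list[int]:
        return sorted({idx for idx, _ in self.rois.get("GTV-1", [])})


@dataclass
class Manifest:
    """Ground truth for a generated cohort, keyed by patient id."""

    patients: dict[str, dict] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.patients, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        return cls(patients=json.loads(Path(path).read_text()))


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float, z: float,
                     n_vertices: int, phase: float = 0.0) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False) + phase
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t),
                            np.full(n_vertices, z)])


def ellipsoid_slice_radii(tumor: TumorModel, z: float) -> tuple[float, float] | None:
    """In-plane semi-axes of the ellipsoid's cross-section at height z."""
    cx, cy, cz = tumor.center_mm
    a, b, c = tumor.semi_axes_mm
    u = 1.0 - ((z - cz) / c) ** 2
    if u <= 0:
        return None
    return a * np.sqrt(u), b * np.sqrt(u)


def expected_gtv1_slices(tumor: TumorModel, z_positions: list[float]) -> list[int]:
    return [i for i, z in enumerate(z_positions)
            if ellipsoid_slice_radii(tumor, z) is not None]


def _slice_uid(seed: int, patient_index: int, slice_index: int) -> str:
    return f"{_UID_ROOT}.{seed}.{patient_index + 1}.{slice_index + 1}"


def make_patient(spec: FixtureSpec, patient_index: int,
                 rng: np.random.Generator) -> PatientFixture:
    """Synthesize one patient: geometry, contours, and CT pixel content."""
    rows, cols = spec.image_size
    sp = spec.pixel_spacing
    n_slices = int(rng.integers(spec.slices_range[0], spec.slices_range[1] + 1))
    x0, y0 = -cols / 2 * sp, -rows / 2 * sp
    z0 = -450.0
    zs = [z0 + i * spec.slice_thickness for i in range(n_slices)]
    width_mm, height_mm = cols * sp, rows * sp

    # lungs as two tall ellipses left/right of midline, spinal cord posterior
    lung_rx, lung_ry = width_mm * 0.18, height_mm * 0.28
    lung_cy = y0 + height_mm * 0.45
    left_cx = x0 + width_mm * 0.28
    right_cx = x0 + width_mm * 0.72
    cord_cx, cord_cy = x0 + width_mm * 0.5, y0 + height_mm * 0.78

    side = rng.choice(["left", "right"])
    tumor_cx = left_cx if side == "left" else right_cx
    tumor_cx += rng.uniform(-4.0, 4.0)
    tumor_cy = lung_cy + rng.uniform(-8.0, 8.0)
    a = rng.uniform(*spec.tumor_semi_axes_xy)
    b = rng.uniform(*spec.tumor_semi_axes_xy)
    c = rng.uniform(*spec.tumor_semi_axis_z)
    # keep the tumour's z extent inside the series with a one-slice margin
    lo = zs[1] + c
    hi = zs[-2] - c
    cz = rng.uniform(lo, hi) if lo < hi else 0.5 * (zs[0] + zs[-1])
    tumor = TumorModel(center_mm=(tumor_cx, tumor_cy, cz),
                       semi_axes_mm=(a, b, c), n_vertices=spec.n_vertices)

    rois: dict[str, list[tuple[int, np.ndarray]]] = {name: [] for name in spec.rois}
    for i, z in enumerate(zs):
        if "Lung-Left" in rois:
            rois["Lung-Left"].append(
                (i, _ellipse_polygon(left_cx, lung_cy, lung_rx, lung_ry, z, spec.n_vertices)))
        if "Lung-Right" in rois:
            rois["Lung-Right"].append(
                (i, _ellipse_polygon(right_cx, lung_cy, lung_rx, lung_ry, z, spec.n_vertices)))
        if "Spinal-Cord" in rois:
            rois["Spinal-Cord"].append(
                (i, _ellipse_polygon(cord_cx, cord_cy, 6.0, 6.0, z, spec.n_vertices)))
        radii = ellipsoid_slice_radii(tumor, z)
        if radii is not None and "GTV-1" in rois:
            rois["GTV-1"].append(
                (i, _ellipse_polygon(tumor_cx, tumor_cy, radii[0], radii[1], z,
                                     spec.n_vertices)))

    pixel_arrays = _render_ct(spec, zs, tumor,
                              lungs=((left_cx, lung_cy), (right_cx, lung_cy),
                                     (lung_rx, lung_ry)),
                              origin=(x0, y0), rng=rng)

    pid = f"SYN1-{patient_index + 1:03d}"
    return PatientFixture(
        patient_id=pid, rows=rows, cols=cols, pixel_spacing=sp,
        slice_thickness=spec.slice_thickness, origin=(x0, y0, z0),
        slice_uids=[_slice_uid(spec.seed, patient_index, i) for i in range(n_slices)],
        z_positions=zs, pixel_arrays=pixel_arrays, rois=rois, tumor=tumor)


def _render_ct(spec: FixtureSpec, zs, tumor: TumorModel, lungs, origin,
               rng: np.random.Generator) -> np.ndarray:
    """Coarse CT-like intensities: body, darker lungs, brighter tumour."""
    rows, cols = spec.image_size
    sp = spec.pixel_spacing
    x0, y0 = origin
    xx = x0 + np.arange(cols) * sp
    yy = y0 + np.arange(rows) * sp
    gx, gy = np.meshgrid(xx, yy)
    (lcx, lcy), (rcx, rcy), (lrx, lry) = lungs
    body_cx, body_cy = x0 + cols * sp / 2, y0 + rows * sp / 2
    body = ((gx - body_cx) / (cols * sp * 0.45)) ** 2 \
        + ((gy - body_cy) / (rows * sp * 0.45)) ** 2 <= 1
    lung_l = ((gx - lcx) / lrx) ** 2 + ((gy - lcy) / lry) ** 2 <= 1
    lung_r = ((gx - rcx) / lrx) ** 2 + ((gy - rcy) / lry) ** 2 <= 1

    out = np.empty((len(zs), rows, cols), dtype=np.int16)
    cx, cy, cz = tumor.center_mm
    a, b, _ = tumor.semi_axes_mm
    for i, z in enumerate(zs):
        hu = np.full((rows, cols), -1000.0)
        hu[body] = 40.0
        hu[lung_l | lung_r] = -820.0
        radii = ellipsoid_slice_radii(tumor, z)
        if radii is not None:
            inside = ((gx - cx) / radii[0]) ** 2 + ((gy - cy) / radii[1]) ** 2 <= 1
            hu[inside] = 60.0
        hu += rng.normal(0.0, 12.0, size=hu.shape)
        out[i] = np.clip(np.round(hu) + 1024, 0, 4095).astype(np.int16)  # stored = HU + 1024
    return out


# ------------------------------------------------------------ error injection

def inject_area_jump(patient: PatientFixture, slice_index: int,
                     shrink_factor: float) -> PatientFixture:
    """Shrink one interior GTV-1 contour about its centroid (Fig.-style
    interpolation artifact).  The original contour is kept in ``injected``."""
    gtv_indices = patient.gtv1_slice_indices()
    if slice_index in (gtv_indices[0], gtv_indices[-1]):
        raise ValueError("area-jump injection requires an interior tumour slice")
    if slice_index not in gtv_indices:
        raise ValueError(f"slice {slice_index} carries no GTV-1 contour")
    entries = patient.rois["GTV-1"]
    for j, (idx, pts) in enumerate(entries):
        if idx == slice_index:
            centroid = pts[:, :2].mean(axis=0)
            shrunk = pts.copy()
            shrunk[:, :2] = centroid + (pts[:, :2] - centroid) * shrink_factor
            if shrink_factor != 1.0:
                entries[j] = (idx, shrunk)
                patient.injected.append({
                    "type": "area_jump", "slice_index": slice_index,
                    "shrink_factor": shrink_factor,
                    "original_points_mm": pts.tolist(),
                })
            return patient
    raise AssertionError("unreachable")


def inject_multi_tumor(patient: PatientFixture, slice_index: int,
                       scale: float = 0.6) -> PatientFixture:
    """Add a second, mirrored tumour contour on one slice (bilateral error)."""
    entries = patient.rois["GTV-1"]
    for idx, pts in list(entries):
        if idx == slice_index:
            mirrored = pts.copy()
            mid_x = patient.origin[0] + patient.cols * patient.pixel_spacing / 2
            centroid = pts[:, :2].mean(axis=0)
            target_x = 2 * mid_x - centroid[0]
            mirrored[:, 0] = target_x + (pts[:, 0] - centroid[0]) * scale
            mirrored[:, 1] = centroid[1] + (pts[:, 1] - centroid[1]) * scale
            entries.append((idx, mirrored))
            patient.injected.append({"type": "multi_tumor", "slice_index": slice_index,
                                     "scale": scale})
            return patient
    raise ValueError(f"slice {slice_index} carries no GTV-1 contour")


def inject_mislabel(patient: PatientFixture, slice_index: int) -> PatientFixture:
    """Move one GTV-1 contour outside the lungs (unverifiable mislabel)."""
    entries = patient.rois["GTV-1"]
    for j, (idx, pts) in enumerate(entries):
        if idx == slice_index:
            moved = pts.copy()
            # park it at the posterior body wall, clear of both lungs
            moved[:, 0] += patient.origin[0] + patient.cols * patient.pixel_spacing * 0.5 \
                - pts[:, 0].mean()
            moved[:, 1] += patient.origin[1] + patient.rows * patient.pixel_spacing * 0.9 \
                - pts[:, 1].mean()
            entries[j] = (idx, moved)
            patient.injected.append({"type": "mislabel", "slice_index": slice_index,
                                     "original_points_mm": pts.tolist()})
            return patient
    raise ValueError(f"slice {slice_index} carries no GTV-1 contour")


# ------------------------------------------------------------- survival model

def survival_generator(tumor_extent: int, spec: FixtureSpec,
                       rng: np.random.Generator) -> tuple[float, int]:
    """Draw (survival_time days, deadstatus) for a GTV-1 slice count.

    Survival is Weibull with its log-scale linear in the slice count
    (negative coefficient: taller tumours die sooner).  A Bernoulli
    ``censoring_rate`` fraction of patients is censored at a uniform fraction
    of the true survival time.
    """
    log_scale = np.log(spec.survival_scale_days) + spec.slice_count_coef * tumor_extent
    u = rng.uniform()
    t = np.exp(log_scale) * (-np.log(u)) ** (1.0 / spec.survival_shape)
    if rng.uniform() < spec.censoring_rate:
        follow_up = t * rng.uniform(0.1, 1.0)
        return max(1.0, float(np.round(follow_up))), 0
    return max(1.0, float(np.round(t))), 1


_STAGES = ["I", "II", "IIIa", "IIIb"]
_HISTOLOGIES = ["adenocarcinoma", "squamous cell carcinoma",
                "large cell", "nos"]


def clinical_row(patient: PatientFixture, spec: FixtureSpec,
                 rng: np.random.Generator) -> dict:
    n_gtv = len(patient.gtv1_slice_indices())
    t, dead = survival_generator(n_gtv, spec, rng)
    return {
        "PatientID": patient.patient_id,
        "age": float(np.round(rng.uniform(45, 90) * 365.25)),  # in days, per schema
        "clinical.T.Stage": int(rng.integers(1, 5)),
        "Clinical.N.Stage": int(rng.integers(0, 4)),
        "Clinical.M.Stage": int(rng.integers(0, 2)),
        "Overall.Stage": _STAGES[int(rng.integers(0, len(_STAGES)))],
        "Histology": _HISTOLOGIES[int(rng.integers(0, len(_HISTOLOGIES)))],
        "gender": "male" if rng.uniform() < 0.7 else "female",
        "Survival.time": t,
        "deadstatus.event": dead,
    }


# ----------------------------------------------------- in-memory conversions

def to_ct_series(patient: PatientFixture) -> CTSeries:
    slices = []
    for i, (uid, z) in enumerate(zip(patient.slice_uids, patient.z_positions)):
        slices.append(SliceMeta(
            sop_instance_uid=uid, z_position=z,
            rescale_slope=1.0, rescale_intercept=-1024.0,
            slice_thickness=patient.slice_thickness,
            pixel_spacing=(patient.pixel_spacing, patient.pixel_spacing),
            image_position=(patient.origin[0], patient.origin[1], z),
            pixel_array=patient.pixel_arrays[i]))
    return CTSeries(patient_id=patient.patient_id, slices=slices)


def to_structure_set(patient: PatientFixture) -> StructureSet:
    rois: dict[str, list[Contour]] = {}
    for name, entries in patient.rois.items():
        contours = []
        for idx, pts in entries:
            ref = "" if patient.geometry_only else patient.slice_uids[idx]
            contours.append(Contour(referenced_sop_uid=ref, points_mm=pts))
        rois[name] = contours
    return StructureSet(patient_id=patient.patient_id, rois=rois)


# -------------------------------------------------------------- DICOM writing

def _base_dataset(sop_class: str, sop_uid: str, filename: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _IMPL_UID
    ds = FileDataset(filename, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    return ds


def write_ct_slice(patient: PatientFixture, slice_index: int, path: Path) -> None:
    uid = patient.slice_uids[slice_index]
    ds = _base_dataset(CT_SOP_CLASS, uid, path.name)
    ds.Modality = "CT"
    ds.PatientID = patient.patient_id
    ds.StudyInstanceUID = f"{uid.rsplit('.', 1)[0]}.900"
    ds.SeriesInstanceUID = f"{uid.rsplit('.', 1)[0]}.901"
    ds.InstanceNumber = slice_index + 1
    ds.ImagePositionPatient = [f"{patient.origin[0]:.4f}", f"{patient.origin[1]:.4f}",
                               f"{patient.z_positions[slice_index]:.4f}"]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.PixelSpacing = [f"{patient.pixel_spacing:.4f}", f"{patient.pixel_spacing:.4f}"]
    ds.SliceThickness = f"{patient.slice_thickness:.4f}"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    ds.Rows = patient.rows
    ds.Columns = patient.cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.PixelData = patient.pixel_arrays[slice_index].astype("<i2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_rtstruct(patient: PatientFixture, path: Path) -> None:
    uid = patient.slice_uids[0].rsplit(".", 1)[0] + ".999"
    ds = _base_dataset(RTSTRUCT_SOP_CLASS, uid, path.name)
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient.patient_id
    ds.StructureSetLabel = "synthetic"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, entries) in enumerate(patient.rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for idx, pts in entries:
            cs = Dataset()
            cs.ContourGeometricType = "CLOSED_PLANAR"
            cs.NumberOfContourPoints = len(pts)
            cs.ContourData = [f"{v:.4f}" for v in pts.ravel()]
            if not patient.geometry_only:
                img = Dataset()
                img.ReferencedSOPClassUID = CT_SOP_CLASS
                img.ReferencedSOPInstanceUID = patient.slice_uids[idx]
                cs.ContourImageSequence = [img]
            rc.ContourSequence.append(cs)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def write_patient(patient: PatientFixture, root: Path) -> Path:
    """Write one patient folder: CT/<slices>.dcm plus RTSTRUCT/rtstruct.dcm."""
    pdir = root / patient.patient_id
    ct_dir = pdir / "CT"
    rt_dir = pdir / "RTSTRUCT"
    ct_dir.mkdir(parents=True, exist_ok=True)
    rt_dir.mkdir(parents=True, exist_ok=True)
    for i in range(patient.n_slices):
        write_ct_slice(patient, i, ct_dir / f"slice_{i + 1:03d}.dcm")
    write_rtstruct(patient, rt_dir / "rtstruct.dcm")
    return pdir


# -------------------------------------------------------------- whole cohorts

def make_patients(spec: FixtureSpec) -> tuple[list[PatientFixture], Manifest]:
    """Generate a cohort in memory with ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    patients = []
    manifest = Manifest()
    for i in range(spec.n_patients):
        fx = make_patient(spec, i, rng)
        gtv = fx.gtv1_slice_indices()
        if spec.inject_area_jump_rate and rng.uniform() < spec.inject_area_jump_rate \
                and len(gtv) >= 3:
            interior = gtv[1:-1]
            target = int(interior[rng.integers(0, len(interior))])
            inject_area_jump(fx, target, shrink_factor=0.2)
        if spec.inject_multi_tumor_rate and rng.uniform() < spec.inject_multi_tumor_rate \
                and gtv:
            target = int(gtv[rng.integers(0, len(gtv))])
            inject_multi_tumor(fx, target)
        if spec.inject_mislabel_rate and rng.uniform() < spec.inject_mislabel_rate and gtv:
            target = int(gtv[rng.integers(0, len(gtv))])
            inject_mislabel(fx, target)
        row = clinical_row(fx, spec, rng)
        manifest.patients[fx.patient_id] = {
            "n_slices": fx.n_slices,
            "gtv1_slice_count": len(fx.gtv1_slice_indices()),
            "gtv1_slice_indices": fx.gtv1_slice_indices(),
            "tumor": {"center_mm": list(fx.tumor.center_mm),
                      "semi_axes_mm": list(fx.tumor.semi_axes_mm)},
            "gtv1_area_mm2": {
                str(i): float(np.pi * r[0] * r[1])
                for i in fx.gtv1_slice_indices()
                if (r := ellipsoid_slice_radii(fx.tumor, fx.z_positions[i])) is not None
            },
            "injected": fx.injected,
            "clinical": row,
        }
        patients.append(fx)
    return patients, manifest


def make_cohort(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Manifest]:
    """Materialize a cohort on disk: patient folders, clinical CSV, manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients, manifest = make_patients(spec)
    rows = []
    for fx in patients:
        write_patient(fx, out_dir)
        rows.append(manifest.patients[fx.patient_id]["clinical"])
    pd.DataFrame(rows).to_csv(out_dir / "clinical.csv", index=False)
    manifest.save(out_dir / "manifest.json")
    return out_dir, manifest


def synthetic_records(n: int, spec: FixtureSpec | None = None, seed: int = 0,
                      slice_count_range: tuple[int, int] = (2, 20)) -> list:
    """Clinical records straight from the survival process (no DICOM needed).

    GTV-1 slice counts are drawn uniformly from ``slice_count_range`` and
    survival follows the cohort's Weibull model, so the association between
    GTV1-SliceNum and the 2-year label is present by construction (or absent,
    with ``spec.slice_count_coef = 0``).
    """
    from .clinical import PatientRecord

    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        count = int(rng.integers(slice_count_range[0], slice_count_range[1] + 1))
        t, dead = survival_generator(count, spec, rng)
        records.append(PatientRecord(
            patient_id=f"SYN1-{i + 1:03d}",
            age=float(np.round(rng.uniform(45, 90), 1)),
            t_stage=float(rng.integers(1, 5)),
            n_stage=float(rng.integers(0, 4)),
            m_stage=float(rng.integers(0, 2)),
            overall_stage=_STAGES[int(rng.integers(0, len(_STAGES)))],
            histology=_HISTOLOGIES[int(rng.integers(0, len(_HISTOLOGIES)))],
            gender="male" if rng.uniform() < 0.7 else "female",
            survival_time=t, deadstatus_event=dead,
            gtv1_slice_num=count))
    return records


def separable_stack_dataset(n: int = 80, size: int = 32, depth: int = 5,
                            seed: int = 0, blob_intensity: float = 0.8
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable volumes for harness sanity checks.

    Positives carry a bright Gaussian blob at a random in-plane location on
    every slice over low-amplitude noise; negatives are noise only.  Returns
    ``(stacks, labels)`` with stacks shaped (n, size, size, depth) in [0, 1].
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 0.25, size=(n, size, size, depth))
    y = np.zeros(n, dtype=np.int64)
    y[rng.permutation(n)[: n // 2]] = 1
    gr, gc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for i in np.nonzero(y)[0]:
        r0 = rng.uniform(size * 0.3, size * 0.7)
        c0 = rng.uniform(size * 0.3, size * 0.7)
        blob = blob_intensity * np.exp(-(((gr - r0) ** 2 + (gc - c0) ** 2)
                                         / (2 * (size / 8) ** 2)))
        x[i] += blob[:, :, None]
    return np.clip(x, 0.0, 1.0), y


# ------------------------------------------------- special-purpose fixtures

def make_inventory_patient(counts: dict[str, int], n_slices: int,
                           seed: int = 0, patient_id: str = "SYN1-INV") -> PatientFixture:
    """A patient whose per-ROI contour counts are prescribed exactly.

    Contours cycle over slices (several per slice when count > n_slices),
    which reproduces real inventories where a lung ROI has more contours than
    the series has slices.
    """
    spec = FixtureSpec(n_patients=1, slices_range=(n_slices, n_slices),
                       rois=tuple(counts), seed=seed)
    rng = np.random.default_rng(seed)
    fx = make_patient(spec, 0, rng)
    fx = PatientFixture(**{**asdict_shallow(fx), "rois": {}})
    for name, count in counts.items():
        entries = []
        for k in range(count):
            idx = k % n_slices
            z = fx.z_positions[idx]
            entries.append((idx, _ellipse_polygon(-20.0 + (k % 7), -10.0, 8.0, 6.0, z, 8)))
        fx.rois[name] = entries
    fx2 = fx
    fx2.patient_id = patient_id
    return fx2


def asdict_shallow(fx: PatientFixture) -> dict:
    return {f: getattr(fx, f) for f in fx.__dataclass_fields__}
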