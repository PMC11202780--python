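"""Contour geometry: mm→pixel transform, polygon rasterization, intensity scaling.

The patient coordinate system of an axial CT slice maps to pixels through the
slice's reference point (ImagePositionPatient) and pixel spacing:

    x_pixel = (x_mm - x0) / xs        y_pixel = (y_mm - y0) / ys

with x along columns and y along rows.  Contours are filled with an even-odd
rule at pixel centers, boundary pixels included, so hand-drawn (possibly
self-intersecting) contours rasterize deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dicom_io import Contour, SliceMeta

_BOUNDARY_EPS = 1e-9


@dataclass
class TumorMask:
    """Binary tumour mask on one slice with its summary geometry."""

    sop_uid: str
    mask: np.ndarray  # 2-D bool
    area_px: int
    bbox: tuple[int, int, int, int] | None  # (row_min, col_min, row_max, col_max) inclusive
    centroid_px: tuple[float, float] | None  # (row, col)

    @classmethod
    def from_mask(cls, sop_uid: str, mask: np.ndarray) -> "TumorMask":
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            return cls(sop_uid, mask, 0, None, None)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
        centroid = (float(rows.mean()), float(cols.mean()))
        return cls(sop_uid, mask, int(rows.size), bbox, centroid)

    @property
    def empty(self) -> bool:
        return self.area_px == 0


@dataclass
class TumorMaskStack:
    """Per-slice GTV-1 masks for one patient, in CT z order."""

    patient_id: str
    masks: list[TumorMask]

    @property
    def areas(self) -> np.ndarray:
        return np.array([m.area_px for m in self.masks])

    @property
    def uids(self) -> list[str]:
        return [m.sop_uid for m in self.masks]


def mm_to_pixel(point_mm, image_position, pixel_spacing) -> tuple[float, float]:
    """Map a patient-coordinate (x, y) in mm to fractional (x, y) pixels.

    ``image_position`` is the (x0, y0) of the slice reference frame and
    ``pixel_spacing`` the (xs, ys) mm-per-pixel along x (columns) and y (rows).
    Rounding is deliberately deferred to rasterization.
    """
    xs, ys = float(pixel_spacing[0]), float(pixel_spacing[1])
    if xs <= 0 or ys <= 0:
        raise ValueError(f"pixel spacing must be positive, got {pixel_spacing}")
    x = (np.asarray(point_mm[0], dtype=np.float64) - float(image_position[0])) / xs
    y = (np.asarray(point_mm[1], dtype=np.float64) - float(image_position[1])) / ys
    if np.ndim(x) == 0:
        return float(x), float(y)
    return x, y


def _point_in_polygon(px: np.ndarray, py: np.ndarray,
                      vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Even-odd crossing test of points against a closed polygon (vectorized).

    Points within ``_BOUNDARY_EPS`` of an edge count as inside.
    """
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(vx)
    for i in range(n):
        x1, y1 = vx[i], vy[i]
        x2, y2 = vx[(i + 1) % n], vy[(i + 1) % n]
        # ray casting toward +x
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = np.where(crosses, (x2 - x1) * (py - y1) / (y2 - y1) + x1, np.inf)
        inside ^= crosses & (px < x_at)
        # distance from point to segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0.0:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
        else:
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / seg2, 0.0, 1.0)
            d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        on_edge |= d2 <= _BOUNDARY_EPS ** 2
    return inside | on_edge


def rasterize_polygon_px(vertices_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a polygon given in fractional pixel (x, y) coordinates.

    A pixel (r, c) is set when its center (x=c, y=r) is inside the polygon by
    the even-odd rule, or on its boundary.
    """
    vertices_xy = np.asarray(vertices_xy, dtype=np.float64)
    h, w = shape
    vx, vy = vertices_xy[:, 0], vertices_xy[:, 1]
    # only test the bounding-box neighbourhood
    c0 = max(int(np.floor(vx.min())) - 1, 0)
    c1 = min(int(np.ceil(vx.max())) + 1, w - 1)
    r0 = max(int(np.floor(vy.min())) - 1, 0)
    r1 = min(int(np.ceil(vy.max())) + 1, h - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    mask[r0:r1 + 1, c0:c1 + 1] = _point_in_polygon(
        cc.astype(np.float64), rr.astype(np.float64), vx, vy
    )
    return mask


def rasterize_contour(contour: Contour, slice_meta: SliceMeta) -> TumorMask:
    """Rasterize one mm contour onto its slice's pixel grid.

    Degenerate contours (fewer than 3 distinct vertices) produce an empty mask
    with a warning rather than an error — they occur in real structure sets.
    """
    import warnings

    pts = contour.points_mm
    distinct = np.unique(np.round(pts[:, :2], 9), axis=0)
    shape = slice_meta.pixel_array.shape
    if distinct.shape[0] < 3:
        warnings.warn("degenerate contour (<3 distinct points); empty mask", stacklevel=2)
        return TumorMask.from_mask(contour.referenced_sop_uid, np.zeros(shape, dtype=bool))
    xs, ys = slice_meta.pixel_spacing[1], slice_meta.pixel_spacing[0]
    x0, y0 = slice_meta.image_position[0], slice_meta.image_position[1]
    verts = np.column_stack(mm_to_pixel((pts[:, 0], pts[:, 1]), (x0, y0), (xs, ys)))
    mask = rasterize_polygon_px(verts, shape)
    return TumorMask.from_mask(contour.referenced_sop_uid, mask)


def rasterize_slice(contours: list[Contour], slice_meta: SliceMeta) -> TumorMask:
    """Union of all contours on one slice (multi-region slices, Fig.-style)."""
    mask = np.zeros(slice_meta.pixel_array.shape, dtype=bool)
    uid = slice_meta.sop_instance_uid
    for c in contours:
        mask |= rasterize_contour(c, slice_meta).mask
    return TumorMask.from_mask(uid, mask)


def dicom_to_byte_image(pixel_array: np.ndarray, *, strict_as_printed: bool = False) -> np.ndarray:
    """Normalize raw CT values into the 0–255 byte range.

    Default: ``round((dcm - min) / (max - min) * 255)``, which maps min→0 and
    max→255 for any input.  ``strict_as_printed`` divides by ``max(dcm)``
    alone instead; that variant can leave the 0–255 range when the array holds
    negative values and is provided only for comparison.
    Constant arrays map to all zeros (division guard).
    """
    import warnings

    arr = np.asarray(pixel_array, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("constant image; normalized to all zeros", stacklevel=2)
        return np.zeros(arr.shape, dtype=np.uint8)
    denom = hi if strict_as_printed else hi - lo
    out = np.round((arr - lo) / denom * 255.0)
    if strict_as_printed:
        return out.astype(np.int64)
    return out.astype(np.uint8)


def build_mask_stack(series, ss, *, roi_name: str = "GTV-1",
                     roi_regex: str | None = None) -> TumorMaskStack:
    """Rasterize every GTV-1 contour of a patient into a z-ordered mask stack."""
    from .dicom_io import gtv1_slice_uids, resolve_roi

    contours = resolve_roi(ss, roi_name, regex=roi_regex)
    uids = gtv1_slice_uids(series, ss, roi_name=roi_name, roi_regex=roi_regex)
    by_uid: dict[str, list[Contour]] = {}
    for c in contours:
        by_uid.setdefault(c.referenced_sop_uid, []).append(c)
    masks = [rasterize_slice(by_uid[uid], series.slice_by_uid(uid)) for uid in uids]
    return TumorMaskStack(patient_id=series.patient_id, masks=masks)


def export_mask_png(mask: TumorMask, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask * np.uint8(255)))


def export_slice_png(slice_meta: SliceMeta, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), dicom_to_byte_image(slice_meta.pixel_array))
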