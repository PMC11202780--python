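"""Quality control of GTV-1 mask stacks.

Lung1-style structure sets carry three classes of segmentation error:

* ``mislabel`` — the contour does not delineate the tumour at all; flagged
  only (no automatic repair is defensible without a clinician).
* ``area_jump`` — an interior slice whose tumour area collapses relative to
  both neighbours, the footprint of inter-slice interpolation artifacts;
  repaired by shape-based interpolation of the two neighbours.
* ``multi_tumor`` — more than one connected tumour region on a slice;
  repaired by keeping the patient's dominant laterality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .roi_geometry import TumorMask, TumorMaskStack

DEFAULT_TAU = 0.5


@dataclass
class QCReport:
    patient_id: str
    flags: list[tuple[str, str, str]] = field(default_factory=list)  # (sop_uid, class, detail)
    repaired: list[str] = field(default_factory=list)

    def add(self, sop_uid: str, error_class: str, detail: str) -> None:
        self.flags.append((sop_uid, error_class, detail))

    @property
    def clean(self) -> bool:
        return not self.flags

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.flags, columns=["sop_uid", "error_class", "detail"])
        df["repaired"] = df["sop_uid"].isin(self.repaired)
        df.insert(0, "patient_id", self.patient_id)
        df.to_csv(path, sep="\t", index=False)


def detect_area_jumps(stack: TumorMaskStack, tau: float = DEFAULT_TAU) -> list[str]:
    """Flag interior slices whose area collapses below ``tau`` of both neighbours.

    Slice i is flagged iff ``area_i < tau * min(area_{i-1}, area_{i+1})``.
    First and last slices have only one neighbour and are never flagged.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    areas = stack.areas
    flagged = []
    for i in range(1, len(areas) - 1):
        if areas[i] < tau * min(areas[i - 1], areas[i + 1]):
            flagged.append(stack.masks[i].sop_uid)
    return flagged


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the shape, negative outside, zero-crossing at the edge."""
    mask = mask.astype(bool)
    if not mask.any():
        return np.full(mask.shape, -np.inf)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_mask(prev: TumorMask, next_: TumorMask, sop_uid: str | None = None) -> TumorMask:
    """Shape-based interpolation between two neighbouring masks.

    The signed distance transforms of the neighbours are averaged and
    thresholded at zero, which reduces to the analytically obvious mid-shape
    for nested shapes (e.g. concentric disks → the mid-radius disk) and
    degrades gracefully for disjoint ones.
    """
    if prev.mask.shape != next_.mask.shape:
        raise ValueError("neighbour masks must share a shape")
    uid = sop_uid if sop_uid is not None else prev.sop_uid
    if prev.empty and next_.empty:
        raise ValueError("cannot interpolate between two empty masks")
    if prev.empty:
        return TumorMask.from_mask(uid, next_.mask.copy())
    if next_.empty:
        return TumorMask.from_mask(uid, prev.mask.copy())
    sd = 0.5 * (_signed_distance(prev.mask) + _signed_distance(next_.mask))
    return TumorMask.from_mask(uid, sd > 0)


def connected_components(mask: TumorMask) -> list[np.ndarray]:
    labels, n = ndimage.label(mask.mask)
    return [labels == k for k in range(1, n + 1)]


def _dominant_side(history: TumorMaskStack) -> str:
    """'left' or 'right' of the image vertical midline by summed tumour area."""
    if not history.masks:
        raise ValueError("empty stack")
    mid = history.masks[0].mask.shape[1] / 2.0
    left = sum(int(m.mask[:, : int(np.floor(mid))].sum()) for m in history.masks)
    right = sum(int(m.mask.sum()) for m in history.masks) - left
    if left > right:
        return "left"
    if right > left:
        return "right"
    # tie: side of the single largest connected component anywhere in the stack
    best_size, best_side = -1, "left"
    for m in history.masks:
        for comp in connected_components(m):
            size = int(comp.sum())
            if size > best_size:
                rows, cols = np.nonzero(comp)
                best_side = "left" if cols.mean() < mid else "right"
                best_size = size
    return best_side


def select_laterality(mask: TumorMask, history: TumorMaskStack) -> TumorMask:
    """Keep only the connected components on the patient's dominant side.

    Bilateral appearances (more than one tumour region on a slice) are
    resolved toward the side holding the larger summed GTV-1 area across the
    whole stack; single-component masks pass through unchanged.
    """
    comps = connected_components(mask)
    if len(comps) <= 1:
        return mask
    side = _dominant_side(history)
    mid = mask.mask.shape[1] / 2.0
    kept = np.zeros_like(mask.mask)
    for comp in comps:
        rows, cols = np.nonzero(comp)
        comp_side = "left" if cols.mean() < mid else "right"
        if comp_side == side:
            kept |= comp
    if not kept.any():  # every component on the minority side: keep largest
        largest = max(comps, key=lambda c: c.sum())
        kept = largest
    return TumorMask.from_mask(mask.sop_uid, kept)


def flag_mislabels(stack: TumorMaskStack, lung_masks: dict[str, np.ndarray] | None) -> list[str]:
    """Heuristic mislabel flags: GTV-1 centroid outside every lung mask.

    Requires rasterized lung ROIs (by slice UID); without them no mislabel
    call is made.  Flag-only — repairs need a clinician.
    """
    if not lung_masks:
        return []
    flagged = []
    for m in stack.masks:
        if m.empty or m.sop_uid not in lung_masks:
            continue
        r, c = int(round(m.centroid_px[0])), int(round(m.centroid_px[1]))
        lungs = lung_masks[m.sop_uid]
        if not lungs[r, c]:
            flagged.append(m.sop_uid)
    return flagged


def run_qc(stack: TumorMaskStack, tau: float = DEFAULT_TAU,
           lung_masks: dict[str, np.ndarray] | None = None) -> tuple[TumorMaskStack, QCReport]:
    """Full QC pass: laterality selection, area-jump repair, mislabel flags.

    Multi-component slices are reduced to the dominant side first (so that the
    area profile used for jump detection reflects a single tumour), then
    collapsed interior slices are replaced by the shape interpolation of their
    neighbours.  Mislabel flags never alter masks.  The pass is idempotent on
    its own output.
    """
    report = QCReport(patient_id=stack.patient_id)

    masks = list(stack.masks)
    for i, m in enumerate(masks):
        if len(connected_components(m)) > 1:
            report.add(m.sop_uid, "multi_tumor", "multiple connected tumour regions")
            masks[i] = select_laterality(m, stack)
    working = TumorMaskStack(patient_id=stack.patient_id, masks=masks)

    for uid in detect_area_jumps(working, tau):
        i = working.uids.index(uid)
        report.add(uid, "area_jump",
                   f"area {masks[i].area_px} < {tau} * min(neighbours)")
        masks[i] = interpolate_mask(masks[i - 1], masks[i + 1], sop_uid=uid)
        report.repaired.append(uid)

    for uid in flag_mislabels(working, lung_masks):
        report.add(uid, "mislabel", "GTV-1 centroid outside lung ROIs")

    return TumorMaskStack(patient_id=stack.patient_id, masks=masks), report


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
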