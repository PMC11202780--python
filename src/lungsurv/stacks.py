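"""Model-ready input stacks.

The classifier consumes a fixed-depth stack of tumour-bearing slices centred
on the slice with the largest GTV-1 area: by default five 240×240 grayscale
slices normalized to [0, 1].  Patients with fewer tumour slices than the
target depth are oversampled by duplicating edge slices; an ROI-crop variant
cuts a 128×128 window centred on the tumour bounding box instead of resizing
the whole slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .dicom_io import CTSeries
from .roi_geometry import TumorMaskStack, dicom_to_byte_image

DEFAULT_SIZE = (240, 240)
DEFAULT_DEPTH = 5
DEFAULT_CROP = (128, 128)


@dataclass
class InputStack:
    patient_id: str
    volume: np.ndarray  # H×W×D in [0, 1]
    source_uids: list[str]
    variant: str  # "full_slice" | "roi_crop"

    def __post_init__(self) -> None:
        if self.volume.ndim != 3:
            raise ValueError("volume must be H×W×D")
        if self.volume.shape[2] != len(self.source_uids):
            raise ValueError("depth must equal len(source_uids)")
        if self.volume.min() < 0 or self.volume.max() > 1:
            raise ValueError("volume values must lie in [0, 1]")

    @property
    def depth(self) -> int:
        return self.volume.shape[2]


def argmax_area_index(stack: TumorMaskStack) -> int:
    """Index of the largest-area slice; ties break toward the lower z index."""
    areas = stack.areas
    if len(areas) == 0:
        raise ValueError("empty mask stack")
    return int(np.argmax(areas))  # np.argmax returns the first maximum


def oversample_slices(uids: list[str], depth: int) -> list[str]:
    """Pad a short slice list to ``depth`` by duplicating edge slices.

    Copies alternate outward starting at the end: [7,8,9] → [7,7,8,9,9] for
    depth 5, [a,b,c,d] → [a,b,c,d,d].  Original order is preserved and the
    relative position of the centre slice moves as little as possible.
    """
    if not 1 <= len(uids) <= depth:
        raise ValueError(f"need 1 <= len(uids) <= depth, got {len(uids)} vs {depth}")
    out = list(uids)
    at_end = True
    while len(out) < depth:
        if at_end:
            out.append(out[-1])
        else:
            out.insert(0, out[0])
        at_end = not at_end
    return out


def select_slices(stack: TumorMaskStack, depth: int = DEFAULT_DEPTH) -> list[str]:
    """Choose the ``depth`` slice UIDs feeding the model.

    The window always contains the largest-area slice.  With at least
    ``depth`` tumour slices the window is centred on it where possible and
    shifted inward at the ends of the tumour range (so every selected slice
    still contains tumour); with fewer, all tumour slices are kept and edge
    slices are duplicated.
    """
    uids = stack.uids
    if not uids:
        raise ValueError("empty mask stack")
    if depth % 2 == 0:
        # even depths (4-slice ablation) are the next odd window minus its last
        # slice — minus its first when the largest-area slice sits at the end
        window = select_slices(stack, depth + 1)
        by_uid = {m.sop_uid: i for i, m in enumerate(stack.masks)}
        k = argmax_area_index(stack)
        if by_uid.get(window[-1]) == k:
            return window[1:]
        return window[:depth]
    k = argmax_area_index(stack)
    n = len(uids)
    if n >= depth:
        start = min(max(k - depth // 2, 0), n - depth)
        return uids[start:start + depth]
    return oversample_slices(uids, depth)


def _normalized_slice(series: CTSeries, uid: str) -> np.ndarray:
    return dicom_to_byte_image(series.slice_by_uid(uid).pixel_array).astype(np.float64) / 255.0


def build_full_slice_stack(series: CTSeries, uids: list[str],
                           size: tuple[int, int] = DEFAULT_SIZE) -> InputStack:
    """Resize whole normalized slices to ``size`` and stack them in z order."""
    planes = []
    for uid in uids:
        img = _normalized_slice(series, uid)
        img = resize(img, size, order=1, anti_aliasing=True, preserve_range=True)
        planes.append(np.clip(img, 0.0, 1.0))
    return InputStack(patient_id=series.patient_id,
                      volume=np.stack(planes, axis=-1),
                      source_uids=list(uids), variant="full_slice")


def _crop_centered(img: np.ndarray, center_rc: tuple[float, float],
                   crop: tuple[int, int]) -> np.ndarray:
    """Crop around a centre, clamped to the image and zero-padded to size."""
    h, w = img.shape
    ch, cw = crop
    r0 = int(round(center_rc[0])) - ch // 2
    c0 = int(round(center_rc[1])) - cw // 2
    r0 = min(max(r0, 0), max(h - ch, 0))
    c0 = min(max(c0, 0), max(w - cw, 0))
    window = img[r0:r0 + ch, c0:c0 + cw]
    if window.shape != (ch, cw):
        padded = np.zeros((ch, cw), dtype=img.dtype)
        padded[: window.shape[0], : window.shape[1]] = window
        return padded
    return window


def build_roi_crop_stack(series: CTSeries, masks: TumorMaskStack, uids: list[str],
                         crop: tuple[int, int] = DEFAULT_CROP) -> InputStack:
    """Crop a fixed window centred on the tumour bounding-box midpoint per slice.

    Slices whose mask is empty (possible after oversampling corrupt data)
    fall back to the bounding-box centre of the stack's largest-area slice.
    """
    by_uid = {m.sop_uid: m for m in masks.masks}
    fallback = masks.masks[argmax_area_index(masks)]
    planes = []
    for uid in uids:
        mask = by_uid.get(uid)
        if mask is None or mask.empty:
            mask = fallback
        r0, c0, r1, c1 = mask.bbox
        center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
        img = _normalized_slice(series, uid)
        planes.append(np.clip(_crop_centered(img, center, crop), 0.0, 1.0))
    return InputStack(patient_id=series.patient_id,
                      volume=np.stack(planes, axis=-1),
                      source_uids=list(uids), variant="roi_crop")


def build_input_stack(series: CTSeries, masks: TumorMaskStack, *,
                      depth: int = DEFAULT_DEPTH, variant: str = "full_slice",
                      size: tuple[int, int] = DEFAULT_SIZE,
                      crop: tuple[int, int] = DEFAULT_CROP) -> InputStack:
    """End-to-end stack construction for one patient."""
    uids = select_slices(masks, depth)
    if variant == "full_slice":
        return build_full_slice_stack(series, uids, size)
    if variant == "roi_crop":
        return build_roi_crop_stack(series, masks, uids, crop)
    raise ValueError(f"unknown variant {variant!r}")


def save_stack(stack: InputStack, path: str | Path) -> None:
    """Persist volume (.npz) plus a JSON sidecar with provenance."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), volume=stack.volume)
    sidecar = {"patient_id": stack.patient_id, "variant": stack.variant,
               "source_uids": stack.source_uids}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(path: str | Path) -> InputStack:
    path = Path(path)
    volume = np.load(path.with_suffix(".npz"))["volume"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return InputStack(patient_id=meta["patient_id"], volume=volume,
                      source_uids=meta["source_uids"], variant=meta["variant"])
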