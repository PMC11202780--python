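"""Locate the GTV-1 tumour slices of a patient via UID intersection.

The RTSTRUCT's GTV-1 contours reference CT slices by SOP Instance UID;
intersecting those references with the series' own UIDs yields the ordered
set of tumour-bearing slices, and rasterizing the contours gives per-slice
masks, areas and bounding boxes.
"""

import numpy as np

from lungsurv.dicom_io import gtv1_slice_uids, structure_inventory
from lungsurv.fixtures import FixtureSpec, make_patients, to_ct_series, to_structure_set
from lungsurv.roi_geometry import build_mask_stack

patients, manifest = make_patients(FixtureSpec(n_patients=1, seed=11))
fx = patients[0]
series, ss = to_ct_series(fx), to_structure_set(fx)

print(structure_inventory(ss).to_string(index=False))
uids = gtv1_slice_uids(series, ss)
print(f"\n{len(uids)} GTV-1 slices "
      f"(manifest says {manifest.patients[fx.patient_id]['gtv1_slice_count']})")

masks = build_mask_stack(series, ss)
largest = int(np.argmax(masks.areas))
m = masks.masks[largest]
print(f"largest tumour cross-section: slice {largest} of the tumour range, "
      f"{m.area_px} px, bbox {m.bbox}")

# Areas in pixels convert to mm^2 through the 0.977 mm pixel spacing; the
# bounding-box midpoint is what the ROI-crop input variant centres on.
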