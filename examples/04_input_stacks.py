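"""Build the model-ready 240x240x5 input stack for a patient.

The window of five tumour-bearing slices is centred on the largest
cross-section; patients with fewer than five tumour slices get edge slices
duplicated.  Intensities pass through byte normalization and land in [0, 1].
"""

from lungsurv.fixtures import FixtureSpec, make_patients, to_ct_series, to_structure_set
from lungsurv.roi_geometry import build_mask_stack
from lungsurv.stacks import build_input_stack, oversample_slices, select_slices

patients, _ = make_patients(FixtureSpec(n_patients=1, seed=2))
fx = patients[0]
series = to_ct_series(fx)
masks = build_mask_stack(series, to_structure_set(fx))

window = select_slices(masks, depth=5)
print("selected slice UIDs (z order):")
for uid in window:
    i = masks.uids.index(uid)
    print(f"  {uid.rsplit('.', 1)[-1]:>3}  area {masks.masks[i].area_px} px")

stack = build_input_stack(series, masks, depth=5, variant="full_slice")
print(f"full-slice stack: {stack.volume.shape}, "
      f"range [{stack.volume.min():.3f}, {stack.volume.max():.3f}]")

roi = build_input_stack(series, masks, depth=5, variant="roi_crop", crop=(64, 64))
print(f"ROI-crop stack:   {roi.volume.shape}, centred on the tumour bbox")

print("oversampling [7, 8, 9] to depth 5:", oversample_slices(["7", "8", "9"], 5))

# The centre slice of the window is always the largest tumour area; the
# ROI-crop variant trades surrounding anatomy for tumour-local detail.
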