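"""Generate a small synthetic DICOM cohort and inspect its ground truth.

Each patient gets an axial CT series, an RTSTRUCT with GTV-1/lung/cord
contours, a clinical row, and a manifest entry recording the true tumour
geometry and survival process.
"""

import tempfile
from pathlib import Path

from lungsurv.fixtures import FixtureSpec, make_cohort

with tempfile.TemporaryDirectory() as td:
    root, manifest = make_cohort(FixtureSpec(n_patients=3, seed=7), td)
    files = sorted(p.relative_to(root) for p in Path(root).rglob("*") if p.is_file())
    print(f"cohort at {root}: {len(files)} files")
    for f in files[:4]:
        print("  ", f)
    print("   ...")
    for pid, truth in manifest.patients.items():
        c = truth["clinical"]
        print(f"{pid}: {truth['n_slices']} CT slices, "
              f"{truth['gtv1_slice_count']} GTV-1 slices, "
              f"survival {c['Survival.time']:.0f} d "
              f"({'death' if c['deadstatus.event'] else 'censored'})")

# The GTV-1 slice count is the cranio-caudal tumour extent in 3 mm slices;
# the survival times are drawn from a Weibull whose scale shrinks with it.
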