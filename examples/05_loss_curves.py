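"""Compare PEN-BCE with plain BCE on a probability grid.

PEN-BCE adds hinge-squared penalties: alpha*max(0, p_FN - p)^2 on positives
and beta*max(0, p - p_FP)^2 on negatives.  For a positive label the curve
sits above BCE below the p_FN threshold and coincides with it above.
"""

import numpy as np

from lungsurv.losses import LossParams, bce, loss_curve, pen_bce

params = LossParams(alpha=1.0, beta=5.0, p_fn=0.50, p_fp=0.20)  # published best
grid = np.array([0.05, 0.25, 0.50, 0.75, 0.95])

b = loss_curve("bce", grid, y_fixed=1)
pb = loss_curve("pen_bce", grid, y_fixed=1, params=params)
print("y=1      p     BCE  PEN-BCE   penalty")
for (p, lb), (_, lp) in zip(b, pb):
    print(f"      {p:.2f}  {lb:6.4f}  {lp:6.4f}   {lp - lb:+.4f}")

print("\nsingle-sample checks:")
print(f"  y=1, p=0.25: {pen_bce([0.25], [1], LossParams(1, 0, 0.5, 0.2)):.4f}"
      f"  (= -ln 0.25 + 0.25^2 = 1.4488)")
print(f"  y=0, p=0.60: {pen_bce([0.6], [0], LossParams(0, 5, 0.5, 0.2)):.4f}"
      f"  (= -ln 0.40 + 5*0.40^2 = 1.7163)")
print(f"  alpha=beta=0 reduces to BCE exactly: "
      f"{pen_bce([0.3, 0.8], [1, 0], LossParams(0, 0, 0.5, 0.2)) == bce([0.3, 0.8], [1, 0])}")

# The penalty vanishes once a positive is predicted above p_FN (or a negative
# below p_FP), so well-classified samples see the ordinary BCE gradient.
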