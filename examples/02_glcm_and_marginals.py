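"""Count gray-level co-occurrences of a gradient and derive its marginals.

For a linear gradient the non-symmetric GLCM has all its nonzero cells,
with equal counts on exact-period images, on exactly two lines parallel
to the main diagonal; the difference marginal is therefore two-point.
"""

import numpy as np

from gradtex import (
    Displacement, GradientSpec, count_pairs, make_gradient_image,
    marginal_diff, marginal_sum, normalize,
)

img = make_gradient_image(
    GradientSpec(ng=8, grad=2, width=4, height=32, exact_period_for=1)
)
counts = count_pairs(img, Displacement(dx=0, dy=1))
print("GLCM counts (rows = reference level i, cols = target level j):")
print(counts.counts)
print(f"{counts.n_nonzero} nonzero cells, all equal -> a 2-line support: "
      "j - i = +2 (the gradient step) and the single wrap cell (6, 0).")

p = normalize(counts)
dm = marginal_diff(p)
print("\nabsolute difference marginal:",
      {int(k): float(v) for k, v in zip(dm.absolute_support, dm.absolute) if v > 0})
print("-> mass 3/4 at the gradient step d*grad = 2, mass 1/4 at the wrap "
      "difference m1*grad = 6.")

sm = marginal_sum(p)
print("sum marginal:",
      {int(s): float(v) for s, v in zip(sm.support, sm.probs) if v > 0})
print("-> two sum values collide at s = 6, which is why its mass doubles.")
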