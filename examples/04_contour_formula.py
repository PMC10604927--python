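"""Fit the closed-form contour map f(t) and export it as a formula.

A three-layer network (sigmoid hidden layer, ReLU output) is trained on a
chord-length parameterization of a contour; its weights then constitute an
explicit map t -> (x, y) that can be evaluated with no network runtime.
"""

import numpy as np

from kidseg import abnn
from kidseg.aspt import VertexSequence

# a closed star-like contour, parameterized by chord position t in [0, 1)
n = 80
t = np.arange(n) / n
radius = 1.0 + 0.15 * np.cos(4 * np.pi * t)
coords = np.column_stack(
    [radius * np.cos(2 * np.pi * t), radius * np.sin(2 * np.pi * t)]
)

fit = abnn.train_abnn(VertexSequence(t=t, coords=coords), s=20)
print(f"fit MSE {fit.loss_history[-1]:.2e} after {len(fit.loss_history) - 1} epochs; "
      f"closure error |f(0) - f(1)| = {fit.closure_error:.4f}")

doc = abnn.export_map(fit.params, fit.output_transform)
print(f"exported map: {doc['s']} hidden neurons, head={doc['head']}")
for q in (0.0, 0.25, 0.5):
    x, y = abnn.evaluate_map(doc, q)
    print(f"  f({q:.2f}) = ({x:+.3f}, {y:+.3f})   target ({coords[int(q * n), 0]:+.3f}, "
          f"{coords[int(q * n), 1]:+.3f})")
# The exported record alone (weights + thresholds + output transform)
# reproduces the trained network, which is what makes the contour
# representation explainable rather than a black box.
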