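"""Refine a boundary point cloud into an optimized polygon.

Demonstrates the polygon-tracking stage in isolation: the number of
vertices is discovered by adaptive mean-shift clustering, then the vertex
positions are optimized under the penalized-distance objective (average
squared data distance plus the averaged curvature penalty MP).
"""

import numpy as np

from kidseg.aspt import ASPTConfig, run_aspt
from kidseg.geometry import denormalize, dsc, extract_contour_vertices, rasterize_polygon
from kidseg.phantom import PhantomSpec, generate_phantom

_, mask, _ = generate_phantom(PhantomSpec(shape_seed=11))
boundary = extract_contour_vertices(mask)
print(f"boundary cloud: {len(boundary)} pixels")

result = run_aspt(boundary, ASPTConfig(penalty="mp"))
print(f"discovered {result.report['n_modes']} vertices (no count was supplied)")
print(f"objective: {result.report['initial_objective']:.4f} -> "
      f"{result.report['final_objective']:.4f} over "
      f"{result.report['n_accepted_moves']} accepted moves")

polygon = denormalize(result.sequence.coords, result.transform)
print(f"polygon vs true mask DSC: {dsc(rasterize_polygon(polygon, mask.shape), mask):.3f}")
print("first sequence entries (t, x, y):")
for t, (x, y) in list(zip(result.sequence.t, polygon))[:4]:
    print(f"  {t:.3f}  {x:7.2f} {y:7.2f}")
# The objective only ever decreases, and the handful of discovered vertices
# already reproduce the mask to high overlap before any smoothing.
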