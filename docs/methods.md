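# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `kidseg`, in the order the pipeline runs them.

## Synthetic phantom model

Real kidney ultrasound could not be bundled, so the package generates
phantoms whose difficulty factors mirror the clinical ones: blurred and
partially missing boundaries, low organ/background contrast, speckle
texture, and shape variation across "patients" and views.

The shape is an analytic radial function about the organ center: an
ellipse (semi-axes a, b, rotation), minus a cosine-bump indentation on the
medial side standing in for the renal hilum (depth a fraction of b, in
[0, 0.5]), times a low-order random Fourier perturbation of the radius
(orders 2–4, amplitude a fraction of the mean radius). The mask is the
exact even-odd rasterization of this polygon and the contour is the
polygon itself, so segmentation scores are measured against exact ground
truth — the mask/contour DSC consistency is 1.0 by construction.

Texture: the ideal two-level image (background 70, foreground background +
contrast gap) is multiplied by unit-mean gamma speckle with variance
`speckle_strength²` — a standard first-order surrogate for fully developed
ultrasound speckle — then blurred with a Gaussian of
`boundary_blur_sigma` pixels, which also softens the boundary. An optional
angular wedge attenuates contrast to emulate acoustic dropout from
intestinal gas. Additive Gaussian noise at σ ∈ {0, 10, 25, 50} on the
8-bit scale is a separate corruption step used by the robustness
experiment.

Dataset defaults (intervals sampled per phantom, chosen once as plausible
ranges for trans-abdominal kidney views at 96×96): semi-axes 26–38% /
16–26% of the frame, rotation ±0.5 rad, indentation 0.10–0.40, Fourier
amplitude 0.02–0.06, speckle 0.25–0.45, blur 1.0–2.0 px, contrast gap
45–80, 30% shadow-wedge probability. Everything is a pure function of the
spec's seed; all invariants (single 4-connected component, no holes, 5–60%
foreground) are enforced at generation time.

What the phantoms do **not** model: beamforming and depth-dependent
attenuation, internal organ structure (pelvis, calyces), neighboring
organs, and operator-dependent probe geometry. Passing tests therefore
demonstrate the correctness and internal behavior of the pipeline, not
clinical performance.

## Coarse stage

The segmenter is a U-Net (depth 3, base 8 channels, 96×96 inputs by
default; all three are config options) with double 3×3 convolutions per
stage, 2×2 max pooling, nearest-neighbor upsampling followed by a 1×1
channel-halving convolution, and a 1×1 sigmoid head. At each skip
connection the features pass through a squeeze-and-excitation block
(global **max** pooling squeeze — average pooling is available as a
switch — then two 1×1 convolutions with ReLU and sigmoid) and an
attention gate (concatenation of skip and upsampled decoder features →
ReLU → 1×1 convolution → sigmoid → per-pixel multiplicative attention).
The four fusion variants are serial1 (AG then SE), serial2 (SE then AG),
parallel1 (AG(skip) + SE(decoder features)) and parallel2
(AG(skip) + SE(skip)); the parallel combiner is an element-wise sum, which
preserves the channel count and keeps the two branches symmetric, after
which the fused skip is concatenated with the decoder features as in a
plain U-Net.

Training: Dice loss with ε = 1, Adam at 1e-3, batch 8, Kaiming-style
fan-in initialization, one shared rotation in [−20°, 20°] per sample per
epoch (bilinear for the image, nearest for the mask), best-validation
checkpointing, fully seeded. The networks run on the package's numpy
autodiff engine (`kidseg.nn`): reverse-mode tape over float32 arrays with
convolution computed as per-offset einsum contractions. Gradients of every
op are verified against central finite differences in the test suite.

Prediction thresholds the probability map at 0.5 and keeps the largest
4-connected component (the refinement stage assumes a single closed
object); an empty mask is a flagged "no object" result rather than an
error. Inputs of other sizes are resampled in and the probability map
resampled back out bilinearly.

Desk-scale defaults were chosen so a full experiment (train + refine +
noise sweep) runs in minutes on one CPU; a 600×450 configuration is just a
config change.

## Polygon tracking (refinement stage 1)

All geometry happens in min-max-normalized [−1, 1]² coordinates; the
affine transform is stored and inverted exactly on output.

**Vertex discovery.** Per-point bandwidths h_i are distances to the k-th
nearest neighbor, k = max(5, ⌈2% of n⌉) by default. Mean shift uses the
sample-point density estimator: the shifted mean at y weights data point
p_j by h_j^−4 · exp(−‖y−p_j‖²/2h_j²); trajectories stop when the shift
drops below 1e-3 (normalized units) or after 500 iterations, and converged
positions merge into modes within half the median bandwidth. The defaults
matter on boundary-pixel clouds: wider bandwidths (larger k) or a tighter
stopping tolerance let trajectories crawl along the one-pixel-wide curve
and collapse to too few vertices to describe a kidney outline; the chosen
values yield 10–15 vertices on a 96×96 phantom boundary. The mode count is
never supplied by the user. A fixed-bandwidth mode (scalar bandwidth, or
"median" for the median of the adaptive ones) supports the clustering
ablation with exactly one factor changed.

**Ordering.** Modes are sorted by polar angle about their centroid (ties
by radius); if that polygon self-intersects — possible for
non-star-convex mode sets — the fallback chains nearest neighbors from
the lowest-angle mode. Kidney outlines are near-star-convex, so the
fallback is rarely taken.

**Partition.** Each data point is assigned once, to its nearest element
of the closed polygon: the interior of a segment when its projection falls
strictly inside, otherwise the vertex its projection clips to (the Voronoi
partition of the curve). This makes on-curve data an exact fixed point of
the optimization: all points sit in segment sets at distance zero, so the
data term vanishes.

**Objective.** Per vertex, Δ(v_i) = σ₋ + τ + σ₊ sums squared distances of
the vertex-assigned points to v_i and of the two incident segments'
points to those segments (every vertex of a closed polygon is interior;
empty sets contribute zero). The modified curvature penalty MP(v_i)
averages, over the `is` segments, the mean squared distance of each
segment's points to v_i; the classical CP(v_i) = r²(1 + cos γ_i) with the
interior turn angle γ_i is kept for ablations. The penalty weight is
λ = λ′ · iv^{1/3} · √(mean Δ)/r with λ′ = 0.13; λ thus vanishes as the fit
tightens, so the centroid pull of MP is self-limiting. The total
objective is Σ_i [Δ(v_i)/iv + λ·penalty(v_i)/(is+1)].

**Optimizer.** Cyclic coordinate descent: each vertex's x then y
coordinate is minimized by bounded scalar search (±0.5 × median bandwidth,
25 iterations) with the full objective — partitions and λ — recomputed
for every candidate; a move is accepted only if the total does not
increase, which makes the accepted-objective trace provably
non-increasing (a violation aborts with a diagnostic). Rounds stop when
the relative decrease falls below 1e-3 (a tolerance above 1 is satisfied
trivially and returns the initial curve) or after 10 rounds. The objective
function used by the optimizer is a vectorized twin of the readable
per-vertex implementation; the two are held equal to 1e-10 in tests, and
both are checked against brute-force loop oracles.

**Parameterization.** t is the normalized cumulative chord length:
t_1 = 0, t_iv = (perimeter − last segment)/perimeter < 1, with the first
vertex repeated at t = 1 for closed-contour fitting only. Chord length
(rather than vertex index) makes the contour map's input geometry-aware.

## Contour map (refinement stage 2)

The map f(t) has a sigmoid hidden layer and, by default, a ReLU output
head; the printed formula the package exports consists of the weights
(w1, m, w2, u), the head type, and the output transform. An exponential
output head is retained as an option; its training dynamics are less
stable (the gradient scales with the output), so ReLU is the default.

Because a ReLU head is nonnegative while normalized coordinates live in
[−1, 1], targets are affinely mapped into [0.1, 0.9] per axis before
training and inverse-mapped on output; the transform is part of the
exported record, and the bundled scalar evaluator reproduces the runtime
network to 1e-12.

Initialization places each sigmoid's transition at an evenly spaced
position in t ∈ [0, 1] (random-sign input weights of magnitude 12–28,
thresholds m_i = w1_i·(i+0.5)/s), with small output weights and slightly
negative output thresholds so the ReLU head starts active — a dead head
has zero gradient and cannot recover, and zero thresholds concentrate all
knees at t = 0, which empirically leaves the fit an order of magnitude
worse on closed contours.

Training is full-batch gradient descent with momentum 0.9, initial rate
0.4, and at most 1000 epochs. The adaptive rule: after an epoch that
lowers the loss the rate is multiplied by 1.05; after one that raises it
the step is rejected, the momentum buffer cleared, and the rate multiplied
by 0.7 — so the accepted-loss sequence is non-increasing. Disabling the
rule (fixed rate, every step accepted) gives the plain trainer used as the
ablation baseline. The trainer optionally restarts from several seeded
initializations and keeps the lowest final loss (the pipeline uses 3);
momentum descent on small sigmoid networks has poor local minima on
sharply indented contours, and restarts are the cheapest reliable remedy.
"Stochastic" minibatching is unnecessary at tens of training points, so
descent is full-batch.

In the pipeline the network is fit not to the bare vertex sequence but to
the boundary data cloud itself, each point parameterized by the
chord-length position of its projection onto the optimized polygon
(`aspt.project_to_curve` / `aspt.data_sequence`). Fitting 10–15 vertices
alone leaves the smooth map unconstrained between vertices, and fitting a
piecewise-linear resampling of the polygon (`aspt.resample_curve`, kept in
the API) bakes the polygon's chord cuts into the smooth contour; fitting
the data directly lets the network average boundary noise the way a
principal curve should, and measurably improves the refined overlap on
phantoms whose true mask is fed in directly. The vertex sequence D itself
is unchanged and remains the stage's reported output. Default hidden
width s = 20; the closure error |f(0) − f(1)| is reported with every fit.

Before the refined contour is rasterized for scoring, it is offset half a
pixel along its outward normals (`geometry.offset_polygon`). The boundary
point set consists of boundary *pixel centers*, which lie about half a
pixel inside the true region edge; a contour fit to them under-covers the
region by roughly perimeter/2 pixels — around two DSC points at 96×96 —
and the offset removes that discretization bias.

## Experiments and reporting

The ablation harness evaluates six configurations on an identical test
set with identical seeds, sharing one trained Parallel-2 coarse model:
coarse only; fixed-bandwidth clustering + classical penalty + fixed-rate
smoother; and the four combinations toggling adaptive clustering, the
averaged penalty, and the adaptive-rate smoother, up to the full method.
"Fixed bandwidth" is the median of the adaptive bandwidths so the
clustering comparison changes exactly one factor. The noise experiment
corrupts the test images at σ ∈ {0, 10, 25, 50} (σ = 0 is the identity)
and runs the full pipeline per level. Reports store per-image DSC/Jaccard
lists alongside mean ± SD, contain no timestamps, and serialize with
sorted keys, so identical configurations reproduce byte-identical files.

Problem sizes used by the test suite and the acceptance script — 96×96
phantoms, 64/8/16 train/val/test, 30 training epochs — are the package's
desk-scale working point; they are large enough for the qualitative
effects (refinement benefit, monotone noise degradation) to be stable
across seeds while keeping a full run in the minutes range on one CPU.

## Numerical choices and degenerate inputs

- Rasterization fills pixel centers at integer coordinates under the
  even-odd rule; boundary-touching centers count as inside;
  self-intersecting polygons are filled with a warning.
- DSC and Jaccard are 1 when both masks are empty, keeping noise sweeps
  total.
- Duplicate points in bandwidth estimation fall back to the smallest
  positive neighbor distance (warned); an all-identical cloud is an error.
- Collinear mean-shift modes produce a flagged degenerate polygon;
  fewer than 3 modes is an error suggesting a smaller k.
- Non-finite training losses abort immediately in both networks.
- Float32 is used in the U-Net engine (verified against finite
  differences at that precision); the geometry and the contour network
  run in float64.

## Known limitations

- The phantom generator's realism gap (above) bounds what green tests say
  about clinical data.
- Geometric refinement has an intrinsic fidelity ceiling: even fed the
  true mask, the polygon + smooth-map chain reproduces it at DSC ≈ 0.99
  at 96×96 (smooth-map approximation plus rasterization). When the coarse
  stage already scores at or above that ceiling — as it does on clean
  phantoms at this difficulty — refinement is overlap-neutral rather than
  beneficial; its gain appears for imperfect coarse masks (noisy inputs,
  weaker or under-trained models), which is the regime the two-stage
  design targets.
- Mean-shift vertex discovery assumes a single closed boundary; multiple
  organs or interior structures would need a component split upstream.
- The angular ordering heuristic can fail on strongly non-convex shapes;
  the nearest-neighbor fallback handles moderate cases but has no
  optimality guarantee.
- The exponential output head reproduces the printed closed form but is
  kept off by default for stability; the two heads are not numerically
  interchangeable.
- Coordinate descent finds a local optimum of the penalized distance; no
  global-optimality claim is made, only monotonicity.
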