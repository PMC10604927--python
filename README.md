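# kidseg

Coarse-to-refine kidney segmentation for 2D ultrasound images, built as an
importable Python library with a thin `kidseg` command-line tool.

Kidney boundaries in trans-abdominal ultrasound are blurred, low-contrast,
partially occluded by intestinal gas, and variable in shape across patients
and views, so a learned segmenter alone tends to produce ragged or leaky
masks. This package implements a two-stage pipeline for users who need a
single smooth closed contour — for example for organ delineation in
ultrasound-guided therapy planning — together with a synthetic phantom
generator that provides exact ground truth for development and evaluation.

## The method

**Stage 1 — deep fusion coarse segmentation.** A U-Net whose skip
connections are augmented by two recalibration modules: a
squeeze-and-excitation block (global max-pool squeeze, two 1×1
convolutions, sigmoid channel gates) and an attention gate (concatenate
skip and decoder features → ReLU → 1×1 convolution → sigmoid spatial
attention). Four fusion variants are supported at every skip — AG→SE
serial, SE→AG serial, and two parallel forms differing in whether the SE
branch sees decoder or encoder features. Training uses Dice loss

    L = 1 − (2·Σ p q + ε) / (Σ p + Σ q + ε),  ε = 1,

with Adam and rotation augmentation in [−20°, 20°]. The thresholded mask's
boundary pixels form the point set P = {p_1, …, p_n}.

**Stage 2a — automatic searching polygon tracking.** P is min-max
normalized into [−1, 1]², then adaptive mean-shift clustering (per-point
k-NN bandwidths, Gaussian kernel) discovers the polygon vertices — the
vertex count is a property of the data, never a user input. The vertices
are ordered counter-clockwise and optimized by cyclic coordinate descent
on a penalized distance

    G′(v_i) = Δ(v_i)/iv + λ · MP(v_i)/(is + 1),
    λ = λ′ · iv^{1/3} · √(mean Δ) / r,   λ′ = 0.13,

where Δ(v_i) sums squared distances of the data assigned to vertex v_i and
its two incident segments, MP(v_i) is the averaged squared distance from
each segment's data to v_i, and r is the data radius. The classical
angle-based penalty CP(v_i) = r²(1 + cos γ_i) is available for component
ablations.

**Stage 2b — closed-form contour map.** A three-layer network
(sigmoid hidden layer, ReLU output head) is fit to the boundary data,
each point parameterized by the chord-length position of its projection
onto the polygon, using momentum gradient descent with an adaptive
learning rate (×1.05 after an improving epoch; ×0.7 with step rejection
otherwise). Its weights constitute an explicit formula

    f(t) = ( h₂(Σ_i h₁(t·w1_i − m_i)·w2_{i,1} − u₁),
             h₂(Σ_i h₁(t·w1_i − m_i)·w2_{i,2} − u₂) ),  t ∈ [0, 1],

exported as JSON and evaluable with no network runtime.

Evaluation uses the Dice similarity coefficient DSC = 2|A∩B|/(|A|+|B|) and
the Jaccard coefficient Ω = |A∩B|/|A∪B| (DSC = 2Ω/(1+Ω)).

## Worked example

```bash
python examples/03_polygon_tracking.py
```

prints (abbreviated):

```
boundary cloud: 141 pixels
discovered 11 vertices (no count was supplied)
objective: 0.7074 -> 0.0559 over 214 accepted moves
polygon vs true mask DSC: 0.977
```

The boundary pixels of a phantom mask are reduced to 11 automatically
discovered vertices; the penalized-distance objective falls monotonically
across accepted moves; and the resulting polygon reproduces the true mask
with DSC 0.977. `examples/04_contour_formula.py` then shows the same idea
for the smoothing stage: a fit of the closed-form map with MSE ≈ 4e-5
whose exported formula evaluates `f(0.25) = (−0.004, +0.844)` against the
target `(0.000, 0.850)`.

The other examples cover phantom generation (`01`), coarse-model training
(`02`), and the full two-stage chain with per-stage DSC/Jaccard (`05`).

## Command line

```bash
kidseg phantom --n-train 64 --n-val 8 --n-test 16 --seed 0 --out data/
kidseg train --variant parallel2 --data data/ --epochs 30 --seed 0 --out model
kidseg segment --model model.npz --image img.png --out-mask m.png --out-contour c.csv
kidseg refine --mask m.png --out seq.csv --penalty mp
kidseg fit-contour --sequence seq.csv --hidden 20 --out-map map.json --out-contour fine.csv
kidseg ablation --data data/ --model model.npz --out ablation.json
kidseg noise --data data/ --model model.npz --sigmas 0,10,25,50 --out noise.json
```

All commands are deterministic for fixed seeds: rerunning with the same
configuration reproduces outputs byte for byte.

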