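"""Deep fusion coarse segmentation: U-Net with SE/AG skip fusion.

The coarse stage is a small encoder–decoder U-Net whose skip connections
are augmented with two feature-recalibration modules:

* **SE (squeeze-and-excitation)** — channel gates from a global max-pool
  squeeze followed by two 1x1 convolutions (ReLU then sigmoid);
* **AG (attention gate)** — a spatial attention map from the concatenation
  of the skip features and the upsampled decoder features, passed through
  ReLU, a 1x1 convolution and a sigmoid, then multiplied into the skip.

Four fusion variants are supported at every skip connection:

========== =====================================================
serial1    AG then SE applied in series to the skip features
serial2    SE then AG applied in series
parallel1  AG(skip) and SE(decoder features), summed
parallel2  AG(skip) and SE(encoder skip features), summed
========== =====================================================

The parallel combiner is an element-wise sum of the two branches (both
preserve the skip channel count), after which the fused skip is
concatenated with the upsampled decoder features as in a plain U-Net.
Training uses Dice loss and Adam with optional rotation augmentation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from kidseg import nn
from kidseg.geometry import ContourPointSet, extract_contour_vertices
from kidseg.nn import Tensor

__all__ = [
    "DFLNConfig",
    "SegmentationOutput",
    "SEBlock",
    "AGBlock",
    "DFLN",
    "build_model",
    "dice_loss",
    "augment_rotate",
    "train",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

VARIANTS = ("serial1", "serial2", "parallel1", "parallel2")


@dataclass
class DFLNConfig:
    variant: str = "parallel2"
    depth: int = 3
    base_channels: int = 8
    se_reduction: int = 2
    se_pool: str = "max"  # the squeeze op; "avg" available for comparison
    input_size: tuple[int, int] = (96, 96)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    augment_max_degrees: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid options: {', '.join(VARIANTS)}"
            )
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        h, w = self.input_size
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if self.se_pool not in ("max", "avg"):
            raise ValueError("se_pool must be 'max' or 'avg'")


@dataclass
class SegmentationOutput:
    """Probability map plus its thresholded, cleaned binary mask."""

    probability_map: np.ndarray
    binary_mask: np.ndarray
    largest_component_only: bool = True
    no_object: bool = False


class SEBlock(nn.Module):
    """Channel recalibration: global pool -> 1x1 conv bottleneck -> gates."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 pool: str = "max"):
        if channels < reduction:
            logger.warning(
                "SE reduction %d exceeds channel count %d; clamping to 1",
                reduction, channels,
            )
            reduction = 1
        mid = max(channels // reduction, 1)
        self.fc1 = nn.Conv2d(channels, mid, 1, rng)
        self.fc2 = nn.Conv2d(mid, channels, 1, rng)
        self.pool = pool

    def __call__(self, x: Tensor) -> Tensor:
        if self.pool == "max":
            squeezed = nn.global_maxpool(x)
        else:
            squeezed = _global_avgpool(x)
        gates = self.fc2(self.fc1(squeezed).relu()).sigmoid()
        return x * gates


def _global_avgpool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bw(g):
        x._accum(np.broadcast_to(g / (h * w), x.shape).copy())

    return Tensor._make(out, (x,), bw)


class AGBlock(nn.Module):
    """Spatial attention gate on skip features, driven by decoder context.

    concat(skip, gating) -> ReLU -> 1x1 conv -> sigmoid -> one attention
    coefficient per pixel, multiplied into the skip features.
    """

    def __init__(self, skip_channels: int, gate_channels: int, rng: np.random.Generator):
        self.skip_channels = skip_channels
        self.gate_channels = gate_channels
        self.att = nn.Conv2d(skip_channels + gate_channels, 1, 1, rng)

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        if gate.shape[2:] != skip.shape[2:]:
            if (gate.shape[2] * 2, gate.shape[3] * 2) == skip.shape[2:]:
                gate = nn.upsample2x(gate)
            else:
                raise ValueError(
                    f"gating spatial size {gate.shape[2:]} incompatible with skip {skip.shape[2:]}"
                )
        if skip.shape[1] != self.skip_channels or gate.shape[1] != self.gate_channels:
            raise ValueError(
                f"channel mismatch: got skip={skip.shape[1]}, gate={gate.shape[1]}, "
                f"configured ({self.skip_channels}, {self.gate_channels})"
            )
        attention = self.att(nn.concat_channels(skip, gate).relu()).sigmoid()
        return skip * attention


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class DFLN(nn.Module):
    """U-Net backbone with per-skip SE/AG fusion (see module docstring)."""

    def __init__(self, config: DFLNConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
        d, base = config.depth, config.base_channels
        chans = [base * 2**i for i in range(d)]  # encoder stage widths
        self.encoders = [
            _DoubleConv(1 if i == 0 else chans[i - 1], chans[i], rng) for i in range(d)
        ]
        self.bottleneck = _DoubleConv(chans[-1], base * 2**d, rng)
        self.up_convs = []  # halve channels after nearest upsample
        self.ag_blocks = []
        self.se_blocks = []
        self.decoders = []
        for i in reversed(range(d)):
            up_in = base * 2 ** (i + 1)
            self.up_convs.append(nn.Conv2d(up_in, chans[i], 1, rng))
            self.ag_blocks.append(AGBlock(chans[i], chans[i], rng))
            self.se_blocks.append(
                SEBlock(chans[i], config.se_reduction, rng, pool=config.se_pool)
            )
            self.decoders.append(_DoubleConv(2 * chans[i], chans[i], rng))
        self.head = nn.Conv2d(base, 1, 1, rng)

    def _fuse_skip(self, level: int, skip: Tensor, up: Tensor) -> Tensor:
        ag, se = self.ag_blocks[level], self.se_blocks[level]
        v = self.config.variant
        if v == "serial1":
            return se(ag(skip, up))
        if v == "serial2":
            return ag(se(skip), up)
        if v == "parallel1":
            return ag(skip, up) + se(up)
        return ag(skip, up) + se(skip)  # parallel2

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = nn.maxpool2x(x)
        x = self.bottleneck(x)
        for level, (upc, dec) in enumerate(zip(self.up_convs, self.decoders)):
            x = upc(nn.upsample2x(x))
            skip = skips[-(level + 1)]
            fused = self._fuse_skip(level, skip, x)
            x = dec(nn.concat_channels(fused, x))
        return self.head(x).sigmoid()

    def forward_array(self, images: np.ndarray) -> np.ndarray:
        """Probability maps for a (N, H, W) float batch, no gradient tape."""
        x = Tensor(images[:, None, :, :])
        return self(x).data[:, 0]


def build_model(config: DFLNConfig) -> DFLN:
    return DFLN(config)


def dice_loss(probability_map, truth_mask, eps: float = 1.0):
    """Dice loss 1 - (2*sum(pq) + eps) / (sum(p) + sum(q) + eps).

    Works on Tensors (differentiable) or plain arrays; shapes must match.
    """
    p_arr = probability_map.data if isinstance(probability_map, Tensor) else np.asarray(
        probability_map
    )
    q_arr = truth_mask.data if isinstance(truth_mask, Tensor) else np.asarray(truth_mask)
    if p_arr.shape != q_arr.shape:
        raise ValueError(f"shape mismatch: {p_arr.shape} vs {q_arr.shape}")
    if isinstance(probability_map, Tensor):
        q = truth_mask if isinstance(truth_mask, Tensor) else Tensor(q_arr)
        num = 2.0 * (probability_map * q).sum() + eps
        den = probability_map.sum() + q.sum() + eps
        return 1.0 - num / den
    return 1.0 - (2.0 * (p_arr * q_arr).sum() + eps) / (p_arr.sum() + q_arr.sum() + eps)


def augment_rotate(
    image: np.ndarray,
    mask: np.ndarray,
    max_degrees: float,
    seed: int | np.random.Generator,
    angle_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) by one shared random angle.

    The angle is uniform in [-max_degrees, +max_degrees]; the canvas size is
    preserved. ``angle_override`` forces a specific angle (used in tests).
    """
    if max_degrees < 0:
        raise ValueError("max_degrees must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence([int(seed), 31])
    )
    angle = angle_override if angle_override is not None else float(
        rng.uniform(-max_degrees, max_degrees)
    )
    if angle == 0.0:
        return image.copy(), mask.copy()
    img_r = ndimage.rotate(image.astype(float), angle, reshape=False, order=1, mode="nearest")
    mask_r = ndimage.rotate(mask.astype(np.uint8), angle, reshape=False, order=0) > 0
    return img_r, mask_r


@dataclass
class TrainResult:
    model: "DFLN"
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int


def _to_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return img / 255.0 if img.max() > 1.5 else img


def train(
    model: DFLN,
    train_data: list[tuple[np.ndarray, np.ndarray]],
    config: DFLNConfig | None = None,
    val_data: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> TrainResult:
    """Train with Dice loss + Adam; retains the best-validation weights.

    ``train_data``/``val_data`` are lists of (image, mask) pairs at the
    configured input size.  Rotation augmentation (one shared angle per
    sample per epoch) is applied to training samples only.  Fully seeded.
    """
    config = config or model.config
    if not train_data:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    images = np.stack([_to_float(im) for im, _ in train_data])
    masks = np.stack([np.asarray(m) > 0 for _, m in train_data])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_state, best_val, best_epoch = model.state_arrays(), np.inf, 0
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_im = np.empty((len(idx),) + images.shape[1:])
            batch_mk = np.empty_like(batch_im)
            for j, i in enumerate(idx):
                if config.augment_max_degrees > 0:
                    im, mk = augment_rotate(
                        images[i], masks[i], config.augment_max_degrees, rng
                    )
                else:
                    im, mk = images[i], masks[i]
                batch_im[j], batch_mk[j] = im, mk
            x = Tensor(batch_im[:, None])
            prob = model(x)
            loss = dice_loss(prob, Tensor(batch_mk[:, None]))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        train_losses.append(epoch_loss / n)
        if val_data:
            val_loss = evaluate_loss(model, val_data)
        else:
            val_loss = train_losses[-1]
        val_losses.append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    return TrainResult(model, train_losses, val_losses, best_epoch)


def evaluate_loss(model: DFLN, data: list[tuple[np.ndarray, np.ndarray]]) -> float:
    images = np.stack([_to_float(im) for im, _ in data])
    masks = np.stack([np.asarray(m) > 0 for _, m in data]).astype(float)
    probs = model.forward_array(images)
    return float(dice_loss(probs, masks))


def predict_mask(
    model: DFLN, image: np.ndarray, largest_component_only: bool = True
) -> tuple[SegmentationOutput, ContourPointSet | None]:
    """Segment one image; returns the output and the boundary point set P_iv.

    Images not matching the configured input size are resampled in (and the
    probability map resampled back out) bilinearly.  An all-background
    thresholded map yields a flagged "no object" result, not an exception.
    """
    img = _to_float(image)
    in_h, in_w = model.config.input_size
    orig_shape = img.shape
    if img.shape != (in_h, in_w):
        img = ndimage.zoom(img, (in_h / img.shape[0], in_w / img.shape[1]), order=1)
    prob = model.forward_array(img[None])[0]
    if prob.shape != orig_shape:
        prob = np.clip(
            ndimage.zoom(prob, (orig_shape[0] / prob.shape[0], orig_shape[1] / prob.shape[1]),
                         order=1),
            0.0, 1.0,
        )
    binary = prob >= 0.5
    if largest_component_only and binary.any():
        labels, nlab = ndimage.label(
            binary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        if nlab > 1:
            counts = np.bincount(labels.ravel())[1:]
            binary = labels == (int(np.argmax(counts)) + 1)
    out = SegmentationOutput(
        probability_map=prob,
        binary_mask=binary,
        largest_component_only=largest_component_only,
        no_object=not binary.any(),
    )
    contour = extract_contour_vertices(binary) if binary.any() else None
    return out, contour


def save_checkpoint(model: DFLN, path: Path | str) -> None:
    """Single-file weights (npz) with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    cfg["input_size"] = list(model.config.input_size)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def load_checkpoint(path: Path | str) -> DFLN:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg = json.load(fh)
    cfg["input_size"] = tuple(cfg["input_size"])
    model = DFLN(DFLNConfig(**cfg))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
    return model
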