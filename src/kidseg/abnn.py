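"""Closed-form contour parameterization by a three-layer network (ABNN).

The refinement polygon is a sequence ``D = {(t_i, (x_i, y_i))}``; fitting a
tiny fully-connected network to it yields a *formula* for the contour,

    f(t) = ( h2( sum_i h1(t*w1_i - m_i) * w2_{i,1} - u_1 ),
             h2( sum_i h1(t*w1_i - m_i) * w2_{i,2} - u_2 ) )

with sigmoid hidden activation ``h1`` and, by default, a ReLU output head
``h2 = max(0, x)`` (an exponential head is available as a config option).
The trained weights (w1, m, w2, u) *are* the explainable contour map: the
exported JSON record can be evaluated with no network runtime.

Because the ReLU head is nonnegative while normalized coordinates live in
[-1, 1], targets are affinely mapped into [0.1, 0.9] per axis before
training; the transform is stored alongside the weights and inverted on
output.

Training is full-batch gradient descent with momentum and an adaptive
learning rate: the rate grows (x1.05) after an epoch that lowers the loss
and shrinks (x0.7, with the step rejected) after one that raises it, so
the accepted-loss sequence is non-increasing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from kidseg.aspt import VertexSequence

__all__ = [
    "ABNNParams",
    "ABNNTrainConfig",
    "OutputTransform",
    "init_params",
    "forward",
    "train_abnn",
    "export_map",
    "evaluate_map",
    "sample_contour",
]


@dataclass
class ABNNParams:
    """Weights and thresholds of the three-layer map f(t).

    ``w1`` (s,) input->hidden weights; ``m`` (s,) hidden thresholds;
    ``w2`` (s, 2) hidden->output weights; ``u`` (2,) output thresholds;
    ``head`` is "relu" (default) or "exp".
    """

    w1: np.ndarray
    m: np.ndarray
    w2: np.ndarray
    u: np.ndarray
    head: str = "relu"

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        s = len(self.w1)
        if s < 1:
            raise ValueError("need at least one hidden neuron")
        if self.m.shape != (s,) or self.w2.shape != (s, 2) or self.u.shape != (2,):
            raise ValueError("inconsistent parameter shapes")
        if self.head not in ("relu", "exp"):
            raise ValueError("head must be 'relu' or 'exp'")
        for arr in (self.w1, self.m, self.w2, self.u):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    @property
    def s(self) -> int:
        return len(self.w1)

    def copy(self) -> "ABNNParams":
        return ABNNParams(self.w1.copy(), self.m.copy(), self.w2.copy(), self.u.copy(),
                          self.head)


@dataclass
class ABNNTrainConfig:
    initial_learning_rate: float = 0.4
    momentum: float = 0.9
    max_epochs: int = 1000
    lr_increase_factor: float = 1.05
    lr_decrease_factor: float = 0.7
    adaptive: bool = True  # False = fixed-rate (plain BNN) training
    plateau_rel_tol: float = 1e-10
    plateau_window: int = 25
    n_restarts: int = 1  # best-of-k random initializations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class OutputTransform:
    """Per-axis affine map between data coordinates and the head range [0.1, 0.9]."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    lo: float = 0.1
    hi: float = 0.9

    def to_head(self, coords: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords, dtype=float)
        out[..., 0] = self.lo + (self.hi - self.lo) * (coords[..., 0] - self.x_min) / (
            self.x_max - self.x_min
        )
        out[..., 1] = self.lo + (self.hi - self.lo) * (coords[..., 1] - self.y_min) / (
            self.y_max - self.y_min
        )
        return out

    def from_head(self, outputs: np.ndarray) -> np.ndarray:
        out = np.empty_like(outputs, dtype=float)
        out[..., 0] = self.x_min + (outputs[..., 0] - self.lo) / (self.hi - self.lo) * (
            self.x_max - self.x_min
        )
        out[..., 1] = self.y_min + (outputs[..., 1] - self.lo) / (self.hi - self.lo) * (
            self.y_max - self.y_min
        )
        return out


def init_params(s: int, seed: int, head: str = "relu") -> ABNNParams:
    """Seeded symmetric random initialization with spread sigmoid knees.

    Input weights get random sign and moderate magnitude while the hidden
    thresholds place each sigmoid's transition ("knee") at an evenly spaced
    position in t in [0, 1], so the hidden basis varies across the whole
    parameter range from the start.  Output weights are small and the
    output thresholds slightly negative, keeping the ReLU head active at
    initialization (a dead head has zero gradient and cannot recover).
    """
    if s < 1:
        raise ValueError("s must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    w1 = rng.choice([-1.0, 1.0], size=s) * rng.uniform(12.0, 28.0, size=s)
    knees = (np.arange(s) + 0.5) / s
    return ABNNParams(
        w1=w1,
        m=w1 * knees,
        w2=rng.normal(0.0, 0.1, size=(s, 2)),
        u=np.full(2, -0.5),
        head=head,
    )


def forward(params: ABNNParams, t: float | np.ndarray) -> np.ndarray:
    """Evaluate f(t); scalar t -> shape (2,), array t -> shape (n, 2)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    hidden = 1.0 / (1.0 + np.exp(-(t_arr[:, None] * params.w1 - params.m)))
    z = hidden @ params.w2 - params.u
    out = np.maximum(z, 0.0) if params.head == "relu" else np.exp(z)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def _loss_and_grads(params: ABNNParams, t: np.ndarray, targets: np.ndarray):
    n = len(t)
    hidden = 1.0 / (1.0 + np.exp(-(t[:, None] * params.w1 - params.m)))  # (n, s)
    z = hidden @ params.w2 - params.u  # (n, 2)
    if params.head == "relu":
        out = np.maximum(z, 0.0)
        dout_dz = (z > 0).astype(float)
    else:
        out = np.exp(z)
        dout_dz = out
    err = out - targets
    loss = float(np.mean(err**2))
    dz = (2.0 / err.size) * err * dout_dz  # (n, 2)
    g_w2 = hidden.T @ dz  # (s, 2)
    g_u = -dz.sum(axis=0)  # (2,)
    dhid = dz @ params.w2.T  # (n, s)
    dpre = dhid * hidden * (1.0 - hidden)
    g_w1 = dpre.T @ t  # (s,)
    g_m = -dpre.sum(axis=0)
    return loss, (g_w1, g_m, g_w2, g_u)


@dataclass
class ABNNFit:
    params: ABNNParams
    output_transform: OutputTransform
    loss_history: list[float]
    closure_error: float


def train_abnn(
    sequence: VertexSequence,
    s: int = 20,
    config: ABNNTrainConfig | None = None,
    head: str = "relu",
    closed: bool = True,
) -> ABNNFit:
    """Fit the contour map to a vertex sequence by momentum gradient descent.

    For closed contours the first vertex is duplicated at t = 1 so that
    f(0) ~ f(1); the residual closure error is reported in the fit.  With
    ``config.adaptive`` off, the learning rate stays fixed and every step
    is accepted (the plain fixed-rate trainer used for component ablation).
    ``config.n_restarts`` > 1 trains from that many seeded initializations
    and keeps the fit with the lowest final loss (the landscape of small
    sigmoid networks has poor local minima on sharply indented contours).
    """
    config = config or ABNNTrainConfig()
    seq = sequence.with_closure() if closed else sequence
    if len(seq) < 4:
        raise ValueError("need at least 4 sequence entries")
    t, coords = seq.t, seq.coords
    transform = OutputTransform(
        x_min=float(coords[:, 0].min()), x_max=float(coords[:, 0].max()),
        y_min=float(coords[:, 1].min()), y_max=float(coords[:, 1].max()),
    )
    if transform.x_max == transform.x_min or transform.y_max == transform.y_min:
        raise ValueError("degenerate sequence: zero extent on an axis")
    targets = transform.to_head(coords)

    best: tuple[ABNNParams, list[float]] | None = None
    for restart in range(max(config.n_restarts, 1)):
        init_seed = config.seed if restart == 0 else int(
            np.random.SeedSequence([int(config.seed), 43, restart]).generate_state(1)[0]
            % (2**31)
        )
        params, history = _train_once(t, targets, s, config, head, init_seed)
        if best is None or history[-1] < best[1][-1]:
            best = (params, history)
    params, history = best
    closure = float(np.linalg.norm(forward(params, 0.0) - forward(params, 1.0)))
    return ABNNFit(params=params, output_transform=transform, loss_history=history,
                   closure_error=closure)


def _train_once(
    t: np.ndarray,
    targets: np.ndarray,
    s: int,
    config: ABNNTrainConfig,
    head: str,
    init_seed: int,
) -> tuple[ABNNParams, list[float]]:
    params = init_params(s, init_seed, head=head)
    lr = config.initial_learning_rate
    vel = [np.zeros_like(g) for g in (params.w1, params.m, params.w2, params.u)]
    loss, grads = _loss_and_grads(params, t, targets)
    history = [loss]
    for _ in range(config.max_epochs):
        saved = params.copy()
        saved_vel = [v.copy() for v in vel]
        for v, g in zip(vel, grads):
            v *= config.momentum
            v -= lr * g
        params.w1 += vel[0]
        params.m += vel[1]
        params.w2 += vel[2]
        params.u += vel[3]
        new_loss, new_grads = _loss_and_grads(params, t, targets)
        if not np.isfinite(new_loss):
            raise RuntimeError("non-finite training loss; aborting")
        if config.adaptive and new_loss > loss:
            params, vel = saved, saved_vel  # reject the step
            vel = [np.zeros_like(v) for v in vel]
            lr *= config.lr_decrease_factor
            history.append(loss)
            loss, grads = _loss_and_grads(params, t, targets)
        else:
            if config.adaptive:
                lr *= config.lr_increase_factor
            loss, grads = new_loss, new_grads
            history.append(loss)
        w = config.plateau_window
        if len(history) > w and history[-w - 1] > 0:
            if (history[-w - 1] - history[-1]) / history[-w - 1] < config.plateau_rel_tol:
                break
    return params, history


def export_map(params: ABNNParams, output_transform: OutputTransform) -> dict:
    """Serialize the closed-form map: weights, head, and output transform."""
    return {
        "s": params.s,
        "w1": params.w1.tolist(),
        "m": params.m.tolist(),
        "w2": params.w2.tolist(),
        "u": params.u.tolist(),
        "head": params.head,
        "output_transform": asdict(output_transform),
    }


def evaluate_map(doc: dict, t: float) -> tuple[float, float]:
    """Evaluate an exported map record with plain scalar arithmetic.

    Deliberately implemented without the :func:`forward` code path so the
    exported formula can be cross-checked against the runtime network.
    """
    import math

    s = doc["s"]
    acc = [0.0, 0.0]
    for i in range(s):
        h = 1.0 / (1.0 + math.exp(-(t * doc["w1"][i] - doc["m"][i])))
        acc[0] += h * doc["w2"][i][0]
        acc[1] += h * doc["w2"][i][1]
    out = []
    for j in range(2):
        z = acc[j] - doc["u"][j]
        out.append(max(0.0, z) if doc["head"] == "relu" else math.exp(z))
    tr = doc["output_transform"]
    span = tr["hi"] - tr["lo"]
    x = tr["x_min"] + (out[0] - tr["lo"]) / span * (tr["x_max"] - tr["x_min"])
    y = tr["y_min"] + (out[1] - tr["lo"]) / span * (tr["y_max"] - tr["y_min"])
    return x, y


def sample_contour(
    params: ABNNParams,
    n_samples: int,
    output_transform: OutputTransform,
) -> np.ndarray:
    """Evaluate f at t = j/n_samples, j = 0..n_samples-1: a closed polygon."""
    if n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    t = np.arange(n_samples, dtype=float) / n_samples
    pts = output_transform.from_head(forward(params, t))
    if np.ptp(pts, axis=0).max() < 1e-9:
        warnings.warn("degenerate contour: all sampled points coincide", stacklevel=2)
    return pts


def save_map(doc: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def load_map(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)
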