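"""Three-layer 3-D super-resolution CNN with a residual averaging path.

The network maps an interpolated (blurred) volume to a restored volume:

    f(x) = conv_5^3( relu( conv_3^3( relu( conv_9^3(x) ) ) ) )
    out  = (1 - w) * x + w * f(x)

with kernel edges 9/3/5, channel widths 32/16/1, zero "same" padding so the
output grid equals the input grid, no nonlinearity after the last layer, and
residual weight w = 1/2 by default (the final feature map is averaged with
the interpolated input).  Convolution here is cross-correlation, the usual
CNN convention.

Everything is plain numpy: convolutions are evaluated as GEMMs over sliding
windows, and the backward pass (needed by the training loop) reuses the same
primitive with channel-transposed, spatially flipped kernels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SRCNNSpec", "ModelState", "init_model", "forward", "forward_backward",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class SRCNNSpec:
    """Architecture hyperparameters.

    kernel_edges : odd positive convolution side lengths per layer.
    channels : output channel counts per layer; the last must be 1.
    residual_weight : w in out = (1-w)*input + w*f(input); w in [0, 1].
    init_scale : std of the zero-mean Gaussian weight initialization.
    """

    kernel_edges: tuple = (9, 3, 5)
    channels: tuple = (32, 16, 1)
    residual_weight: float = 0.5
    init_scale: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "kernel_edges", tuple(int(k) for k in self.kernel_edges))
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        if len(self.kernel_edges) != len(self.channels):
            raise ValueError("kernel_edges and channels must have equal length")
        if any(k < 1 or k % 2 == 0 for k in self.kernel_edges):
            raise ValueError(f"kernel edges must be odd and positive, got {self.kernel_edges}")
        if self.channels[-1] != 1:
            raise ValueError("last layer must have exactly 1 output channel")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel counts must be positive")
        if not 0.0 <= self.residual_weight <= 1.0:
            raise ValueError(f"residual_weight {self.residual_weight} outside [0, 1]")

    def layer_shapes(self):
        """Weight shapes (c_out, c_in, k, k, k) for each layer."""
        c_in = 1
        shapes = []
        for k, c_out in zip(self.kernel_edges, self.channels):
            shapes.append((c_out, c_in, k, k, k))
            c_in = c_out
        return shapes


@dataclasses.dataclass
class ModelState:
    """Trainable weights/biases for the three layers plus bookkeeping."""

    weights: list
    biases: list
    spec: SRCNNSpec
    iteration_count: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            spec=self.spec,
            iteration_count=self.iteration_count,
        )

    def check_finite(self):
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise FloatingPointError(f"non-finite parameters in layer {i + 1}")


def init_model(spec: SRCNNSpec) -> ModelState:
    """Gaussian(0, init_scale) weights, zero biases; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    weights, biases = [], []
    for shape in spec.layer_shapes():
        weights.append(rng.normal(0.0, spec.init_scale, size=shape))
        biases.append(np.zeros(shape[0], dtype=np.float64))
    return ModelState(weights=weights, biases=biases, spec=spec)


def _conv3d_same(x: np.ndarray, weights: np.ndarray, bias: np.ndarray = None):
    """'Same'-size 3-D cross-correlation, zero padded.

    x : (c_in, X, Y, Z); weights : (c_out, c_in, k, k, k).
    Returns (c_out, X, Y, Z).  Evaluated as one GEMM over sliding windows.
    """
    c_out, c_in, k = weights.shape[0], weights.shape[1], weights.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    out = np.tensordot(weights, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    if bias is not None:
        out += bias[:, np.newaxis, np.newaxis, np.newaxis]
    return out


def _conv3d_weight_grad(x: np.ndarray, delta: np.ndarray, k: int):
    """Gradient of a same-padded correlation w.r.t. its kernel.

    x : (c_in, X, Y, Z) layer input; delta : (c_out, X, Y, Z) output grad.
    Returns (c_out, c_in, k, k, k).
    """
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    return np.tensordot(delta, win, axes=([1, 2, 3], [1, 2, 3]))


def _conv3d_input_grad(delta: np.ndarray, weights: np.ndarray):
    """Gradient w.r.t. the layer input: correlate delta with flipped,
    channel-transposed kernels (exact adjoint of same-size zero padding
    with odd kernels)."""
    w_t = np.swapaxes(weights, 0, 1)[:, :, ::-1, ::-1, ::-1]
    return _conv3d_same(delta, np.ascontiguousarray(w_t))


def _forward_cached(model: ModelState, x: np.ndarray):
    """Run f(x) keeping the intermediates needed for backprop."""
    a = x[np.newaxis]  # (1, X, Y, Z)
    cache = []
    n_layers = len(model.weights)
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = _conv3d_same(a, w, b)
        if i < n_layers - 1:
            mask = z > 0
            cache.append((a, mask))
            a = np.where(mask, z, 0.0)
        else:
            cache.append((a, None))
            a = z
    return a[0], cache


def forward(model: ModelState, interpolated: np.ndarray) -> np.ndarray:
    """out = (1 - w) * interpolated + w * f(interpolated); same grid size."""
    x = np.asarray(interpolated, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got {x.ndim}-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if min(x.shape) < max(model.spec.kernel_edges):
        # Same-size zero padding keeps the convolution well-defined, but most
        # of the receptive field then hangs over the border.
        warnings.warn(
            f"input dims {x.shape} smaller than largest kernel edge "
            f"{max(model.spec.kernel_edges)}; output is dominated by padding",
            stacklevel=2,
        )
    w = model.spec.residual_weight
    f_x, _ = _forward_cached(model, x)
    return (1.0 - w) * x + w * f_x


def forward_backward(model: ModelState, interpolated: np.ndarray, target: np.ndarray):
    """One MSE training evaluation: returns (loss, grads_w, grads_b, output).

    loss = mean((out - target)^2) over voxels, with
    out = (1 - w) * x + w * f(x); gradients are exact.
    """
    x = np.asarray(interpolated, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if x.shape != t.shape:
        raise ValueError(f"source {x.shape} and target {t.shape} shapes differ")
    w_res = model.spec.residual_weight
    f_x, cache = _forward_cached(model, x)
    out = (1.0 - w_res) * x + w_res * f_x
    diff = out - t
    loss = float(np.mean(diff**2))

    delta = (2.0 / diff.size) * w_res * diff  # dL/df
    delta = delta[np.newaxis]
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    for i in range(len(model.weights) - 1, -1, -1):
        a_in, _ = cache[i]
        grads_w[i] = _conv3d_weight_grad(a_in, delta, model.spec.kernel_edges[i])
        grads_b[i] = delta.sum(axis=(1, 2, 3))
        if i > 0:
            delta = _conv3d_input_grad(delta, model.weights[i])
            delta = delta * cache[i - 1][1]  # ReLU gate of the previous layer
    return loss, grads_w, grads_b, out


def save_checkpoint(model: ModelState, path) -> None:
    """Single-file checkpoint: .npz with weights, biases and embedded spec."""
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    spec_json = json.dumps(dataclasses.asdict(model.spec), sort_keys=True)
    arrays["spec"] = np.frombuffer(spec_json.encode(), dtype=np.uint8)
    arrays["iteration_count"] = np.array(model.iteration_count)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as npz:
        spec_dict = json.loads(bytes(npz["spec"].tobytes()).decode())
        spec_dict["kernel_edges"] = tuple(spec_dict["kernel_edges"])
        spec_dict["channels"] = tuple(spec_dict["channels"])
        spec = SRCNNSpec(**spec_dict)
        n = len(spec.channels)
        weights = [npz[f"w{i}"] for i in range(n)]
        biases = [npz[f"b{i}"] for i in range(n)]
        it = int(npz["iteration_count"])
    return ModelState(weights=weights, biases=biases, spec=spec, iteration_count=it)
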