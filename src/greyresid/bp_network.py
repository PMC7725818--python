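"""Three-layer feedforward network trained by error back-propagation.

The network is deliberately minimal — one hidden layer, online (per-sample)
gradient descent on the half squared error ``E = 1/2 sum (d_k - o_k)^2`` —
because that is the role it plays here: a small residual-sequence predictor
whose initial weights can be handed over from an evolutionary optimizer via
a flat-vector encoding.

Weight layout: ``V`` is input-to-hidden, shape ``(n_hidden, n_in + 1)``;
``W`` is hidden-to-output, shape ``(n_out, n_hidden + 1)``.  Column 0 of
each matrix is the bias (a fixed unit activation is prepended to the layer
input).  The flat encoding is ``V`` row-major followed by ``W`` row-major,
biases first in each row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, List, Sequence, Tuple

import json
import numpy as np

__all__ = [
    "NetworkConfig",
    "WeightMatrices",
    "TrainingSample",
    "init_weights",
    "forward",
    "forward_batch",
    "network_error",
    "backprop_step",
    "train",
    "encode",
    "decode",
    "encoding_length",
]

SCHEMA_VERSION = 1

# activation name -> (function of pre-activation, derivative from OUTPUT value)
_ACTIVATIONS: dict[str, Tuple[Callable, Callable]] = {
    "logsig": (lambda h: 1.0 / (1.0 + np.exp(-h)), lambda y: y * (1.0 - y)),
    "tansig": (np.tanh, lambda y: 1.0 - y**2),
    "linear": (lambda h: h, lambda y: np.ones_like(y)),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference configuration for residual forecasting:
    3 lagged residuals in, 8 hidden units, 1 output; tansig hidden layer and
    logsig output; learning rate 0.005, target mean per-sample error 1e-3,
    at most 50 000 epochs.
    """

    n_in: int = 3
    n_hidden: int = 8
    n_out: int = 1
    eta: float = 0.005
    e_min: float = 1e-3
    max_epochs: int = 50_000
    hidden_activation: str = "tansig"
    output_activation: str = "logsig"
    init_half_width: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be >= 1")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("learning rate eta must be in (0, 1)")
        if self.e_min <= 0:
            raise ValueError("e_min must be > 0")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")


@dataclass
class WeightMatrices:
    """Input-to-hidden (V) and hidden-to-output (W) weights, bias column first."""

    V: np.ndarray
    W: np.ndarray

    def copy(self) -> "WeightMatrices":
        return WeightMatrices(V=self.V.copy(), W=self.W.copy())

    def to_json(self, config: NetworkConfig) -> str:
        return json.dumps(
            {
                "config": asdict(config),
                "V": self.V.tolist(),
                "W": self.W.tolist(),
                "encoding": "V row-major then W row-major, bias column first",
                "schema_version": SCHEMA_VERSION,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> Tuple["WeightMatrices", NetworkConfig]:
        obj = json.loads(payload)
        cfg = NetworkConfig(**obj["config"])
        return cls(V=np.array(obj["V"]), W=np.array(obj["W"])), cfg


@dataclass(frozen=True)
class TrainingSample:
    """One supervised pair: input vector ``x`` and expected output ``d``."""

    x: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.d))):
            raise ValueError("training sample contains non-finite values")


def encoding_length(config: NetworkConfig) -> int:
    """Length of the flat weight vector: (n_in+1)*n_hidden + (n_hidden+1)*n_out."""
    return (config.n_in + 1) * config.n_hidden + (config.n_hidden + 1) * config.n_out


def init_weights(config: NetworkConfig) -> WeightMatrices:
    """Uniform random weights in [-w0, +w0]; identical seed, identical weights."""
    rng = np.random.default_rng(config.seed)
    w0 = config.init_half_width
    V = rng.uniform(-w0, w0, size=(config.n_hidden, config.n_in + 1))
    W = rng.uniform(-w0, w0, size=(config.n_out, config.n_hidden + 1))
    return WeightMatrices(V=V, W=W)


def _check_dims(weights: WeightMatrices, config: NetworkConfig) -> None:
    if weights.V.shape != (config.n_hidden, config.n_in + 1) or weights.W.shape != (
        config.n_out,
        config.n_hidden + 1,
    ):
        raise ValueError(
            f"weight shapes {weights.V.shape}, {weights.W.shape} inconsistent with config"
        )


def forward(
    weights: WeightMatrices, x: Sequence[float], config: NetworkConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward pass for one input vector; returns (hidden output y, output o)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (config.n_in,):
        raise ValueError(f"input has shape {x.shape}, expected ({config.n_in},)")
    _check_dims(weights, config)
    f_hid = _ACTIVATIONS[config.hidden_activation][0]
    f_out = _ACTIVATIONS[config.output_activation][0]
    y = f_hid(weights.V[:, 0] + weights.V[:, 1:] @ x)
    o = f_out(weights.W[:, 0] + weights.W[:, 1:] @ y)
    return y, o


def forward_batch(
    weights: WeightMatrices, X: np.ndarray, config: NetworkConfig
) -> np.ndarray:
    """Outputs for a whole (n_samples, n_in) matrix at once; returns (n_samples, n_out)."""
    X = np.asarray(X, dtype=float)
    f_hid = _ACTIVATIONS[config.hidden_activation][0]
    f_out = _ACTIVATIONS[config.output_activation][0]
    Y = f_hid(X @ weights.V[:, 1:].T + weights.V[:, 0])
    return f_out(Y @ weights.W[:, 1:].T + weights.W[:, 0])


def network_error(o: Sequence[float], d: Sequence[float]) -> float:
    """Half squared error ``E = 1/2 sum_k (d_k - o_k)^2``."""
    o = np.asarray(o, dtype=float)
    d = np.asarray(d, dtype=float)
    if o.shape != d.shape:
        raise ValueError("output and expected vectors differ in length")
    return 0.5 * float(np.sum((d - o) ** 2))


def backprop_step(
    weights: WeightMatrices, sample: TrainingSample, config: NetworkConfig
) -> WeightMatrices:
    """One online gradient-descent update on one sample (pure: returns new weights).

    Output deltas ``delta_o = (d - o) f'(o)``, hidden deltas
    ``delta_y = (W^T delta_o) f'(y)``, updates ``eta * delta * activation``
    with the bias treated as a fixed unit input.
    """
    _check_dims(weights, config)
    new = weights.copy()
    _inplace_update(new.V, new.W, sample.x, sample.d, config)
    if not (np.all(np.isfinite(new.V)) and np.all(np.isfinite(new.W))):
        raise FloatingPointError("divergence: non-finite weights after update")
    return new


def _inplace_update(
    V: np.ndarray, W: np.ndarray, x: np.ndarray, d: np.ndarray, config: NetworkConfig
) -> float:
    """Forward + backward + in-place update for one sample; returns pre-update E."""
    f_hid, df_hid = _ACTIVATIONS[config.hidden_activation]
    f_out, df_out = _ACTIVATIONS[config.output_activation]
    y = f_hid(V[:, 0] + V[:, 1:] @ x)
    o = f_out(W[:, 0] + W[:, 1:] @ y)
    err = d - o
    delta_o = err * df_out(o)
    delta_y = (W[:, 1:].T @ delta_o) * df_hid(y)
    eta = config.eta
    W[:, 0] += eta * delta_o
    W[:, 1:] += eta * np.outer(delta_o, y)
    V[:, 0] += eta * delta_y
    V[:, 1:] += eta * np.outer(delta_y, x)
    return 0.5 * float(err @ err)


def train(
    weights: WeightMatrices,
    samples: Sequence[TrainingSample],
    config: NetworkConfig,
) -> Tuple[WeightMatrices, List[float]]:
    """Online gradient descent over epochs; returns (trained weights, error history).

    Each epoch visits the samples in their given, fixed order and applies a
    per-sample update.  The history records the mean per-sample error E of
    each epoch (measured as the samples are visited).  Training stops when
    that mean drops to ``e_min`` or after ``max_epochs`` epochs.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    new = weights.copy()
    V, W = new.V, new.W
    xs = [s.x for s in samples]
    ds = [s.d for s in samples]
    history: List[float] = []
    for _ in range(config.max_epochs):
        total = 0.0
        for x, d in zip(xs, ds):
            total += _inplace_update(V, W, x, d, config)
        mean_e = total / len(samples)
        if not np.isfinite(mean_e):
            raise FloatingPointError("divergence: non-finite training error")
        history.append(mean_e)
        if mean_e <= config.e_min:
            break
    return new, history


def encode(weights: WeightMatrices) -> np.ndarray:
    """Flatten to one vector: V row-major then W row-major, biases first."""
    return np.concatenate([weights.V.ravel(), weights.W.ravel()])


def decode(vector: Sequence[float], config: NetworkConfig) -> WeightMatrices:
    """Inverse of :func:`encode`; raises on wrong vector length."""
    vec = np.asarray(vector, dtype=float)
    n_v = (config.n_in + 1) * config.n_hidden
    n_w = (config.n_hidden + 1) * config.n_out
    if vec.shape != (n_v + n_w,):
        raise ValueError(
            f"flat vector has length {vec.size}, expected {n_v + n_w} for this config"
        )
    V = vec[:n_v].reshape(config.n_hidden, config.n_in + 1).copy()
    W = vec[n_v:].reshape(config.n_out, config.n_hidden + 1).copy()
    return WeightMatrices(V=V, W=W)
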