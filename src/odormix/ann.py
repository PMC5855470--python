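"""Bespoke feedforward network for e-nose regression.

Layer i applies ``y_i = f_i(w_i [1; y_{i-1}])`` where ``w_i`` is an
``n_i x (n_{i-1}+1)`` matrix whose first column holds the thresholds
(biases). Hidden layers use tanh or Leaky ReLU (leak a, default 0.03); the
output layer is linear, as regression requires. Training minimises the mean
squared error by full-batch gradient descent with sign-based per-weight
adaptive steps (iRprop-): a weight's step grows by ``step_up`` while its
gradient keeps its sign and shrinks by ``step_down`` on a sign flip, which
leaves only two controlling factors plus bounds.

Weights can be initialised randomly (Glorot uniform) or by layer-wise
stacked-denoising-autoencoder (SDAE) pretraining: each hidden layer is
trained, in sequence, to reconstruct its clean input from a corrupted copy
through a mirror decoder, the encoder weights are kept, and the clean
encodings feed the next layer. The output layer is always randomly
initialised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, TrainingError
from .preprocessing import (
    NormalizerParams,
    OutputScalerParams,
    apply_normalizer,
    identity_normalizer,
    identity_output_scaler,
    scale_output,
)

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class ActivationKind:
    kind: str  # {"linear", "tanh", "leaky_relu"}
    leak: float = 0.03

    def __post_init__(self):
        if self.kind not in ("linear", "tanh", "leaky_relu"):
            raise ConfigError(f"unknown activation kind: {self.kind!r}")
        if self.kind == "leaky_relu" and not 0.0 < self.leak < 1.0:
            raise ConfigError("leaky_relu leak must be in (0, 1)")

    @property
    def label(self) -> str:
        return self.kind if self.kind != "leaky_relu" else f"leaky_relu:{self.leak:g}"


TANH = ActivationKind("tanh")
LEAKY_RELU = ActivationKind("leaky_relu", 0.03)
LINEAR = ActivationKind("linear")


def activation_eval(kind: ActivationKind, z):
    """Return (value, derivative), elementwise.

    Leaky ReLU uses the right derivative (1) at z = 0.
    """
    z = np.asarray(z, dtype=float)
    if kind.kind == "linear":
        return z, np.ones_like(z)
    if kind.kind == "tanh":
        t = np.tanh(z)
        return t, 1.0 - t * t
    pos = z >= 0
    value = np.where(pos, z, kind.leak * z)
    deriv = np.where(pos, 1.0, kind.leak)
    return value, deriv


@dataclass(frozen=True)
class ANNStructure:
    """Layer widths 8 -> hidden... -> 1 plus the hidden activation."""

    layer_sizes: tuple
    hidden_activation: ActivationKind = TANH

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ConfigError("structure needs at least input and output layers")
        if sizes[0] != 8 or sizes[-1] != 1:
            raise ConfigError("structure must map 8 sensor channels to 1 output")
        if any(s < 1 for s in sizes):
            raise ConfigError("all retained layer sizes must be >= 1")

    @classmethod
    def from_string(cls, text: str, hidden_activation: ActivationKind = TANH) -> "ANNStructure":
        """Parse '8-3-0-1' style notation; a zero width means the layer is absent."""
        try:
            raw = [int(p) for p in text.strip().split("-")]
        except ValueError as exc:
            raise ConfigError(f"cannot parse structure {text!r}") from exc
        sizes = [raw[0]] + [s for s in raw[1:-1] if s > 0] + [raw[-1]]
        return cls(tuple(sizes), hidden_activation)

    @property
    def name(self) -> str:
        return "-".join(str(s) for s in self.layer_sizes)

    @property
    def n_weights(self) -> int:
        return sum(
            self.layer_sizes[i] * (self.layer_sizes[i - 1] + 1)
            for i in range(1, len(self.layer_sizes))
        )

    def activations(self) -> list:
        """Per-trainable-layer activation kinds (hidden..., linear output)."""
        n_layers = len(self.layer_sizes) - 1
        return [self.hidden_activation] * (n_layers - 1) + [LINEAR]


#: the architecture grid explored during structure selection
STRUCTURE_GRID = (
    "8-10-0-1",
    "8-15-0-1",
    "8-2-0-1",
    "8-3-0-1",
    "8-3-2-1",
    "8-3-3-1",
    "8-5-0-1",
    "8-5-2-1",
    "8-5-3-1",
    "8-5-4-1",
    "8-5-5-1",
)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 300
    initial_step: float = 0.05
    step_up: float = 1.2
    step_down: float = 0.5
    step_min: float = 1e-9
    step_max: float = 1.0
    tol: float = 0.0  # stop early once the loss falls below this
    batch: str = "full"
    seed: int = 0

    def __post_init__(self):
        if self.initial_step <= 0 or self.step_min <= 0 or self.step_max <= 0:
            raise ConfigError("step sizes must be positive")
        if not self.step_up > 1.0 > self.step_down > 0.0:
            raise ConfigError("need step_up > 1 > step_down > 0")
        if self.batch != "full":
            raise ConfigError("only full-batch training is supported")


@dataclass(frozen=True)
class DAEConfig:
    corruption_kind: str = "gaussian"  # {"gaussian", "masking"}
    corruption_sd: float = 0.1
    masking_fraction: float = 0.2
    epochs: int = 300
    initial_step: float = 0.05
    step_up: float = 1.2
    step_down: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.corruption_kind not in ("gaussian", "masking"):
            raise ConfigError(f"unknown corruption kind: {self.corruption_kind!r}")
        if self.corruption_sd < 0:
            raise ConfigError("corruption_sd must be >= 0")
        if not 0.0 <= self.masking_fraction < 1.0:
            raise ConfigError("masking_fraction must be in [0, 1)")


@dataclass
class ANNModel:
    structure: ANNStructure
    weights: list  # per-layer (n_i, n_{i-1}+1) arrays, first column = thresholds
    normalizer: NormalizerParams
    output_scaler: OutputScalerParams
    training_log: list = field(default_factory=list)

    def __post_init__(self):
        expected = _weight_shapes(self.structure.layer_sizes)
        got = [w.shape for w in self.weights]
        if got != expected:
            raise DataError(f"weight shapes {got} do not match structure {expected}")
        if not all(np.isfinite(w).all() for w in self.weights):
            raise DataError("non-finite weights")

    # -- evaluation ---------------------------------------------------------
    def forward_pass(self, u, raw: bool = True):
        """Return (prediction in original units, per-layer outputs).

        ``raw`` means ``u`` is an instrument-unit sensor vector and the
        stored normalizer is applied first; otherwise ``u`` is already
        normalized.
        """
        x = u.as_array() if hasattr(u, "as_array") else np.asarray(u, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if raw:
            X = apply_normalizer(self.normalizer, X)
        acts, _ = _forward(self.weights, self.structure.activations(), X)
        y_scaled = acts[-1][:, 0]
        pred = scale_output(self.output_scaler, y_scaled, "inverse")
        if single:
            return float(np.asarray(pred).ravel()[0]), [a[0] for a in acts]
        return np.asarray(pred), acts

    def predict(self, u, raw: bool = True):
        return self.forward_pass(u, raw=raw)[0]

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "structure": {
                "layer_sizes": list(self.structure.layer_sizes),
                "activation": self.structure.hidden_activation.kind,
                "leak": self.structure.hidden_activation.leak,
            },
            "weights": [w.tolist() for w in self.weights],
            "normalizer": {
                "means": list(self.normalizer.means),
                "scales": list(self.normalizer.scales),
                "fitted_on": self.normalizer.fitted_on,
                "degenerate": list(self.normalizer.degenerate),
            },
            "output_scaler": {
                "mean": self.output_scaler.mean,
                "scale": self.output_scaler.scale,
                "target_name": self.output_scaler.target_name,
            },
            "training_log": list(self.training_log),
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        doc = json.loads(text)
        st = doc["structure"]
        activation = ActivationKind(st["activation"], st.get("leak", 0.03)) \
            if st["activation"] != "linear" else LINEAR
        structure = ANNStructure(tuple(st["layer_sizes"]), activation)
        norm = doc["normalizer"]
        scal = doc["output_scaler"]
        return cls(
            structure=structure,
            weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
            normalizer=NormalizerParams(
                means=tuple(norm["means"]),
                scales=tuple(norm["scales"]),
                fitted_on=int(norm["fitted_on"]),
                degenerate=tuple(norm.get("degenerate", ())),
            ),
            output_scaler=OutputScalerParams(
                mean=float(scal["mean"]),
                scale=float(scal["scale"]),
                target_name=scal["target_name"],
            ),
            training_log=list(doc.get("training_log", [])),
        )

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ANNModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# low-level machinery (shared by supervised training and DAE pretraining)
# ---------------------------------------------------------------------------

def _weight_shapes(layer_sizes) -> list:
    return [
        (layer_sizes[i], layer_sizes[i - 1] + 1) for i in range(1, len(layer_sizes))
    ]


def glorot_init(layer_sizes, rng: np.random.Generator) -> list:
    """Uniform +-sqrt(6/(fan_in+fan_out)) weights, zero thresholds."""
    weights = []
    for n_out, n_in_p1 in _weight_shapes(layer_sizes):
        n_in = n_in_p1 - 1
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = np.zeros((n_out, n_in_p1))
        w[:, 1:] = rng.uniform(-limit, limit, size=(n_out, n_in))
        weights.append(w)
    return weights


def _forward(weights, activations, X):
    """Return (per-layer outputs [X, a_1, ..., a_L], per-layer derivative caches)."""
    acts = [X]
    derivs = []
    a = X
    for w, act in zip(weights, activations):
        z = a @ w[:, 1:].T + w[:, 0]
        a, d = activation_eval(act, z)
        acts.append(a)
        derivs.append(d)
    return acts, derivs


def loss_and_gradients(weights, activations, X, Y):
    """Mean-squared-error loss and its per-layer weight gradients.

    ``Y`` may be (n,) or (n, m); the loss is averaged over samples and, for
    multi-output reconstruction targets, over output dimensions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] == 0:
        raise DataError("empty batch")
    n, m = Y.shape
    acts, derivs = _forward(weights, activations, X)
    err = acts[-1] - Y
    mse = float(np.mean(err * err) if m == 1 else np.mean(np.sum(err * err, axis=1)))
    delta = (2.0 / n) * err  # d mse / d output
    grads = [None] * len(weights)
    for i in range(len(weights) - 1, -1, -1):
        d = delta * derivs[i]
        grads[i] = np.hstack([d.sum(axis=0)[:, None], d.T @ acts[i]])
        if i > 0:
            delta = d @ weights[i][:, 1:]
    return mse, grads


def rprop_minimize(weights, activations, X, Y, config: TrainConfig):
    """iRprop- full-batch minimisation; returns (best_weights, loss_log)."""
    weights = [w.copy() for w in weights]
    steps = [np.full_like(w, config.initial_step) for w in weights]
    prev_grad = [np.zeros_like(w) for w in weights]
    best_loss = np.inf
    best_weights = [w.copy() for w in weights]
    log = []
    for epoch in range(config.max_epochs):
        loss, grads = loss_and_gradients(weights, activations, X, Y)
        if not np.isfinite(loss):
            raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
        log.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_weights = [w.copy() for w in weights]
        if best_loss <= config.tol:
            break
        for w, g, s, pg in zip(weights, grads, steps, prev_grad):
            same = pg * g > 0
            flip = pg * g < 0
            s[same] = np.minimum(s[same] * config.step_up, config.step_max)
            s[flip] = np.maximum(s[flip] * config.step_down, config.step_min)
            g[flip] = 0.0  # iRprop-: skip the update after a sign flip
            w -= np.sign(g) * s
            pg[...] = g
    return best_weights, log


def train_network(
    structure: ANNStructure,
    X_nn,
    y_scaled,
    config: TrainConfig | None = None,
    init_weights=None,
    normalizer: NormalizerParams | None = None,
    output_scaler: OutputScalerParams | None = None,
) -> ANNModel:
    """Fit a network on normalized inputs / scaled targets.

    ``init_weights`` may be a pretrained weight list; otherwise Glorot
    initialisation seeded by ``config.seed`` is used. The returned model
    carries the provided normalizer/scaler (identity maps by default) so
    that ``predict`` works in original units.
    """
    if config is None:
        config = TrainConfig()
    X_nn = np.asarray(X_nn, dtype=float)
    y_scaled = np.asarray(y_scaled, dtype=float)
    if X_nn.shape[0] == 0:
        raise DataError("empty training set")
    if init_weights is None:
        rng = np.random.default_rng(config.seed)
        init_weights = glorot_init(structure.layer_sizes, rng)
    weights, log = rprop_minimize(
        init_weights, structure.activations(), X_nn, y_scaled, config
    )
    return ANNModel(
        structure=structure,
        weights=weights,
        normalizer=normalizer or identity_normalizer(structure.layer_sizes[0]),
        output_scaler=output_scaler or identity_output_scaler(),
        training_log=log,
    )


def pretrain_sdae(
    structure: ANNStructure,
    X_nn,
    dae_config: DAEConfig | None = None,
) -> list:
    """Layer-wise denoising-autoencoder initial weights for ``structure``.

    Each hidden layer is trained to reconstruct its clean input from a
    corrupted copy through a mirror decoder; encoder weights are kept, the
    clean encodings feed the next layer. The output layer stays random. The
    corrupted copy is drawn once per layer so the full-batch adaptive-step
    optimiser sees a deterministic objective.
    """
    if dae_config is None:
        dae_config = DAEConfig()
    X = np.asarray(X_nn, dtype=float)
    sizes = structure.layer_sizes
    rng = np.random.default_rng(dae_config.seed)
    hidden_act = structure.hidden_activation
    train_cfg = TrainConfig(
        max_epochs=dae_config.epochs,
        initial_step=dae_config.initial_step,
        step_up=dae_config.step_up,
        step_down=dae_config.step_down,
        seed=dae_config.seed,
    )
    weights = []
    current = X
    for layer in range(1, len(sizes) - 1):
        d_in, h = sizes[layer - 1], sizes[layer]
        if dae_config.corruption_kind == "gaussian":
            corrupted = current + rng.normal(0.0, dae_config.corruption_sd, current.shape)
        else:
            mask = rng.random(current.shape) < dae_config.masking_fraction
            corrupted = np.where(mask, 0.0, current)
        dae_weights = glorot_init((d_in, h, d_in), rng)
        dae_weights, _ = rprop_minimize(
            dae_weights, [hidden_act, LINEAR], corrupted, current, train_cfg
        )
        encoder = dae_weights[0]
        weights.append(encoder)
        current, _ = activation_eval(hidden_act, current @ encoder[:, 1:].T + encoder[:, 0])
    # output layer: random
    weights.extend(glorot_init(sizes[-2:], rng))
    return weights


def dae_reconstruction_losses(
    structure: ANNStructure, X_nn, dae_config: DAEConfig | None = None
) -> list:
    """Per-hidden-layer (initial, final) reconstruction MSE during pretraining."""
    if dae_config is None:
        dae_config = DAEConfig()
    X = np.asarray(X_nn, dtype=float)
    sizes = structure.layer_sizes
    rng = np.random.default_rng(dae_config.seed)
    hidden_act = structure.hidden_activation
    train_cfg = TrainConfig(
        max_epochs=dae_config.epochs,
        initial_step=dae_config.initial_step,
        step_up=dae_config.step_up,
        step_down=dae_config.step_down,
        seed=dae_config.seed,
    )
    out = []
    current = X
    for layer in range(1, len(sizes) - 1):
        d_in, h = sizes[layer - 1], sizes[layer]
        if dae_config.corruption_kind == "gaussian":
            corrupted = current + rng.normal(0.0, dae_config.corruption_sd, current.shape)
        else:
            mask = rng.random(current.shape) < dae_config.masking_fraction
            corrupted = np.where(mask, 0.0, current)
        dae_weights = glorot_init((d_in, h, d_in), rng)
        initial_loss, _ = loss_and_gradients(
            dae_weights, [hidden_act, LINEAR], corrupted, current
        )
        dae_weights, log = rprop_minimize(
            dae_weights, [hidden_act, LINEAR], corrupted, current, train_cfg
        )
        final_loss = min(log)
        out.append((initial_loss, final_loss))
        encoder = dae_weights[0]
        current, _ = activation_eval(hidden_act, current @ encoder[:, 1:].T + encoder[:, 0])
    return out
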