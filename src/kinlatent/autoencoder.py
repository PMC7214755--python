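"""Shallow nonlinear autoencoder trained by full-batch gradient descent.

The network has three hidden layers, the middle one being the low-dimensional
bottleneck::

    layer1 = act(X  w1 + b1)        (n_channels -> h,  nonlinear)
    layer2 =     layer1 w2 + b2     (h -> k,           linear bottleneck)
    layer3 = act(layer2 w3 + b3)    (k -> h,           nonlinear)
    Y      =     layer3 w4 + b4     (h -> n_channels,  linear output)

following Kramer's classic autoassociative design: nonlinear activation on
the mapping layers, linear activation on the bottleneck and the output.  The
bottleneck columns are the *coding units* (CUs), the nonlinear analogue of
principal-component scores.  Training minimizes mean squared reconstruction
error over the full batch with the ADAM optimizer; no regularization.

Everything here is explicit NumPy — forward pass, backpropagation, and the
optimizer — so that gradients can be verified against finite differences and
runs are bit-reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .metrics import LatentRepresentation, vaf
from .preprocess import kfold_indices


class AutoencoderError(ValueError):
    """Raised on invalid shapes, parameters, or configurations."""


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# activations

def _tanh(a):
    return np.tanh(a)


def _tanh_grad(a):
    return 1.0 - np.tanh(a) ** 2


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


def _sigmoid_grad(a):
    s = _sigmoid(a)
    return s * (1.0 - s)


def _relu(a):
    return np.maximum(a, 0.0)


def _relu_grad(a):
    return (a > 0.0).astype(float)


ACTIVATIONS = {
    "tanh": (_tanh, _tanh_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "sig": (_sigmoid, _sigmoid_grad),
    "relu": (_relu, _relu_grad),
    # identity turns the network into a linear autoencoder, whose optimal
    # k-dimensional reconstruction coincides with the PCA subspace — kept as
    # a diagnostic limit, not a recommended operating mode
    "identity": (lambda a: a, lambda a: np.ones_like(a)),
}

_PARAM_KEYS = ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")


@dataclass
class AutoencoderModel:
    """Weights and biases of the 4-layer autoencoder.

    Shapes chain ``n_channels -> h -> k -> h -> n_channels``; ``k`` must be a
    genuine bottleneck (``k < n_channels``).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray
    w4: np.ndarray
    b4: np.ndarray
    hidden_size: int
    bottleneck_size: int
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise AutoencoderError(
                f"unknown activation {self.activation!r}; choose from "
                f"{sorted(set(ACTIVATIONS) - {'sig'})}"
            )
        c, h, k = self.n_channels, self.hidden_size, self.bottleneck_size
        expected = {
            "w1": (c, h), "b1": (h,), "w2": (h, k), "b2": (k,),
            "w3": (k, h), "b3": (h,), "w4": (h, c), "b4": (c,),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise AutoencoderError(f"{name} has shape {got}, expected {shape}")
        if k >= c:
            raise AutoencoderError(
                f"bottleneck_size={k} must be smaller than n_channels={c}"
            )

    @property
    def n_channels(self) -> int:
        return self.w1.shape[0]

    def params(self) -> dict:
        return {k: getattr(self, k) for k in _PARAM_KEYS}

    def with_params(self, params: dict) -> "AutoencoderModel":
        return replace(self, **{k: params[k] for k in _PARAM_KEYS})

    def copy(self) -> "AutoencoderModel":
        return self.with_params({k: getattr(self, k).copy() for k in _PARAM_KEYS})

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k).tolist() for k in _PARAM_KEYS}
        payload.update(
            hidden_size=self.hidden_size,
            bottleneck_size=self.bottleneck_size,
            activation=self.activation,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AutoencoderModel":
        with open(path) as fh:
            d = json.load(fh)
        arrays = {k: np.asarray(d[k], dtype=float) for k in _PARAM_KEYS}
        return cls(
            **arrays,
            hidden_size=int(d["hidden_size"]),
            bottleneck_size=int(d["bottleneck_size"]),
            activation=d["activation"],
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Full-batch training hyperparameters.

    Defaults follow the tuned operating point for this architecture on
    kinematic data: learning rate 0.01 for 10,000 ADAM steps with tanh
    activation and no regularization.
    """

    learning_rate: float = 0.01
    steps: int = 10_000
    activation: str = "tanh"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise AutoencoderError("learning_rate must be > 0")
        if self.steps < 0:
            raise AutoencoderError("steps must be >= 0")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise AutoencoderError("ADAM betas must lie in (0, 1)")
        if self.adam_eps <= 0:
            raise AutoencoderError("adam_eps must be > 0")


@dataclass
class TrainingTrace:
    loss_per_step: np.ndarray
    final_vaf_train: float
    steps_run: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"step": np.arange(1, self.steps_run + 1), "loss": self.loss_per_step}
        ).to_csv(path, index=False)


def init_model(
    n_channels: int, h: int, k: int, activation: str = "tanh", seed: int = 0
) -> AutoencoderModel:
    """Seeded Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases."""
    if k >= n_channels:
        raise AutoencoderError(
            f"bottleneck_size={k} must be smaller than n_channels={n_channels}"
        )
    if h < 1 or k < 1:
        raise AutoencoderError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return AutoencoderModel(
        w1=glorot(n_channels, h), b1=np.zeros(h),
        w2=glorot(h, k), b2=np.zeros(k),
        w3=glorot(k, h), b3=np.zeros(h),
        w4=glorot(h, n_channels), b4=np.zeros(n_channels),
        hidden_size=h, bottleneck_size=k, activation=activation,
    )


def _check_columns(name: str, X: np.ndarray, expected: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != expected:
        raise AutoencoderError(
            f"{name} must be 2-D with {expected} columns; got shape {X.shape}"
        )
    return X


def encode(model: AutoencoderModel, X: np.ndarray) -> LatentRepresentation:
    """Map inputs to the bottleneck: the coding units (one column per CU)."""
    X = _check_columns("X", X, model.n_channels)
    act, _ = ACTIVATIONS[model.activation]
    layer1 = act(X @ model.w1 + model.b1)
    Z = layer1 @ model.w2 + model.b2
    return LatentRepresentation(A=Z, method="nAEN")


def decode(model: AutoencoderModel, Z) -> np.ndarray:
    """Map bottleneck scores back to channel space (linear output layer)."""
    A = Z.A if isinstance(Z, LatentRepresentation) else np.asarray(Z, dtype=float)
    A = _check_columns("Z", A, model.bottleneck_size)
    act, _ = ACTIVATIONS[model.activation]
    layer3 = act(A @ model.w3 + model.b3)
    return layer3 @ model.w4 + model.b4


def forward(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Full reconstruction pass: decode(encode(X))."""
    return decode(model, encode(model, X))


def loss_and_gradients(model: AutoencoderModel, X: np.ndarray):
    """Mean squared reconstruction error and its gradients by backpropagation.

    The loss is averaged over both samples and channels.  Returns
    ``(loss, grads)`` with one gradient array per parameter block.
    """
    X = _check_columns("X", X, model.n_channels)
    if X.shape[0] == 0:
        raise AutoencoderError("X must contain at least one sample")
    act, act_grad = ACTIVATIONS[model.activation]

    a1 = X @ model.w1 + model.b1
    layer1 = act(a1)
    z = layer1 @ model.w2 + model.b2
    a3 = z @ model.w3 + model.b3
    layer3 = act(a3)
    Y = layer3 @ model.w4 + model.b4

    resid = Y - X
    loss = float(np.mean(resid**2))

    dY = 2.0 * resid / resid.size
    grads = {}
    grads["w4"] = layer3.T @ dY
    grads["b4"] = dY.sum(axis=0)
    dlayer3 = dY @ model.w4.T
    da3 = dlayer3 * act_grad(a3)
    grads["w3"] = z.T @ da3
    grads["b3"] = da3.sum(axis=0)
    dz = da3 @ model.w3.T
    grads["w2"] = layer1.T @ dz
    grads["b2"] = dz.sum(axis=0)
    dlayer1 = dz @ model.w2.T
    da1 = dlayer1 * act_grad(a1)
    grads["w1"] = X.T @ da1
    grads["b1"] = da1.sum(axis=0)
    return loss, grads


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: dict
    v: dict
    t: int = 0

    @classmethod
    def zeros_like(cls, params: dict) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in params.items()},
            v={k: np.zeros_like(p) for k, p in params.items()},
            t=0,
        )


def adam_step(params: dict, grads: dict, state: AdamState, config: TrainingConfig):
    """One bias-corrected ADAM update; returns (new_params, new_state)."""
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
    t = state.t + 1
    new_params, new_m, new_v = {}, {}, {}
    for key, p in params.items():
        g = grads[key]
        m = b1 * state.m[key] + (1 - b1) * g
        v = b2 * state.v[key] + (1 - b2) * g**2
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        new_params[key] = p - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        new_m[key], new_v[key] = m, v
    return new_params, AdamState(m=new_m, v=new_v, t=t)


def train(model: AutoencoderModel, X_train: np.ndarray, config: TrainingConfig):
    """Run full-batch ADAM for ``config.steps`` steps.

    Deterministic given (model, data, config).  Aborts with
    :class:`TrainingDivergenceError` naming the step if the loss becomes
    non-finite.  Returns ``(trained_model, TrainingTrace)``.
    """
    config.validate()
    X_train = _check_columns("X_train", X_train, model.n_channels)
    if X_train.shape[0] == 0:
        raise AutoencoderError("X_train must contain at least one sample")
    model = replace(model, activation=config.activation).copy()
    params = model.params()
    state = AdamState.zeros_like(params)
    losses = np.empty(config.steps)
    for step in range(config.steps):
        loss, grads = loss_and_gradients(model.with_params(params), X_train)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                f"loss became non-finite at step {step + 1}"
            )
        losses[step] = loss
        params, state = adam_step(params, grads, state, config)
    trained = model.with_params(params)
    final_vaf = vaf(X_train, forward(trained, X_train)).aggregate_vaf
    trace = TrainingTrace(
        loss_per_step=losses, final_vaf_train=final_vaf, steps_run=config.steps
    )
    return trained, trace


def hyperparameter_sweep(
    X: np.ndarray,
    grid: dict,
    bottleneck_size: int = 2,
    hidden_size: int = 10,
    folds: int = 5,
    seed: int = 0,
):
    """Cross-validated grid sweep over learning rate, step count, and activation.

    ``grid`` maps any of ``learning_rate``, ``steps``, ``activation`` to a
    list of values; missing keys use the :class:`TrainingConfig` default.
    Every grid point is scored by mean held-out VAF over ``folds`` folds
    (same fold partition for all points, so cells are comparable).  Training
    failures are recorded in the table's ``error`` column rather than
    aborting the sweep.  Returns a tidy DataFrame with one row per
    (grid point, fold) and the per-point mean in ``mean_vaf``.
    """
    import itertools

    import pandas as pd

    if not grid:
        raise AutoencoderError("sweep grid must be nonempty")
    unknown = set(grid) - {"learning_rate", "steps", "activation"}
    if unknown:
        raise AutoencoderError(f"unknown grid keys: {sorted(unknown)}")
    X = np.asarray(X, dtype=float)
    defaults = TrainingConfig()
    axes = {
        "learning_rate": list(grid.get("learning_rate", [defaults.learning_rate])),
        "steps": list(grid.get("steps", [defaults.steps])),
        "activation": list(grid.get("activation", [defaults.activation])),
    }
    fold_list = kfold_indices(X.shape[0], k=folds, seed=seed)
    rows = []
    for lr, steps, activation in itertools.product(
        axes["learning_rate"], axes["steps"], axes["activation"]
    ):
        config = TrainingConfig(
            learning_rate=lr, steps=steps, activation=activation, seed=seed
        )
        for fold, (tr, te) in enumerate(fold_list):
            row = {
                "learning_rate": lr,
                "steps": steps,
                "activation": activation,
                "fold": fold,
                "vaf": np.nan,
                "error": "",
            }
            try:
                model = init_model(
                    X.shape[1], hidden_size, bottleneck_size,
                    activation=activation, seed=seed,
                )
                trained, _ = train(model, X[tr], config)
                row["vaf"] = vaf(X[te], forward(trained, X[te])).aggregate_vaf
            except (TrainingDivergenceError, AutoencoderError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["learning_rate", "steps", "activation"])["vaf"]
        .mean()
        .rename("mean_vaf")
        .reset_index()
    )
    return table.merge(means, on=["learning_rate", "steps", "activation"])
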