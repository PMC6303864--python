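"""Loss, penalized cost, exact backpropagation and the optimizer family.

The data loss is the half mean squared error L = (1/2n) sum (y_i - yhat_i)^2.
Two routes to l2 regularization are provided and they are not equivalent:

* the *coupled* route adds lambda * ||W||^2 terms to the cost and their
  gradients to backprop (used with plain gradient descent, where it is
  exactly ridge regression for the linear one-unit network);
* the *decoupled* route multiplies parameters by (1 - lr * lambda / b) inside
  the Adam update, which is the canonical training path here.

Per-group decay coefficients follow the penalty configuration: lambda1 for
input-layer weights, lambda2 for deeper weights, lambda3 for biases
(biases are unpenalized by default so the intercept can absorb the
phenotype mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    DropoutSpec,
    MaskSet,
    NetArchitecture,
    NetParams,
    NetworkError,
    activation_deriv,
    forward,
)


class TrainingError(ValueError):
    """Raised for invalid training configurations or diverged losses."""


@dataclass(frozen=True)
class PenaltyConfig:
    """l2 coefficients: lambda1 input weights, lambda2 deeper weights, lambda3 biases.

    ``lambda2=None`` defaults to ``lambda1`` (experiments typically vary only
    the input-weight decay).
    """

    lambda1: float = 0.0
    lambda2: float | None = None
    lambda3: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda3 < 0:
            raise TrainingError("penalty coefficients must be nonnegative")
        if self.lambda2 is not None and self.lambda2 < 0:
            raise TrainingError("penalty coefficients must be nonnegative")

    @property
    def hidden(self) -> float:
        return self.lambda1 if self.lambda2 is None else self.lambda2

    def weight_lambda(self, layer: int) -> float:
        return self.lambda1 if layer == 0 else self.hidden


@dataclass
class AdamState:
    """Adam moment accumulators and hyper-parameters."""

    m: NetParams
    v: NetParams
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    lr: float = 1e-3


@dataclass
class TrainConfig:
    """Optimizer family, batch size, epochs, penalties and dropout for a run."""

    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 6000
    optimizer: str = "minibatch_adam"
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    joint_triples: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise TrainingError("batch_size must be positive")
        if self.epochs < 1:
            raise TrainingError("epochs must be positive")
        if self.learning_rate <= 0:
            raise TrainingError("learning rate must be positive")
        if self.optimizer not in ("gd", "sgd", "minibatch_adam"):
            raise TrainingError(f"unknown optimizer {self.optimizer!r}")


def euclidean_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Half mean squared error, (1/2n) sum (y - yhat)^2."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise TrainingError("y and yhat must have equal length")
    return float(0.5 * np.mean((y - yhat) ** 2))


def penalized_cost(
    params: NetParams, y: np.ndarray, yhat: np.ndarray, penalty: PenaltyConfig
) -> float:
    """Data loss plus the coupled l2 penalty terms."""
    cost = euclidean_loss(y, yhat)
    for layer, (W, b) in enumerate(zip(params.weights, params.biases)):
        cost += penalty.weight_lambda(layer) * float(np.sum(W**2))
        cost += penalty.lambda3 * float(np.sum(b**2))
    return cost


def backprop(
    params: NetParams,
    arch: NetArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    masks: MaskSet | None = None,
    penalty: PenaltyConfig | None = None,
) -> NetParams:
    """Exact gradient of the (optionally penalized) cost w.r.t. every parameter.

    With masks, gradients flow through the rescaled-mask forward pass, so
    dropped weights receive exactly zero gradient.  ``penalty=None`` (the
    default) returns the data-loss gradient only; decoupled decay is then
    applied inside the optimizer update instead.
    """
    y = np.asarray(y, dtype=float)
    yhat, caches = forward(params, X, arch, masks)
    if not np.isfinite(yhat).all():
        raise TrainingError("nonfinite activations in forward pass")
    n = len(y)
    grads = params.zeros_like()
    delta = ((yhat - y) / n)[:, None]  # dL/dA at the output layer
    for layer in range(arch.n_layers - 1, -1, -1):
        A_in, S, scale, W_eff = caches[layer]
        dS = delta * activation_deriv(S, arch.activation)
        gW = A_in.T @ dS
        if scale is not None:
            gW *= scale[:, None]  # dropped rows get exactly zero gradient
        grads.weights[layer] = gW
        grads.biases[layer] = dS.sum(axis=0)
        if layer > 0:
            delta = dS @ W_eff.T  # masked weights carry the z/p factor back
    if penalty is not None:
        for layer in range(arch.n_layers):
            grads.weights[layer] += (
                2.0 * penalty.weight_lambda(layer) * params.weights[layer]
            )
            grads.biases[layer] += 2.0 * penalty.lambda3 * params.biases[layer]
    return grads


def gd_step(params: NetParams, grads: NetParams, lr: float) -> NetParams:
    """Plain descent update theta <- theta - lr * g."""
    if lr <= 0:
        raise TrainingError("learning rate must be positive")
    out = params.copy()
    for layer in range(params.n_layers):
        out.weights[layer] -= lr * grads.weights[layer]
        out.biases[layer] -= lr * grads.biases[layer]
    return out


def init_adam(
    params: NetParams,
    lr: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> AdamState:
    return AdamState(
        m=params.zeros_like(), v=params.zeros_like(), t=0,
        beta1=beta1, beta2=beta2, eps=eps, lr=lr,
    )


def adam_step(
    state: AdamState,
    grads: NetParams,
    params: NetParams,
    penalty: PenaltyConfig,
    batch_size: int,
) -> tuple[NetParams, AdamState]:
    """One Adam update with decoupled weight decay.

    Moments are updated and bias-corrected, then every parameter group theta
    is replaced by (1 - lr*lambda/b) * theta - lr * m_hat / (sqrt(v_hat)+eps)
    with the group's own decay coefficient.
    """
    lambdas = [penalty.weight_lambda(layer) for layer in range(params.n_layers)]
    for lam in lambdas + [penalty.lambda3]:
        if state.lr * lam / batch_size >= 1.0:
            raise TrainingError(
                "lr*lambda/batch_size >= 1 would flip parameter signs"
            )
    out = params.copy()
    state.t += 1
    bc1 = 1.0 - state.beta1**state.t
    bc2 = 1.0 - state.beta2**state.t
    for layer in range(params.n_layers):
        for attr, g, lam in (
            ("weights", grads.weights[layer], lambdas[layer]),
            ("biases", grads.biases[layer], penalty.lambda3),
        ):
            m = getattr(state.m, attr)[layer]
            v = getattr(state.v, attr)[layer]
            m *= state.beta1
            m += (1.0 - state.beta1) * g
            v *= state.beta2
            v += (1.0 - state.beta2) * g**2
            m_hat = m / bc1
            v_hat = v / bc2
            theta = getattr(out, attr)[layer]
            theta *= 1.0 - state.lr * lam / batch_size
            theta -= state.lr * m_hat / (np.sqrt(v_hat) + state.eps)
    return out, state


def run_epoch(
    params: NetParams,
    X: np.ndarray,
    y: np.ndarray,
    arch: NetArchitecture,
    config: TrainConfig,
    rng: np.random.Generator,
    masks: MaskSet | None = None,
    adam: AdamState | None = None,
) -> tuple[NetParams, AdamState | None]:
    """One optimization pass over the training data.

    Batches are sampled without replacement (reshuffled per epoch); ``gd``
    uses the full batch, ``sgd`` single samples, ``minibatch_adam`` batches
    of ``config.batch_size``.  Any dropout masks stay fixed for the whole
    pass.  The decoupled decay factor always uses the configured batch size,
    so a ragged final batch decays at the same per-step rate.  ``gd`` and
    ``sgd`` take the coupled route (penalty gradients inside backprop);
    ``minibatch_adam`` applies decay decoupled inside the update.
    """
    n = len(y)
    if config.optimizer == "gd":
        X_pass, y_pass = X, y
        bounds = [(0, n)]
    else:
        order = rng.permutation(n)
        X_pass, y_pass = X[order], y[order]  # one copy; batches are views
        size = 1 if config.optimizer == "sgd" else min(config.batch_size, n)
        bounds = [(i, min(i + size, n)) for i in range(0, n, size)]
    coupled = config.penalty if config.optimizer != "minibatch_adam" else None
    for lo, hi in bounds:
        grads = backprop(
            params, arch, X_pass[lo:hi], y_pass[lo:hi], masks=masks, penalty=coupled
        )
        if config.optimizer == "minibatch_adam":
            if adam is None:
                raise TrainingError("minibatch_adam requires an AdamState")
            params, adam = adam_step(
                adam, grads, params, config.penalty, config.batch_size
            )
        else:
            params = gd_step(params, grads, config.learning_rate)
    return params, adam
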