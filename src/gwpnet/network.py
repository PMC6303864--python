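"""Layered feed-forward network: parameters, activations, dropout masks, forward pass.

The regression model is a stack of 1-3 fully connected layers ending in a
single output unit; the activation is applied at every layer.  A one-layer,
one-unit network with linear activation is exactly an affine map (multiple
regression), which is the identifiable configuration used for SNP-effect
extraction.

Dropout multiplies the inputs of each layer by independent Bernoulli masks
rescaled by the retention probability (inverted dropout), so the expected
pre-activation is unchanged.  Masks are sampled once per chain iteration and
held fixed through an optimization pass; the masked-and-rescaled weights are
what the posterior chain records as one approximate posterior draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NetworkError(ValueError):
    """Raised for invalid architectures, shapes or activation names."""


def _linear(x):
    return np.asarray(x, dtype=float)


def _d_linear(x):
    return np.ones_like(np.asarray(x, dtype=float))


def _relu(x):
    return np.maximum(0.0, np.asarray(x, dtype=float))


def _d_relu(x):
    return (np.asarray(x, dtype=float) > 0).astype(float)


def _d_tanh(x):
    return 1.0 - np.tanh(x) ** 2


ACTIVATIONS = {
    "linear": (_linear, _d_linear),
    "tanh": (np.tanh, _d_tanh),
    "relu": (_relu, _d_relu),
}


def activation_eval(x, kind: str):
    """Evaluate an activation function elementwise."""
    try:
        fn, _ = ACTIVATIONS[kind]
    except KeyError:
        raise NetworkError(f"unknown activation {kind!r}") from None
    return fn(x)


def activation_deriv(x, kind: str):
    """Evaluate the derivative of an activation function elementwise."""
    try:
        _, dfn = ACTIVATIONS[kind]
    except KeyError:
        raise NetworkError(f"unknown activation {kind!r}") from None
    return dfn(x)


@dataclass(frozen=True)
class NetArchitecture:
    """Ordered hidden-layer widths (last width 1) and a shared activation."""

    layer_widths: tuple
    activation: str = "linear"

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.layer_widths)
        object.__setattr__(self, "layer_widths", widths)
        if len(widths) < 1:
            raise NetworkError("need at least one layer")
        if any(w < 1 for w in widths):
            raise NetworkError("layer widths must be positive")
        if widths[-1] != 1:
            raise NetworkError("final layer width must be 1 (scalar output)")
        if self.activation not in ACTIVATIONS:
            raise NetworkError(f"unknown activation {self.activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths)


@dataclass(frozen=True)
class DropoutSpec:
    """Retention probabilities: p1 for the input side, p2 for hidden outputs.

    p = 1 disables dropout at that site.
    """

    p1: float = 0.5
    p2: float = 0.5

    def __post_init__(self) -> None:
        for name, p in (("p1", self.p1), ("p2", self.p2)):
            if not 0.0 < p <= 1.0:
                raise NetworkError(f"{name} must be in (0, 1], got {p}")


@dataclass
class NetParams:
    """Per-layer weight matrices (fan_in x width) and bias vectors (width)."""

    weights: list
    biases: list

    def copy(self) -> "NetParams":
        return NetParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def zeros_like(self) -> "NetParams":
        return NetParams(
            weights=[np.zeros_like(w) for w in self.weights],
            biases=[np.zeros_like(b) for b in self.biases],
        )

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclass
class MaskSet:
    """One binary mask per dropout site.

    ``masks[l]`` multiplies the input of layer ``l`` (so ``masks[0]`` is the
    input-feature mask in the z1 role and ``masks[l>0]`` drop hidden units in
    the z2 role).  Biases are never masked.
    """

    masks: list
    retention: tuple

    def scale(self, layer: int) -> np.ndarray | None:
        """Mask divided by its retention probability (inverted dropout).

        A ``None`` mask entry means the site is identity (already applied or
        disabled); ``scale`` then returns ``None``.
        """
        if self.masks[layer] is None:
            return None
        return self.masks[layer] / self.retention[layer]

    def with_input_applied(self) -> "MaskSet":
        """Copy of the mask set whose input-site mask is marked as applied."""
        return MaskSet(masks=[None] + self.masks[1:], retention=self.retention)


def init_params(
    arch: NetArchitecture, input_dim: int, rng: np.random.Generator
) -> NetParams:
    """Zero biases; weights uniform on +-1/sqrt(fan_in)."""
    weights, biases = [], []
    fan_in = int(input_dim)
    for width in arch.layer_widths:
        scale = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-scale, scale, size=(fan_in, width)))
        biases.append(np.zeros(width))
        fan_in = width
    return NetParams(weights=weights, biases=biases)


def sample_masks(
    spec: DropoutSpec,
    arch: NetArchitecture,
    input_dim: int,
    rng: np.random.Generator,
    joint_triples: bool = False,
) -> MaskSet:
    """Sample Bernoulli dropout masks for the input and every hidden output.

    With ``joint_triples`` the input mask drops the three one-hot indicator
    columns of a marker together (input_dim must be a multiple of 3);
    by default indicator columns are dropped independently.
    """
    masks = []
    retention = []
    if joint_triples:
        if input_dim % 3:
            raise NetworkError("joint_triples requires input_dim divisible by 3")
        per_marker = (rng.random(input_dim // 3) < spec.p1).astype(float)
        masks.append(np.repeat(per_marker, 3))
    else:
        masks.append((rng.random(input_dim) < spec.p1).astype(float))
    retention.append(spec.p1)
    for width in arch.layer_widths[:-1]:
        masks.append((rng.random(width) < spec.p2).astype(float))
        retention.append(spec.p2)
    return MaskSet(masks=masks, retention=tuple(retention))


def forward(
    params: NetParams,
    X: np.ndarray,
    arch: NetArchitecture,
    masks: MaskSet | None = None,
):
    """Run the forward pass; returns (predictions, per-layer caches).

    Without masks this is the plain layered map ``A_l = act(A_{l-1} W_l + b_l)``.
    With masks, layer ``l`` uses the thinned-and-rescaled weights
    ``diag(z_{l-1}/p) W_l`` — algebraically identical to multiplying the layer
    input elementwise by ``z/p``, but applied to the small weight matrix.
    Caches hold (layer input, pre-activation, mask scale) for backpropagation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise NetworkError("X must be a 2-d design matrix")
    if len(params.weights) != arch.n_layers:
        raise NetworkError("params and architecture disagree on layer count")
    A = X
    caches = []
    for layer, (W, b) in enumerate(zip(params.weights, params.biases)):
        if A.shape[1] != W.shape[0]:
            raise NetworkError(
                f"layer {layer + 1} expects fan-in {W.shape[0]}, got {A.shape[1]}"
            )
        scale = masks.scale(layer) if masks is not None and layer < len(masks.masks) else None
        W_eff = W if scale is None else W * scale[:, None]
        S = A @ W_eff + b
        A_next = activation_eval(S, arch.activation)
        caches.append((A, S, scale, W_eff))
        A = A_next
    return A[:, 0], caches


def masked_params(params: NetParams, masks: MaskSet) -> NetParams:
    """Bake the rescaled masks into the weights: layer l rows get z_{l-1}/p.

    ``forward(masked_params(params, masks), X, arch)`` equals
    ``forward(params, X, arch, masks)``; this thinned-and-rescaled parameter
    set is the posterior draw the chain records.
    """
    out = params.copy()
    for layer in range(len(out.weights)):
        if layer < len(masks.masks):
            scale = masks.scale(layer)
            if scale is not None:
                out.weights[layer] = out.weights[layer] * scale[:, None]
    return out


def params_to_vector(params: NetParams) -> np.ndarray:
    """Flatten parameters layer by layer (W then b)."""
    parts = []
    for W, b in zip(params.weights, params.biases):
        parts.append(W.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def vector_to_params(vec: np.ndarray, template: NetParams) -> NetParams:
    """Inverse of :func:`params_to_vector` given a shape template."""
    expected = sum(w.size + b.size for w, b in zip(template.weights, template.biases))
    if len(vec) != expected:
        raise NetworkError(
            f"vector length {len(vec)} does not match parameter count {expected}"
        )
    out = template.zeros_like()
    offset = 0
    for layer, (W, b) in enumerate(zip(template.weights, template.biases)):
        out.weights[layer] = vec[offset : offset + W.size].reshape(W.shape)
        offset += W.size
        out.biases[layer] = vec[offset : offset + b.size].reshape(b.shape)
        offset += b.size
    if offset != len(vec):
        raise NetworkError("vector length does not match parameter shapes")
    return out
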