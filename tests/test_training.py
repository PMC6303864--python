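import numpy as np
import pytest

from gwpnet import (
    DropoutSpec,
    NetArchitecture,
    NetParams,
    PenaltyConfig,
    TrainConfig,
    TrainingError,
    adam_step,
    backprop,
    euclidean_loss,
    forward,
    gd_step,
    init_adam,
    init_params,
    penalized_cost,
    run_epoch,
    sample_masks,
)


def _finite_difference(params, arch, X, y, masks=None, penalty=None, h=1e-6):
    """Central-difference gradient of the (optionally penalized) cost."""
    from gwpnet import params_to_vector, vector_to_params

    vec = params_to_vector(params)
    grad = np.zeros_like(vec)
    for i in range(len(vec)):
        for sign in (+1, -1):
            bumped = vec.copy()
            bumped[i] += sign * h
            p = vector_to_params(bumped, params)
            yhat, _ = forward(p, X, arch, masks)
            cost = (
                euclidean_loss(y, yhat)
                if penalty is None
                else penalized_cost(p, y, yhat, penalty)
            )
            grad[i] += sign * cost
    return grad / (2 * h)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_euclidean_loss_values():
    assert euclidean_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert euclidean_loss([0.0, 2.0], [0.0, 0.0]) == 1.0
    base = euclidean_loss([0.0, 2.0], [0.0, 0.0])
    scaled = euclidean_loss([0.0, 6.0], [0.0, 0.0])  # error scaled by 3
    assert scaled == pytest.approx(9 * base)
    with pytest.raises(TrainingError):
        euclidean_loss([1.0], [1.0, 2.0])


def test_penalized_cost_values(rng):
    params = NetParams(weights=[np.array([[2.0]])], biases=[np.array([0.0])])
    y = np.array([2.0])
    yhat = np.array([2.0])
    assert penalized_cost(params, y, yhat, PenaltyConfig()) == euclidean_loss(y, yhat)
    assert penalized_cost(params, y, yhat, PenaltyConfig(lambda1=1.4)) == pytest.approx(5.6)
    zero = params.zeros_like()
    assert penalized_cost(zero, np.zeros(1), np.zeros(1), PenaltyConfig(1.0, 2.0, 3.0)) == 0.0


def test_penalty_config_groups():
    pen = PenaltyConfig(lambda1=0.5)
    assert pen.weight_lambda(0) == 0.5
    assert pen.weight_lambda(1) == 0.5  # lambda2 defaults to lambda1
    pen = PenaltyConfig(lambda1=0.5, lambda2=0.1, lambda3=0.2)
    assert pen.weight_lambda(2) == 0.1
    with pytest.raises(TrainingError):
        PenaltyConfig(lambda1=-1.0)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_backprop_hand_case():
    # single linear unit, one observation: dJ/dW = (yhat - y) * x = 1
    arch = NetArchitecture((1,), "linear")
    params = NetParams(weights=[np.array([[1.0]])], biases=[np.array([0.0])])
    grads = backprop(params, arch, np.array([[1.0]]), np.array([0.0]))
    assert grads.weights[0][0, 0] == pytest.approx(1.0)
    assert grads.biases[0][0] == pytest.approx(1.0)


@pytest.mark.parametrize("activation", ["linear", "tanh", "relu"])
def test_backprop_matches_finite_differences_with_penalty(activation):
    rng = np.random.default_rng(1)
    arch = NetArchitecture((2, 1), activation)
    X = rng.normal(size=(5, 3)) + 0.5
    y = rng.normal(size=5)
    params = init_params(arch, 3, rng)
    # central differences are only valid away from relu kinks
    _, caches = forward(params, X, arch)
    assert all(np.abs(S).min() > 1e-3 for _, S, _, _ in caches)
    penalty = PenaltyConfig(lambda1=0.3, lambda2=0.1, lambda3=0.05)
    from gwpnet import params_to_vector

    got = params_to_vector(backprop(params, arch, X, y, penalty=penalty))
    want = _finite_difference(params, arch, X, y, penalty=penalty)
    np.testing.assert_allclose(got, want, atol=1e-7)


def test_masked_weights_get_zero_gradient(rng):
    arch = NetArchitecture((3, 1), "tanh")
    params = init_params(arch, 6, rng)
    masks = sample_masks(DropoutSpec(0.5, 0.5), arch, 6, rng)
    X = rng.normal(size=(10, 6))
    y = rng.normal(size=10)
    grads = backprop(params, arch, X, y, masks=masks)
    dropped_inputs = masks.masks[0] == 0
    assert (grads.weights[0][dropped_inputs] == 0).all()
    dropped_hidden = masks.masks[1] == 0
    assert (grads.weights[1][dropped_hidden] == 0).all()
    # and the masked gradient matches finite differences of the masked loss
    from gwpnet import params_to_vector

    got = params_to_vector(grads)
    want = _finite_difference(params, arch, X, y, masks=masks)
    np.testing.assert_allclose(got, want, atol=1e-7)


# ---------------------------------------------------------------------------
# optimizer steps
# ---------------------------------------------------------------------------

def test_gd_step_arithmetic():
    params = NetParams(weights=[np.array([[1.0]])], biases=[np.array([0.5])])
    zero = params.zeros_like()
    unchanged = gd_step(params, zero, lr=0.1)
    assert unchanged.weights[0][0, 0] == 1.0
    grads = NetParams(weights=[np.array([[2.0]])], biases=[np.array([0.0])])
    stepped = gd_step(params, grads, lr=0.1)
    assert stepped.weights[0][0, 0] == pytest.approx(0.8)


def test_full_batch_epoch_equals_single_gd_step(rng):
    arch = NetArchitecture((1,), "linear")
    X = rng.normal(size=(12, 4))
    y = rng.normal(size=12)
    params = init_params(arch, 4, rng)
    cfg = TrainConfig(optimizer="gd", learning_rate=0.05, penalty=PenaltyConfig(0.1))
    via_epoch, _ = run_epoch(params, X, y, arch, cfg, np.random.default_rng(0))
    direct = gd_step(
        params, backprop(params, arch, X, y, penalty=cfg.penalty), lr=0.05
    )
    np.testing.assert_array_equal(via_epoch.weights[0], direct.weights[0])


def test_adam_first_step_is_signed_learning_rate(rng):
    arch = NetArchitecture((1,), "linear")
    params = init_params(arch, 3, rng)
    grads = params.zeros_like()
    grads.weights[0] = np.array([[0.5], [-2.0], [1e-3]])
    state = init_adam(params, lr=0.01)
    new, state = adam_step(state, grads, params, PenaltyConfig(), batch_size=10)
    # m_hat = g and v_hat = g^2 at t=1, so the move is -lr * sign(g)
    delta = new.weights[0] - params.weights[0]
    np.testing.assert_allclose(delta, -0.01 * np.sign(grads.weights[0]), rtol=1e-4)


def test_adam_zero_gradient_behaviour(rng):
    arch = NetArchitecture((1,), "linear")
    params = init_params(arch, 3, rng)
    zero = params.zeros_like()
    state = init_adam(params, lr=0.1)
    same, state = adam_step(state, zero, params, PenaltyConfig(), batch_size=4)
    np.testing.assert_allclose(same.weights[0], params.weights[0], atol=1e-12)
    # with decay, the update is exactly the multiplicative factor
    state = init_adam(params, lr=0.1)
    decayed, state = adam_step(state, zero, params, PenaltyConfig(lambda1=2.0), batch_size=4)
    np.testing.assert_allclose(
        decayed.weights[0], (1 - 0.1 * 2.0 / 4) * params.weights[0], atol=1e-12
    )


def test_adam_decay_strictly_shrinks_norm(rng):
    arch = NetArchitecture((2, 1), "linear")
    params = init_params(arch, 3, rng)
    state = init_adam(params, lr=0.05)
    zero = params.zeros_like()
    norms = []
    for _ in range(5):
        norms.append(sum(float(np.sum(w**2)) for w in params.weights))
        params, state = adam_step(state, zero, params, PenaltyConfig(0.5), batch_size=2)
    assert all(b < a for a, b in zip(norms, norms[1:]))


def test_adam_rejects_sign_flipping_decay(rng):
    arch = NetArchitecture((1,), "linear")
    params = init_params(arch, 2, rng)
    state = init_adam(params, lr=1.0)
    with pytest.raises(TrainingError, match="flip"):
        adam_step(state, params.zeros_like(), params, PenaltyConfig(lambda1=3.0), batch_size=2)


def test_train_config_validation():
    with pytest.raises(TrainingError):
        TrainConfig(batch_size=0)
    with pytest.raises(TrainingError):
        TrainConfig(optimizer="momentum")
    with pytest.raises(TrainingError):
        TrainConfig(epochs=0)


def test_sgd_epoch_is_sequence_of_single_sample_steps(rng):
    """One SGD epoch = n single-sample GD steps in a seeded shuffle order."""
    arch = NetArchitecture((1,), "linear")
    n, p = 6, 3
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    params = init_params(arch, p, rng)
    cfg = TrainConfig(optimizer="sgd", learning_rate=0.2)
    via_epoch, _ = run_epoch(params, X, y, arch, cfg, np.random.default_rng(1))
    order = np.random.default_rng(1).permutation(n)
    manual = params
    for i in order:
        grads = backprop(
            manual, arch, X[i : i + 1], y[i : i + 1], penalty=cfg.penalty
        )
        manual = gd_step(manual, grads, lr=0.2)
    np.testing.assert_allclose(via_epoch.weights[0], manual.weights[0], atol=1e-12)
    np.testing.assert_allclose(via_epoch.biases[0], manual.biases[0], atol=1e-12)
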