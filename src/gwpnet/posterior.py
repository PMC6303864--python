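"""Monte-Carlo dropout chain: sample masks, fit, predict, summarize.

Each chain iteration t samples fresh Bernoulli dropout masks, runs one
optimization pass over the training data with those masks held fixed
(warm-starting from the current parameters), and records

* the masked-and-rescaled parameter snapshot (one approximate posterior draw),
* the test predictions under that draw, and
* their test MSE and MAE.

After discarding a burn-in prefix, elementwise means and variances of the
snapshots approximate posterior moments, and the mean of the per-iteration
test MSE is the model-averaged prediction error.  The variance uses the
1/(T - t_s) normalization (the biased sample variance over retained draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    NetArchitecture,
    NetParams,
    forward,
    init_params,
    masked_params,
    params_to_vector,
    sample_masks,
    vector_to_params,
)
from .training import TrainConfig, init_adam, run_epoch


class ChainDivergedError(RuntimeError):
    """Nonfinite loss during a chain; the partial chain is attached."""

    def __init__(self, message: str, chain: "PosteriorChain"):
        super().__init__(message)
        self.chain = chain


def mse_t(yhat: np.ndarray, y: np.ndarray) -> float:
    """Per-iteration test mean squared error (no 1/2 factor)."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("prediction and truth lengths differ")
    return float(np.mean((yhat - y) ** 2))


def mae_t(yhat: np.ndarray, y: np.ndarray) -> float:
    """Per-iteration test mean absolute error."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("prediction and truth lengths differ")
    return float(np.mean(np.abs(yhat - y)))


@dataclass
class PosteriorChain:
    """Per-iteration posterior draws, test predictions and error traces."""

    arch: NetArchitecture
    input_dim: int
    snapshots: np.ndarray  # (T, n_params) masked-and-rescaled draws
    test_predictions: np.ndarray  # (T, n_test)
    mse: np.ndarray  # (T,)
    mae: np.ndarray  # (T,)
    y_test: np.ndarray
    final_params: NetParams
    config: TrainConfig

    @property
    def n_iterations(self) -> int:
        return len(self.mse)

    def params_at(self, t: int) -> NetParams:
        return vector_to_params(self.snapshots[t], self.final_params)


@dataclass
class PosteriorSummary:
    """Posterior moments and model-averaged scores over retained iterations."""

    mean_params: np.ndarray
    var_params: np.ndarray
    mse_model_averaged: float
    mae_model_averaged: float
    sd_mse: float
    mean_prediction: np.ndarray
    mse_of_mean_prediction: float
    burn_in: int
    n_retained: int
    arch: NetArchitecture
    input_dim: int
    _template: NetParams

    @property
    def mean_net(self) -> NetParams:
        """Posterior-mean parameters reshaped into network layers."""
        return vector_to_params(self.mean_params, self._template)

    @property
    def var_net(self) -> NetParams:
        """Posterior parameter variances reshaped into network layers."""
        return vector_to_params(self.var_params, self._template)


def run_chain(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    arch: NetArchitecture,
    config: TrainConfig,
    rng: np.random.Generator,
    n_iterations: int | None = None,
    snapshot_masked: bool = True,
    init: NetParams | None = None,
) -> PosteriorChain:
    """Run the MC-dropout chain for ``n_iterations`` (default: config.epochs).

    Fully reproducible given ``rng``: initialization, mask draws and batch
    shuffles all consume the one generator in a fixed order.  Set
    ``snapshot_masked=False`` to record raw (unthinned) weights for
    diagnostics instead of the masked draws.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    T = config.epochs if n_iterations is None else int(n_iterations)
    if T < 1:
        raise ValueError("need at least one chain iteration")
    params = init.copy() if init is not None else init_params(
        arch, X_train.shape[1], rng
    )
    adam = (
        init_adam(params, lr=config.learning_rate)
        if config.optimizer == "minibatch_adam"
        else None
    )
    n_params = len(params_to_vector(params))
    snapshots = np.empty((T, n_params))
    test_pred = np.empty((T, len(y_test)))
    mse = np.empty(T)
    mae = np.empty(T)
    for t in range(T):
        masks = sample_masks(
            config.dropout, arch, X_train.shape[1], rng,
            joint_triples=config.joint_triples,
        )
        params, adam = run_epoch(
            params, X_train, y_train, arch, config, rng, masks=masks, adam=adam
        )
        omega = masked_params(params, masks)
        snapshots[t] = params_to_vector(omega if snapshot_masked else params)
        yhat, _ = forward(omega, X_test, arch)
        test_pred[t] = yhat
        mse[t] = mse_t(yhat, y_test)
        mae[t] = mae_t(yhat, y_test)
        if not np.isfinite(mse[t]):
            partial = PosteriorChain(
                arch=arch, input_dim=X_train.shape[1],
                snapshots=snapshots[: t + 1], test_predictions=test_pred[: t + 1],
                mse=mse[: t + 1], mae=mae[: t + 1], y_test=y_test,
                final_params=params, config=config,
            )
            raise ChainDivergedError(f"chain diverged at iteration {t}", partial)
    return PosteriorChain(
        arch=arch, input_dim=X_train.shape[1], snapshots=snapshots,
        test_predictions=test_pred, mse=mse, mae=mae, y_test=y_test,
        final_params=params, config=config,
    )


def summarize(chain: PosteriorChain, burn_in: int) -> PosteriorSummary:
    """Moments and model-averaged scores over iterations burn_in+1 .. T."""
    T = chain.n_iterations
    if not 0 <= burn_in < T:
        raise ValueError(f"burn_in must be in [0, {T}), got {burn_in}")
    snaps = chain.snapshots[burn_in:]
    mean_params = snaps.mean(axis=0)
    var_params = np.mean((snaps - mean_params) ** 2, axis=0)  # 1/(T - t_s)
    mean_prediction = chain.test_predictions[burn_in:].mean(axis=0)
    kept_mse = chain.mse[burn_in:]
    return PosteriorSummary(
        mean_params=mean_params,
        var_params=var_params,
        mse_model_averaged=float(kept_mse.mean()),
        mae_model_averaged=float(chain.mae[burn_in:].mean()),
        sd_mse=float(kept_mse.std(ddof=0)),
        mean_prediction=mean_prediction,
        mse_of_mean_prediction=mse_t(mean_prediction, chain.y_test),
        burn_in=burn_in,
        n_retained=T - burn_in,
        arch=chain.arch,
        input_dim=chain.input_dim,
        _template=chain.final_params,
    )


def trace_table(chain: PosteriorChain) -> pd.DataFrame:
    """Tidy (iteration, mse, mae) table for burn-in inspection."""
    return pd.DataFrame(
        {
            "iteration": np.arange(1, chain.n_iterations + 1),
            "mse": chain.mse,
            "mae": chain.mae,
        }
    )


def trace_report(
    chain: PosteriorChain, csv_path=None, plot_path=None
) -> pd.DataFrame:
    """Write the MSE/MAE trace as CSV and optionally render a trace plot."""
    table = trace_table(chain)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(table["iteration"], table["mse"], lw=0.8)
        ax.set_xlabel("iteration")
        ax.set_ylabel("test MSE")
        ax.set_title("MC-dropout chain trace")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table


def plateau_iteration(
    values: np.ndarray, window: int = 100, tol: float = 1e-2
) -> int | None:
    """Advisory burn-in helper: first t where the trailing-window mean of the
    trace changes by less than ``tol`` relative to the previous window.

    Returns ``None`` if the trace never plateaus.  Convergence should still
    be confirmed on the trace plot.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or len(values) < 2 * window:
        return None
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    means = (cumsum[window:] - cumsum[:-window]) / window  # mean ending at i+window
    for t in range(window, len(means)):
        if abs(means[t] - means[t - window]) < tol:
            return t + window  # 1-based iteration index of the window end
    return None
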