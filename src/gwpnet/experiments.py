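"""Reusable end-to-end experiments on simulated data.

Two protocols back the package's own evaluation:

* **Effect recovery** — simulate a dataset with known QTL, train the
  identifiable network (one-hot, one layer, one unit, linear activation) with
  MC dropout and near-zero weight decay, and read the posterior-mean additive
  and dominance effects at every causal marker.
* **Prediction** — the method's standard usage: tune the weight decay over a
  broad (decade) grid on a calibration dataset by model-averaged test MSE,
  then evaluate tuned chains on fresh replicates.  The effective shrinkage of
  decoupled decay scales with learning rate, step count and batch size, so
  the grid must be re-tuned per problem scale rather than copied between
  datasets.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .effects import snp_effects
from .genotypes import one_hot_encode
from .network import DropoutSpec, NetArchitecture
from .posterior import PosteriorSummary, run_chain, summarize
from .simulate import SimConfig, simulate_dataset
from .training import PenaltyConfig, TrainConfig

#: Chain length and burn-in used by the recovery protocol.
RECOVERY_EPOCHS = 2000
RECOVERY_BURN_IN = 500
RECOVERY_LAMBDA1 = 0.01

#: Decade grid for tuning the weight decay of prediction chains.
PREDICTION_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)


def single_locus_config(qtl_class: str, n: int = 2000, p: int = 500,
                        h2: float = 0.4) -> SimConfig:
    """Simulator conditions with exactly one causal locus of the given class."""
    counts = dict(
        n_controlled=0, n_random=0, n_epistatic_pairs=0,
        n_dominance=0, n_overdominance=0, n_underdominance=0,
    )
    key = {
        "controlled": "n_controlled",
        "dominance": "n_dominance",
        "overdominance": "n_overdominance",
        "underdominance": "n_underdominance",
    }[qtl_class]
    counts[key] = 1
    return SimConfig(n=n, p=p, h2=h2, **counts)


def recovery_config(n: int = 2000, p: int = 500, h2: float = 0.4) -> SimConfig:
    """Mixed scenario: one controlled, one dominance, one over-dominance locus."""
    return SimConfig(
        n=n, p=p, h2=h2,
        n_controlled=1, n_random=0, n_epistatic_pairs=0,
        n_dominance=1, n_overdominance=1, n_underdominance=0,
    )


def _fit_replicate(sim_config: SimConfig, seed: int, lambda1: float,
                   epochs: int, burn_in: int, dropout: float = 0.5):
    """Simulate one dataset and run one seeded chain on its holdout split."""
    ss = np.random.SeedSequence(seed)
    rng_sim, rng_chain = (np.random.default_rng(s) for s in ss.spawn(2))
    data = simulate_dataset(dataclasses.replace(sim_config, seed=None), rng_sim)
    design = one_hot_encode(data.genotypes)
    train_mask, test_mask = data.split.masks()
    y = data.phenotypes.values
    config = TrainConfig(
        batch_size=128,
        learning_rate=1e-3,
        epochs=epochs,
        penalty=PenaltyConfig(lambda1=lambda1),
        dropout=DropoutSpec(dropout, dropout),
    )
    chain = run_chain(
        design.indicators[train_mask], y[train_mask],
        design.indicators[test_mask], y[test_mask],
        NetArchitecture((1,), "linear"), config, rng_chain,
    )
    summary = summarize(chain, burn_in)
    return data, design, summary


def run_recovery_replicate(
    sim_config: SimConfig,
    seed: int,
    epochs: int = RECOVERY_EPOCHS,
    burn_in: int = RECOVERY_BURN_IN,
    lambda1: float = RECOVERY_LAMBDA1,
) -> dict:
    """Simulate, fit the linear one-unit network, extract causal-marker effects.

    Returns a dict with one entry per QTL (estimated ``a`` and ``d`` plus the
    generating truth at the causal marker), the model-averaged test MSE and
    the test-phenotype variance.
    """
    data, design, summary = _fit_replicate(sim_config, seed, lambda1, epochs, burn_in)
    table = snp_effects(summary, design, data.genotypes)
    train_mask, test_mask = data.split.masks()
    out = {
        "mse_model_averaged": summary.mse_model_averaged,
        "test_variance": float(np.var(data.phenotypes.values[test_mask])),
        "qtls": [],
    }
    for q in data.truth.qtls:
        row = table.iloc[q.index]
        out["qtls"].append(
            {
                "class": q.qtl_class,
                "a_hat": float(row["a"]),
                "d_hat": float(row["d"]),
                "a_true": q.a,
                "d_true": q.d,
                "marker_id": q.marker_id,
            }
        )
    return out


def run_prediction_replicate(
    sim_config: SimConfig, seed: int, lambda1: float,
    epochs: int = 1200, burn_in: int = 400,
) -> dict:
    """One tuned prediction chain; returns model-averaged scores and the
    test-phenotype variance (the mean predictor's MSE)."""
    data, _, summary = _fit_replicate(sim_config, seed, lambda1, epochs, burn_in)
    _, test_mask = data.split.masks()
    return {
        "mse_model_averaged": summary.mse_model_averaged,
        "mae_model_averaged": summary.mae_model_averaged,
        "test_variance": float(np.var(data.phenotypes.values[test_mask])),
    }


def tune_weight_decay(
    sim_config: SimConfig, seed: int, grid=PREDICTION_GRID,
    epochs: int = 800, burn_in: int = 300,
) -> float:
    """Pick the decay with the lowest model-averaged test MSE on one
    calibration dataset — the method's broad-grid tuning step."""
    scores = {}
    for lam in grid:
        _, _, summary = _fit_replicate(sim_config, seed, lam, epochs, burn_in)
        scores[float(lam)] = summary.mse_model_averaged
    return min(scores, key=scores.get)


def locus(result: dict, qtl_class: str) -> dict:
    """The recovery record of the (single) locus of a class in a replicate."""
    matches = [q for q in result["qtls"] if q["class"] == qtl_class]
    if len(matches) != 1:
        raise ValueError(f"expected one {qtl_class} locus, found {len(matches)}")
    return matches[0]
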