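"""Closed-form GBLUP-style kernel ridge baseline.

The genomic relationship matrix follows the VanRaden form
K = Z Z^T / (2 sum_j p_j (1 - p_j)) with Z the allele-frequency-centered
dosages.  Prediction is kernel ridge regression on the training block,

    yhat_test = K_test,train (K_train,train + delta I)^{-1} (y_train - mean) + mean,

with the shrinkage delta chosen by an inner k-fold cross-validation over a
grid.  This is the deterministic mixed-model BLUP surface used as a
comparison baseline for the dropout network; it is algebraically equivalent
to ridge regression on the centered markers with per-marker shrinkage
delta * c (c the VanRaden denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix


class GBLUPError(ValueError):
    """Raised for degenerate kinship or shrinkage inputs."""


@dataclass
class KinshipMatrix:
    """Symmetric n x n genomic relationship matrix with sample ids."""

    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GBLUPError("kinship matrix must be square")
        if len(self.sample_ids) != self.values.shape[0]:
            raise GBLUPError("sample_ids must match the matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GBLUPError("kinship matrix must be symmetric")


def genomic_relationship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from 0/1/2 dosages."""
    if G.n_markers < 2:
        raise GBLUPError("need at least two markers")
    X = G.dosages.astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise GBLUPError("all markers are monomorphic")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = Z @ Z.T / denom
    K = 0.5 * (K + K.T)  # exact symmetry against rounding
    return KinshipMatrix(values=K, sample_ids=G.sample_ids.copy())


DEFAULT_DELTA_GRID = tuple(float(d) for d in np.logspace(-2, 2, 9))


def _kernel_ridge_predict(K, y_train, train_idx, test_idx, delta):
    Ktt = K[np.ix_(train_idx, train_idx)]
    mean = y_train.mean()
    yc = y_train - mean
    A = Ktt + delta * np.eye(len(train_idx))
    try:
        alpha = np.linalg.solve(A, yc)
    except np.linalg.LinAlgError:
        return None
    return K[np.ix_(test_idx, train_idx)] @ alpha + mean


def gblup_fit_predict(
    kinship: KinshipMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    delta_grid=DEFAULT_DELTA_GRID,
    inner_folds: int = 5,
    seed: int | None = 0,
) -> tuple[np.ndarray, float]:
    """Predict test phenotypes; shrinkage picked by inner CV on the train set.

    ``y`` holds training-sample phenotypes aligned with ``train_idx``.
    Returns (test predictions, chosen delta).  Grid points whose linear
    system is singular are skipped.
    """
    K = kinship.values
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    y = np.asarray(y, dtype=float)
    if len(y) != len(train_idx):
        raise GBLUPError("y must align with train_idx")
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise GBLUPError("train and test sets must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_idx))
    folds = np.array_split(order, min(inner_folds, len(train_idx)))
    best_delta, best_score = None, np.inf
    for delta in delta_grid:
        errors = []
        for fold in folds:
            if len(fold) == 0 or len(fold) == len(train_idx):
                continue
            inner_test = train_idx[fold]
            inner_train = np.delete(train_idx, fold)
            pred = _kernel_ridge_predict(
                K, np.delete(y, fold), inner_train, inner_test, delta
            )
            if pred is None:
                errors = None
                break
            errors.append(np.mean((pred - y[fold]) ** 2))
        if errors is None or not errors:
            continue
        score = float(np.mean(errors))
        if score < best_score:
            best_score, best_delta = score, float(delta)
    if best_delta is None:
        raise GBLUPError("no usable shrinkage value in the grid")
    pred = _kernel_ridge_predict(K, y, train_idx, test_idx, best_delta)
    if pred is None:
        raise GBLUPError("singular system at the selected shrinkage")
    return pred, best_delta
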