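"""Per-SNP additive and dominance effects from posterior-mean input weights.

For the one-layer, one-unit, linear network on a one-hot design, the three
first-layer weights of a marker are attached to its Hom0/Het1/Hom2 indicator
columns, so

* additive effect:  a = -E[w_Hom0] + E[w_Hom2]
* dominance effect: d =  E[w_Het1]

Deeper or nonlinear networks mix the input weights through subsequent layers
and activations, so their weights are not interpretable this way; requesting
effects from such a model raises :class:`EffectsNotIdentifiableError`.

The reported effects are regularized (dropout + weight decay) estimates:
shrinkage is not undone, so magnitudes are attenuated relative to the
generating values, exactly as in the model-averaged weight plots the method
is used for.  Posterior variances of a and d sum the Hom0/Hom2 (resp. take
the Het1) variance components; covariances between weights are not tracked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, OneHotDesign
from .network import NetArchitecture
from .posterior import PosteriorSummary


class EffectsNotIdentifiableError(ValueError):
    """Effects are defined only for the linear one-layer one-unit network."""


def _check_identifiable(arch: NetArchitecture, input_dim: int, design: OneHotDesign):
    if arch.layer_widths != (1,) or arch.activation != "linear":
        raise EffectsNotIdentifiableError(
            "SNP effects are read off first-layer weights and are only "
            "identifiable for the one-layer, one-unit, linear network; "
            "weights of deeper or nonlinear models do not map to per-marker "
            "additive/dominance effects"
        )
    if input_dim != design.n_columns:
        raise EffectsNotIdentifiableError(
            f"design has {design.n_columns} indicator columns but the model "
            f"was trained on {input_dim} inputs"
        )


def _triples(design: OneHotDesign) -> np.ndarray:
    return np.array([design.triple_map[m] for m in design.marker_ids])


def additive_effects(mean_w1: np.ndarray, design: OneHotDesign) -> np.ndarray:
    """a_j = -mean weight of Hom0 column + mean weight of Hom2 column."""
    mean_w1 = np.asarray(mean_w1, dtype=float).ravel()
    if len(mean_w1) != design.n_columns:
        raise EffectsNotIdentifiableError(
            "weight vector length does not match the one-hot design"
        )
    t = _triples(design)
    return -mean_w1[t[:, 0]] + mean_w1[t[:, 2]]


def dominance_effects(mean_w1: np.ndarray, design: OneHotDesign) -> np.ndarray:
    """d_j = mean weight of the Het1 column."""
    mean_w1 = np.asarray(mean_w1, dtype=float).ravel()
    if len(mean_w1) != design.n_columns:
        raise EffectsNotIdentifiableError(
            "weight vector length does not match the one-hot design"
        )
    return mean_w1[_triples(design)[:, 1]]


def snp_effects(
    summary: PosteriorSummary,
    design: OneHotDesign,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Effect table: marker_id, chrom, pos, a, d, var_a, var_d.

    ``genotypes`` supplies optional chrom/pos metadata for the output.
    """
    _check_identifiable(summary.arch, summary.input_dim, design)
    mean_w1 = summary.mean_net.weights[0][:, 0]
    var_w1 = summary.var_net.weights[0][:, 0]
    t = _triples(design)
    table = pd.DataFrame(
        {
            "marker_id": design.marker_ids,
            "chrom": _metadata(genotypes, design, "chrom"),
            "pos": _metadata(genotypes, design, "pos"),
            "a": additive_effects(mean_w1, design),
            "d": dominance_effects(mean_w1, design),
            "var_a": var_w1[t[:, 0]] + var_w1[t[:, 2]],
            "var_d": var_w1[t[:, 1]],
        }
    )
    return table


def _metadata(genotypes, design, field):
    if genotypes is None or getattr(genotypes, field) is None:
        return np.full(design.n_markers, "", dtype=object)
    lookup = dict(zip(genotypes.marker_ids, getattr(genotypes, field)))
    return np.array([lookup.get(m, "") for m in design.marker_ids], dtype=object)


def rank_effects(table: pd.DataFrame, top_k: int, by: str = "a") -> pd.DataFrame:
    """Top ``top_k`` rows by |effect|, ties broken by original marker order."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if by not in ("a", "d"):
        raise ValueError("rank by 'a' or 'd'")
    order = (-table[by].abs()).to_numpy()
    idx = np.argsort(order, kind="stable")  # stable sort keeps marker order on ties
    return table.iloc[idx[: min(top_k, len(table))]].reset_index(drop=True)


def write_effects(table: pd.DataFrame, path) -> None:
    """Write the effect table as TSV (Manhattan-plot friendly)."""
    table.to_csv(path, sep="\t", index=False)
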