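"""Genotype, phenotype and split containers with file I/O, filtering and encoding.

Genotypes are biallelic SNP dosages coded 0/1/2 (count of the alternate
allele).  Two on-disk dialects are supported: a plain CSV (rows = samples,
header row of marker ids, first column the sample id) and the PLINK
``--recode A`` ``.raw`` layout (whitespace-delimited, six leading
non-genotype columns, allele-suffixed marker names).

For modelling, dosages are expanded into a one-hot design of three indicator
columns per marker (Hom0, Het1, Hom2) so that both additive and dominance
signal can be represented by first-layer network weights.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLINK_RAW_LEAD_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeError(ValueError):
    """Raised when genotype/phenotype/split data violate their contracts."""


@dataclass
class GenotypeMatrix:
    """n x p integer dosage matrix with marker metadata.

    Every entry must be 0, 1 or 2; missing values are resolved (imputed)
    before construction.  ``chrom`` and ``pos`` (1-based) are optional
    metadata and never enter any computation.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-d array")
        n, p = self.dosages.shape
        if n < 1 or p < 1:
            raise GenotypeError("need at least one sample and one marker")
        if len(self.sample_ids) != n:
            raise GenotypeError("sample_ids length does not match dosage rows")
        if len(self.marker_ids) != p:
            raise GenotypeError("marker_ids length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("sample_ids are not unique")
        if len(set(self.marker_ids)) != p:
            raise GenotypeError("marker_ids are not unique")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.dosages, (0, 1, 2)))[0]
            raise GenotypeError(
                f"dosage {self.dosages[bad[0], bad[1]]!r} at sample "
                f"{self.sample_ids[bad[0]]!r}, marker {self.marker_ids[bad[1]]!r} "
                "is not in {0, 1, 2}"
            )
        self.dosages = self.dosages.astype(np.int8)
        for name in ("chrom", "pos"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value)
                if len(value) != p:
                    raise GenotypeError(f"{name} length does not match marker count")
                setattr(self, name, value)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to a boolean/index marker selection."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            sample_ids=self.sample_ids,
            marker_ids=self.marker_ids[keep],
            chrom=None if self.chrom is None else self.chrom[keep],
            pos=None if self.pos is None else self.pos[keep],
        )


@dataclass
class OneHotDesign:
    """n x 3p indicator expansion of a GenotypeMatrix.

    Column triple (3j, 3j+1, 3j+2) of marker j holds the (Hom0, Het1, Hom2)
    indicators; exactly one of the three is 1 in every row.
    """

    indicators: np.ndarray
    marker_ids: np.ndarray
    triple_map: dict = field(repr=False)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_columns(self) -> int:
        return self.indicators.shape[1]


@dataclass
class PhenotypeVector:
    """One finite trait value per sample, aligned by sample id."""

    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise GenotypeError("phenotype values and sample_ids must align 1:1")
        if not np.isfinite(self.values).all():
            raise GenotypeError("phenotype values must be finite")


@dataclass
class SplitPlan:
    """Train/test roles, or k-fold assignments, one per sample."""

    sample_ids: np.ndarray
    roles: np.ndarray | None = None
    folds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if (self.roles is None) == (self.folds is None):
            raise GenotypeError("provide exactly one of roles or folds")
        if self.roles is not None:
            self.roles = np.asarray(self.roles, dtype=object)
            if len(self.roles) != len(self.sample_ids):
                raise GenotypeError("roles must align with sample_ids")
            if not set(self.roles) <= {"train", "test"}:
                raise GenotypeError("roles must be 'train' or 'test'")
            if (self.roles == "train").sum() == 0 or (self.roles == "test").sum() == 0:
                raise GenotypeError("both train and test sets must be non-empty")
        else:
            self.folds = np.asarray(self.folds, dtype=int)
            if len(self.folds) != len(self.sample_ids):
                raise GenotypeError("folds must align with sample_ids")
            if self.n_folds < 2:
                raise GenotypeError("k-fold split needs at least 2 folds")

    @property
    def n_folds(self) -> int:
        if self.folds is None:
            return 0
        return int(self.folds.max()) + 1

    def masks(self, fold: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_mask, test_mask) boolean arrays over samples."""
        if self.roles is not None:
            test = self.roles == "test"
        else:
            if fold is None:
                raise GenotypeError("fold index required for a k-fold plan")
            test = self.folds == fold
        return ~test, test


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------

def _check_rectangular(path, delimiter: str | None) -> None:
    """Fail early, naming the line, if any row width differs from the header."""
    with open(path, newline="") as fh:
        if delimiter is None:
            rows = (line.split() for line in fh)
        else:
            rows = csv.reader(fh, delimiter=delimiter)
        try:
            width = len(next(rows))
        except StopIteration:
            raise GenotypeError(f"{path}: file is empty") from None
        for lineno, row in enumerate(rows, start=2):
            if len(row) == 0:
                continue
            if len(row) != width:
                raise GenotypeError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {width}"
                )


def _parse_dosage_block(
    raw: pd.DataFrame, sample_ids, marker_ids, missing: str
) -> np.ndarray:
    """Parse a string dosage block, imputing missing entries per marker."""
    values = raw.to_numpy(dtype=object)
    flat = values.astype(str)
    is_missing = (flat == missing) | (flat == "nan")
    parsed = np.full(values.shape, -1, dtype=float)
    for token, dosage in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        parsed[flat == token] = dosage
    bad = np.argwhere((parsed < 0) & ~is_missing)
    if len(bad):
        i, j = bad[0]
        raise GenotypeError(
            f"non-biallelic dosage {values[i, j]!r} at sample {sample_ids[i]!r}, "
            f"marker {marker_ids[j]!r} (expected 0/1/2 or {missing!r})"
        )
    n_imputed = int(is_missing.sum())
    if n_imputed:
        frac = is_missing.mean(axis=0)
        for j in np.flatnonzero(frac > 0.10):
            warnings.warn(
                f"marker {marker_ids[j]!r}: {frac[j]:.1%} missing dosages",
                stacklevel=3,
            )
        parsed[is_missing] = np.nan
        col_mean = np.nanmean(np.where(is_missing, np.nan, parsed), axis=0)
        if np.isnan(col_mean).any():
            j = int(np.flatnonzero(np.isnan(col_mean))[0])
            raise GenotypeError(f"marker {marker_ids[j]!r} has no observed dosages")
        fill = np.clip(np.rint(col_mean), 0, 2)
        ii, jj = np.nonzero(is_missing)
        parsed[ii, jj] = fill[jj]
        logger.info("imputed %d missing dosages to rounded per-marker means", n_imputed)
    return parsed.astype(np.int8)


def read_genotypes(path, dialect: str = "csv", missing: str = "NA") -> GenotypeMatrix:
    """Read a dosage matrix from ``csv`` or ``plink_raw`` files.

    Missing dosages (token ``missing``, default ``NA``) are imputed to the
    rounded per-marker mean; the imputation count is logged and markers with
    more than 10% missingness trigger a warning.
    """
    if dialect == "csv":
        _check_rectangular(path, ",")
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        sample_ids = df.index.to_numpy(dtype=object)
        marker_ids = df.columns.to_numpy(dtype=object)
        block = df
    elif dialect == "plink_raw":
        _check_rectangular(path, None)
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = tuple(df.columns[: len(PLINK_RAW_LEAD_COLUMNS)])
        if lead != PLINK_RAW_LEAD_COLUMNS:
            raise GenotypeError(
                f"{path}: not a PLINK .raw header (leading columns {lead})"
            )
        sample_ids = df["IID"].to_numpy(dtype=object)
        block = df.iloc[:, len(PLINK_RAW_LEAD_COLUMNS):]
        # strip the counted-allele suffix PLINK appends, e.g. "snp1_A" -> "snp1"
        marker_ids = np.array(
            [c.rsplit("_", 1)[0] if "_" in c else c for c in block.columns],
            dtype=object,
        )
    else:
        raise GenotypeError(f"unknown genotype dialect {dialect!r}")
    dosages = _parse_dosage_block(block, sample_ids, marker_ids, missing)
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, marker_ids=marker_ids)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_phenotypes(path) -> PhenotypeVector:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise GenotypeError(f"{path}: phenotype file must have 2 columns")
    return PhenotypeVector(
        values=df.iloc[:, 1].to_numpy(dtype=float),
        sample_ids=df.iloc[:, 0].to_numpy(dtype=object),
    )


def write_phenotypes(y: PhenotypeVector, path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "value": y.values}).to_csv(
        path, index=False
    )


def align_phenotypes(y: PhenotypeVector, G: GenotypeMatrix) -> np.ndarray:
    """Return phenotype values ordered to match ``G.sample_ids`` exactly."""
    index = {s: i for i, s in enumerate(y.sample_ids)}
    try:
        order = [index[s] for s in G.sample_ids]
    except KeyError as err:
        raise GenotypeError(f"sample {err.args[0]!r} has no phenotype") from None
    return y.values[order]


def read_split(path) -> SplitPlan:
    df = pd.read_csv(path, dtype=str)
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    col = df.iloc[:, 1]
    if set(col) <= {"train", "test"}:
        return SplitPlan(sample_ids=ids, roles=col.to_numpy(dtype=object))
    return SplitPlan(sample_ids=ids, folds=col.to_numpy(dtype=int))


def write_split(plan: SplitPlan, path) -> None:
    second = plan.roles if plan.roles is not None else plan.folds
    pd.DataFrame({"sample_id": plan.sample_ids, "role": second}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# filtering, encoding, splitting
# ---------------------------------------------------------------------------

def minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF = min(f, 1-f) with f the mean dosage / 2."""
    f = G.dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers whose MAF is below ``threshold`` (order preserved)."""
    if not 0.0 <= threshold <= 0.5:
        raise GenotypeError("MAF threshold must be in [0, 0.5]")
    keep = minor_allele_frequency(G) >= threshold
    if not keep.any():
        raise GenotypeError(f"MAF filter at {threshold} removed every marker")
    if keep.all():
        return G
    return G.subset_markers(keep)


def one_hot_encode(G: GenotypeMatrix) -> OneHotDesign:
    """Expand dosages into (Hom0, Het1, Hom2) indicator triples."""
    n, p = G.dosages.shape
    indicators = np.zeros((n, 3 * p))
    cols = 3 * np.arange(p)[None, :] + G.dosages
    indicators[np.arange(n)[:, None], cols] = 1.0
    triple_map = {
        m: (3 * j, 3 * j + 1, 3 * j + 2) for j, m in enumerate(G.marker_ids)
    }
    return OneHotDesign(
        indicators=indicators, marker_ids=G.marker_ids.copy(), triple_map=triple_map
    )


def decode_one_hot(design: OneHotDesign) -> np.ndarray:
    """Invert :func:`one_hot_encode`: per-triple argmax recovers the dosages."""
    n = design.indicators.shape[0]
    return design.indicators.reshape(n, design.n_markers, 3).argmax(axis=2)


def make_split(
    sample_ids,
    *,
    groups=None,
    test_groups=None,
    k: int | None = None,
    seed: int | None = None,
) -> SplitPlan:
    """Build a holdout (by group label) or seeded k-fold split plan.

    For k-fold, samples are permuted with ``seed`` and divided into folds
    whose sizes differ by at most one.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    n = len(sample_ids)
    if k is not None:
        if not 2 <= k <= n:
            raise GenotypeError("k must be between 2 and the sample count")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for i, chunk in enumerate(np.array_split(order, k)):
            folds[chunk] = i
        return SplitPlan(sample_ids=sample_ids, folds=folds)
    if groups is None or test_groups is None:
        raise GenotypeError("provide either k or (groups, test_groups)")
    groups = np.asarray(groups, dtype=object)
    if len(groups) != n:
        raise GenotypeError("groups must align with sample_ids")
    test_groups = set(test_groups)
    roles = np.where(np.isin(groups, list(test_groups)), "test", "train")
    return SplitPlan(sample_ids=sample_ids, roles=roles.astype(object))
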