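import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwpnet import (
    GenotypeError,
    GenotypeMatrix,
    PhenotypeVector,
    align_phenotypes,
    decode_one_hot,
    maf_filter,
    make_split,
    minor_allele_frequency,
    one_hot_encode,
    read_genotypes,
    read_phenotypes,
    read_split,
    write_genotypes,
    write_phenotypes,
    write_split,
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_read_csv_parses_dosages(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("sample_id,m1,m2\na,0,1\nb,2,0\nc,1,2\n")
    G = read_genotypes(path)
    assert G.dosages.shape == (3, 2)
    assert list(G.sample_ids) == ["a", "b", "c"]
    assert list(G.marker_ids) == ["m1", "m2"]
    assert G.dosages[2, 1] == 2


def test_read_csv_rejects_non_biallelic_entry(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("sample_id,m1,m2\na,0,1\nb,3,0\n")
    with pytest.raises(GenotypeError, match="'3'.*'b'.*'m1'"):
        read_genotypes(path)


def test_read_csv_names_ragged_line(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("sample_id,m1,m2\na,0,1\nb,2\n")
    with pytest.raises(GenotypeError, match="line 3"):
        read_genotypes(path)


def test_read_plink_raw_strips_allele_suffix(tmp_path):
    path = tmp_path / "g.raw"
    path.write_text(
        "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_T\n"
        "f1 i1 0 0 1 -9 0 2\n"
        "f2 i2 0 0 2 -9 1 NA\n"
    )
    with pytest.warns(UserWarning, match="snp2"):  # 1 of 2 dosages missing
        G = read_genotypes(path, dialect="plink_raw")
    assert list(G.marker_ids) == ["snp1", "snp2"]
    assert list(G.sample_ids) == ["i1", "i2"]
    # the missing snp2 dosage imputes to the rounded marker mean (2)
    assert G.dosages[1, 1] == 2


def test_read_plink_raw_rejects_foreign_header(tmp_path):
    path = tmp_path / "g.raw"
    path.write_text("A B C D E F snp1_A\nx y 0 0 1 -9 0\n")
    with pytest.raises(GenotypeError, match="header"):
        read_genotypes(path, dialect="plink_raw")


def test_missing_imputation_warns_above_ten_percent(tmp_path):
    rows = ["sample_id,m1,m2"]
    rows += [f"s{i},NA,1" for i in range(3)]
    rows += [f"s{i},0,1" for i in range(3, 20)]
    path = tmp_path / "g.csv"
    path.write_text("\n".join(rows) + "\n")
    with pytest.warns(UserWarning, match="m1"):
        G = read_genotypes(path)
    assert (G.dosages[:3, 0] == 0).all()  # rounded mean of observed zeros


def test_genotype_roundtrip(tmp_path, tiny_genotypes):
    path = tmp_path / "g.csv"
    write_genotypes(tiny_genotypes, path)
    G = read_genotypes(path)
    assert np.array_equal(G.dosages, tiny_genotypes.dosages)


def test_matrix_invariants_enforced():
    with pytest.raises(GenotypeError, match="not in"):
        GenotypeMatrix(
            dosages=np.array([[0, 3]]),
            sample_ids=np.array(["a"]),
            marker_ids=np.array(["m1", "m2"]),
        )
    with pytest.raises(GenotypeError, match="unique"):
        GenotypeMatrix(
            dosages=np.array([[0], [1]]),
            sample_ids=np.array(["a", "a"]),
            marker_ids=np.array(["m1"]),
        )


# ---------------------------------------------------------------------------
# MAF filtering
# ---------------------------------------------------------------------------

def test_maf_filter_thresholds():
    n = 1000
    dosages = np.zeros((n, 3), dtype=int)
    dosages[:500, 1] = 1  # MAF 0.25
    dosages[:22, 2] = 1  # mean dosage 0.022 -> MAF 0.011
    G = GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        marker_ids=np.array(["mono", "common", "rare"], dtype=object),
    )
    kept = maf_filter(G, 0.01)
    assert list(kept.marker_ids) == ["common", "rare"]  # monomorphic removed
    assert list(maf_filter(G, 0.0).marker_ids) == ["mono", "common", "rare"]
    with pytest.raises(GenotypeError, match="every marker"):
        maf_filter(G, 0.5)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_maf_filter_idempotent(seed):
    rng = np.random.default_rng(seed)
    n, p = 30, 8
    G = GenotypeMatrix(
        dosages=rng.integers(0, 3, size=(n, p)),
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(p)], dtype=object),
    )
    try:
        once = maf_filter(G, 0.1)
    except GenotypeError:
        return
    twice = maf_filter(once, 0.1)
    assert np.array_equal(once.dosages, twice.dosages)
    assert list(once.marker_ids) == list(twice.marker_ids)


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

def test_one_hot_triples(tiny_genotypes):
    design = one_hot_encode(tiny_genotypes)
    assert design.indicators.shape == (4, 9)
    # dosage column [0,1,2,...] of marker m1 maps to the canonical triples
    np.testing.assert_array_equal(design.indicators[0, :3], [1, 0, 0])
    np.testing.assert_array_equal(design.indicators[1, :3], [0, 1, 0])
    np.testing.assert_array_equal(design.indicators[2, :3], [0, 0, 1])
    assert design.triple_map["m2"] == (3, 4, 5)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_one_hot_roundtrip_and_row_sums(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 12))
    p = int(rng.integers(1, 9))
    G = GenotypeMatrix(
        dosages=rng.integers(0, 3, size=(n, p)),
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(p)], dtype=object),
    )
    design = one_hot_encode(G)
    assert design.indicators.shape == (n, 3 * p)
    # exactly one indicator per marker per row
    np.testing.assert_array_equal(design.indicators.sum(axis=1), np.full(n, p))
    np.testing.assert_array_equal(decode_one_hot(design), G.dosages)


# ---------------------------------------------------------------------------
# phenotypes and splits
# ---------------------------------------------------------------------------

def test_phenotype_roundtrip_and_alignment(tmp_path, tiny_genotypes):
    y = PhenotypeVector(
        values=np.array([4.0, 3.0, 2.0, 1.0]),
        sample_ids=np.array(["s4", "s3", "s2", "s1"], dtype=object),
    )
    path = tmp_path / "y.csv"
    write_phenotypes(y, path)
    aligned = align_phenotypes(read_phenotypes(path), tiny_genotypes)
    np.testing.assert_array_equal(aligned, [1.0, 2.0, 3.0, 4.0])
    missing = PhenotypeVector(
        values=np.array([1.0]), sample_ids=np.array(["s1"], dtype=object)
    )
    with pytest.raises(GenotypeError, match="s2"):
        align_phenotypes(missing, tiny_genotypes)


def test_kfold_sizes_differ_by_at_most_one():
    ids = [f"s{i}" for i in range(3141)]
    plan = make_split(ids, k=5, seed=0)
    sizes = sorted(np.bincount(plan.folds), reverse=True)
    assert sizes == [629, 628, 628, 628, 628]


def test_split_determinism_and_holdout():
    ids = [f"s{i}" for i in range(50)]
    a = make_split(ids, k=4, seed=11)
    b = make_split(ids, k=4, seed=11)
    assert np.array_equal(a.folds, b.folds)
    groups = ["g1"] * 30 + ["g2"] * 20
    plan = make_split(ids, groups=groups, test_groups=["g2"])
    train_mask, test_mask = plan.masks()
    assert train_mask.sum() == 30 and test_mask.sum() == 20
    with pytest.raises(GenotypeError, match="non-empty"):
        make_split(ids, groups=["g1"] * 50, test_groups=["g2"])


def test_split_roundtrip(tmp_path):
    ids = [f"s{i}" for i in range(10)]
    plan = make_split(ids, k=3, seed=2)
    path = tmp_path / "split.csv"
    write_split(plan, path)
    back = read_split(path)
    assert np.array_equal(back.folds, plan.folds)


def test_minor_allele_frequency_definition(tiny_genotypes):
    # f = mean(dosage)/2 per marker; MAF folds frequencies above 0.5
    maf = minor_allele_frequency(tiny_genotypes)
    np.testing.assert_allclose(maf, [3 / 8, 3 / 8, 3 / 8])
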