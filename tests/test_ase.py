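"""TPM, the NB allelic test, BH adjustment, and 5-way categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hapase import (
    CATEGORIES,
    ClassificationThresholds,
    allele_de_test,
    bh_adjust,
    call_ase,
    category_specific_pairs,
    classify_pair,
    compute_tpm,
)
from hapase.ase import size_factors

THR = ClassificationThresholds()


# -- TPM ---------------------------------------------------------------------

def test_tpm_single_gene_is_one_million():
    counts = pd.DataFrame({"s1": [7]}, index=["g1"])
    tpm = compute_tpm(counts, pd.Series({"g1": 1500.0}))
    assert tpm.loc["g1", "s1"] == pytest.approx(1e6)


def test_tpm_hand_example():
    counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
    tpm = compute_tpm(counts, pd.Series({"g1": 1000.0, "g2": 2000.0}))
    assert tpm.loc["g1", "s1"] == pytest.approx(666666.67, abs=0.01)
    assert tpm.loc["g2", "s1"] == pytest.approx(333333.33, abs=0.01)


def test_tpm_columns_sum_to_one_million():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 500, size=(40, 6)))
    counts.iloc[:, 3] = 0  # degenerate all-zero sample
    lengths = pd.Series(rng.integers(500, 5000, size=40).astype(float))
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = compute_tpm(counts, lengths)
    sums = tpm.sum(axis=0)
    assert np.allclose(sums.drop(3), 1e6)
    assert sums[3] == 0.0


def test_tpm_rejects_bad_lengths():
    counts = pd.DataFrame({"s1": [1]}, index=["g1"])
    with pytest.raises(ValueError):
        compute_tpm(counts, pd.Series({"g1": 0.0}))


# -- allelic NB test ---------------------------------------------------------

def test_identical_replicates_are_null():
    a = np.tile([50.0, 60.0, 55.0], (20, 1))
    res = allele_de_test(a, a)
    assert np.allclose(res["log2fc"], 0.0)
    assert (res["p"] > 0.9).all()


def test_null_pvalues_uniform_ks():
    """Raw p on 10,000 null pairs (NB mu=100, alpha=0.1, 3 reps) pass a
    Kolmogorov-Smirnov uniformity check at alpha = 0.01."""
    rng = np.random.default_rng(2024)
    r = 10.0  # 1/alpha
    p_nb = r / (r + 100.0)
    a = rng.negative_binomial(r, p_nb, size=(10_000, 3)).astype(float)
    g = rng.negative_binomial(r, p_nb, size=(10_000, 3)).astype(float)
    res = allele_de_test(a, g)
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01
    # type-I control after BH
    assert (bh_adjust(res["p"]) <= 0.05).mean() <= 0.05 + 0.01


def test_power_on_eight_fold_difference():
    """A ~ NB(800, 0.05) vs G ~ NB(100, 0.05), 3 reps: p < 1e-4 in >= 99%."""
    rng = np.random.default_rng(5)
    r = 20.0
    a = rng.negative_binomial(r, r / (r + 800.0), size=(1000, 3)).astype(float)
    g = rng.negative_binomial(r, r / (r + 100.0), size=(1000, 3)).astype(float)
    res = allele_de_test(a, g)
    assert (res["p"] < 1e-4).mean() >= 0.99


def test_single_replicate_untestable():
    res = allele_de_test(np.array([[10.0]]), np.array([[30.0]]))
    assert np.isnan(res["p"]).all()
    assert np.isfinite(res["log2fc"]).all()


def test_scale_equivariance_of_log2fc():
    """Rescaling each sample's counts (at fixed geometric mean) is undone by
    median-of-ratios normalization, leaving log2fc invariant."""
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(10, 1000, size=(200, 6)).astype(float))
    factors = rng.uniform(0.5, 2.0, size=6)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    rescaled = counts.mul(factors, axis=1)
    norm = counts.div(size_factors(counts), axis=1)
    norm2 = rescaled.div(size_factors(rescaled), axis=1)
    assert np.allclose(norm.to_numpy(), norm2.to_numpy())
    a1 = allele_de_test(norm.iloc[:100].to_numpy(), norm.iloc[100:].to_numpy())
    a2 = allele_de_test(norm2.iloc[:100].to_numpy(), norm2.iloc[100:].to_numpy())
    assert np.allclose(a1["log2fc"], a2["log2fc"])


# -- BH ----------------------------------------------------------------------

def bh_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_single_and_tied_values_unchanged():
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_step_up_oracle(p):
    got = bh_adjust(p)
    assert np.allclose(got, bh_oracle(p))
    assert (got >= np.asarray(p) - 1e-12).all()  # padj >= p


# -- categorization ----------------------------------------------------------

LOW = np.array([0.1, 0.2, 0.1])
HIGH = np.array([40.0, 55.0, 38.0])


@pytest.mark.parametrize(
    "tpm_a,tpm_g,padj,fc,expected",
    [
        (HIGH, HIGH, 0.01, 10.0, "Diff8"),
        (HIGH, HIGH, 0.20, 20.0, "Diff00"),
        (LOW, LOW, 0.01, 3.0, "NE"),
        (HIGH, LOW, 0.01, 2.0, "Diff0"),   # FC = 2 boundary -> Diff0
        (HIGH, LOW, 0.01, 8.0, "Diff8"),   # FC = 8 boundary -> Diff8
        (HIGH, LOW, 0.01, 5.0, "Diff2"),
        (HIGH, LOW, 0.05, 5.0, "Diff2"),   # padj = alpha is significant
        (HIGH, LOW, np.nan, 5.0, "Diff00"),  # untestable
    ],
)
def test_classification_examples(tpm_a, tpm_g, padj, fc, expected):
    assert classify_pair(tpm_a, tpm_g, padj, fc, THR) == expected


def test_categories_partition_all_calls():
    """Every (padj, fc, expression) combination maps to exactly one of the
    five categories, and lowering alpha never moves Diff00 into an ASE class."""
    rng = np.random.default_rng(8)
    for _ in range(500):
        expressed = rng.random() < 0.8
        tpm = HIGH * rng.random() if expressed else LOW * rng.random()
        padj = float(rng.random())
        fc = float(2.0 ** (4 * rng.random()))
        cat = classify_pair(tpm, tpm, padj, fc, THR)
        assert cat in CATEGORIES
        strict = ClassificationThresholds(alpha=0.01)
        cat_strict = classify_pair(tpm, tpm, padj, fc, strict)
        if cat == "Diff00":
            assert cat_strict in ("Diff00", "NE")


def test_category_specific_pairs_brute_force():
    rng = np.random.default_rng(11)
    pair_ids = [f"p{i}" for i in range(50)]
    rows = []
    for pid in pair_ids:
        for cond in range(4):
            rows.append(
                {
                    "pair_id": pid,
                    "tissue": f"t{cond % 2}",
                    "treatment": f"x{cond // 2}",
                    "category": rng.choice(CATEGORIES, p=[0.1, 0.45, 0.15, 0.2, 0.1]),
                }
            )
    calls = pd.DataFrame(rows)
    exclusive, matrix = category_specific_pairs(calls)
    # brute-force oracle: count distinct categories per pair
    for pid in pair_ids:
        cats = set(calls.loc[calls["pair_id"] == pid, "category"])
        for c in CATEGORIES:
            assert (pid in exclusive[c]) == (cats == {c})
    assert matrix.shape == (50, 4)


def test_call_ase_end_to_end(small_dataset):
    ds = small_dataset
    calls = call_ase(ds.counts, ds.lengths, ds.samples, ds.pairs_truth)
    n_cond = ds.samples.groupby(["tissue", "treatment"]).ngroups
    assert len(calls) == len(ds.pairs_truth) * n_cond
    assert set(calls["category"]) <= set(CATEGORIES)
    assert (calls["padj"] >= calls["p"] - 1e-12).all()
    assert np.allclose(calls["fc"], 2.0 ** np.abs(calls["log2fc"]))
    # planted-unexpressed pairs are never called an ASE class; at this small
    # library size a single stray count can exceed the TPM threshold, so the
    # remainder land in Diff00 rather than NE
    ne_truth = ds.truth.loc[~ds.truth["expressed"], "pair_id"]
    ne_calls = calls.loc[calls["pair_id"].isin(ne_truth), "category"]
    assert set(ne_calls) <= {"NE", "Diff00"}
    assert (ne_calls == "NE").mean() >= 0.5
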