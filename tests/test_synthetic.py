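"""The synthetic-data generator: determinism, planted effects, count law,
and agreement between planted truth and re-extracted features."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hapase import (
    SyntheticConfig,
    generate_dataset,
    planted_truth,
)
from hapase.ase import ClassificationThresholds, category_from_ratio
from hapase.features import CATALOG
from hapase.io import write_dataset
from hapase.pipeline import extract_pair_features


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_pairs=0)
    with pytest.raises(ValueError):
        SyntheticConfig(replicates_per_condition=1)
    with pytest.raises(ValueError):
        SyntheticConfig(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        SyntheticConfig(tissues=())
    with pytest.raises(ValueError):
        SyntheticConfig(frac_unexpressed_pairs=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(effect_sizes={"not_a_feature": 1.0})


def test_zero_effects_zero_noise_gives_zero_ratios():
    cfg = SyntheticConfig(n_pairs=40, effect_sizes={}, ratio_noise_sd=0.0,
                          frac_null_pairs=0.0, seed=5)
    ds = generate_dataset(cfg, with_tracks=False)
    assert (ds.truth["planted_log2_ratio"] == 0.0).all()
    expressed = ds.truth["expressed"]
    assert (ds.truth.loc[expressed, "expected_category"] == "Diff00").all()
    assert (ds.truth.loc[~expressed, "expected_category"] == "NE").all()


def test_structural_invariants():
    ds = generate_dataset(SyntheticConfig(n_pairs=200, seed=1), with_tracks=False)
    assert len(ds.pairs_truth) == 200
    all_genes = [g.gene_id for g in ds.genes_a] + [g.gene_id for g in ds.genes_g]
    assert len(set(all_genes)) == 400  # every gene in exactly one pair
    assert set(ds.pairs_truth["gene_a"]) == {g.gene_id for g in ds.genes_a}
    assert ds.counts.shape == (400, len(ds.samples))
    assert (ds.counts.to_numpy() >= 0).all()
    assert set(ds.truth["expected_category"]) <= {"NE", "Diff00", "Diff0", "Diff2", "Diff8"}


def test_reproducibility_byte_identical(tmp_path):
    cfg = SyntheticConfig(n_pairs=30, seed=9)
    d1 = tmp_path / "run1"
    d2 = tmp_path / "run2"
    write_dataset(generate_dataset(cfg), d1)
    write_dataset(generate_dataset(cfg), d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    for name in files1:
        h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
        h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
        assert h1 == h2, name


def test_counts_follow_configured_nb_law():
    """Replicate variance of null pairs matches mu + alpha*mu^2 on average."""
    cfg = SyntheticConfig(
        n_pairs=4000, effect_sizes={}, ratio_noise_sd=0.0, frac_null_pairs=0.0,
        frac_unexpressed_pairs=0.0, tissues=("leaf",), treatments=("NH",),
        replicates_per_condition=6, nb_dispersion=0.1, seed=2,
    )
    ds = generate_dataset(cfg, with_tracks=False)
    a = ds.counts.iloc[:4000].to_numpy(dtype=float)
    g = ds.counts.iloc[4000:].to_numpy(dtype=float)
    x = np.hstack([a, g])  # 12 iid draws per pair (ratio = 0)
    mu_hat = x.mean(axis=1)
    var_hat = x.var(axis=1, ddof=1)
    expected = mu_hat + cfg.nb_dispersion * mu_hat**2
    keep = mu_hat > 5
    ratio = (var_hat[keep] / expected[keep]).mean()
    assert 0.85 < ratio < 1.15


def test_dominant_effect_drives_the_ratio():
    """Top-decile |planted mCHG_gene| pairs carry much larger |log2 ratios|
    than bottom-decile pairs when mCHG_gene is the only effect."""
    cfg = SyntheticConfig(
        n_pairs=1500, effect_sizes={"mCHG_gene": 2.0}, ratio_noise_sd=0.1,
        frac_null_pairs=0.0, frac_unexpressed_pairs=0.0, seed=3,
    )
    ds = generate_dataset(cfg, with_tracks=False)
    t = ds.truth
    q10, q90 = t["mCHG_gene"].quantile([0.1, 0.9])
    low = t.loc[t["mCHG_gene"] <= q10, "planted_log2_ratio"].abs().mean()
    high = t.loc[t["mCHG_gene"] >= q90, "planted_log2_ratio"].abs().mean()
    # both deciles sit far from the feature mean, so both carry signal after
    # standardization; the top decile must still clearly exceed the bottom
    assert high > 1.2 * low


def test_planted_truth_category_rules():
    thr = ClassificationThresholds()
    assert category_from_ratio(0.0, thr) == "Diff00"
    assert category_from_ratio(3.5, thr) == "Diff8"
    assert category_from_ratio(-3.5, thr) == "Diff8"
    assert category_from_ratio(0.7, thr) == "Diff0"   # FC 1.6 <= 2
    assert category_from_ratio(1.0, thr) == "Diff0"   # FC = 2 boundary
    assert category_from_ratio(2.0, thr) == "Diff2"
    assert category_from_ratio(5.0, thr, expressed=False) == "NE"

    ds = generate_dataset(SyntheticConfig(n_pairs=25, seed=8), with_tracks=False)
    strict = planted_truth(ds, ClassificationThresholds(fc_low=1.5, fc_high=4.0))
    default = planted_truth(ds)
    # tighter FC bins can only move pairs toward higher categories
    order = {c: i for i, c in enumerate(["NE", "Diff00", "Diff0", "Diff2", "Diff8"])}
    moved = [
        order[s] >= order[d]
        for s, d in zip(strict["expected_category"], default["expected_category"])
    ]
    assert all(moved)


def test_extracted_features_match_planted_truth():
    """Feature extraction from the generated tracks recovers the planted
    values: exactly for interval/sequence features, r >= 0.95 for methylation
    (site-level binomial sampling is the only noise source)."""
    cfg = SyntheticConfig(
        n_pairs=80, seed=13,
        methylation_site_spacing=6, methylation_mean_coverage=80,
    )
    ds = generate_dataset(cfg)
    extracted = extract_pair_features(
        ds.pairs_truth, ds.genes_a, ds.genes_g, ds.cds,
        ds.methylation_a, ds.methylation_g, ds.te_a, ds.te_g,
        ds.tfbs_a, ds.tfbs_g,
    ).set_index("pair_id")
    truth = ds.truth.set_index("pair_id")

    exact = [
        "TE_shared_number", "TE_unique_number", "TE_gene_distance",
        "TE_occupation_upstream10kb", "TE_occupation_downstream2kb",
        "TE_length_inside_exon", "TE_number_inside_intron",
        "TFBS_shared", "TFBS_unique",
        "Gene_length", "Exon_length", "Intron_length", "Exon_number", "Intron_number",
        "Ka", "Ks",
    ]
    for col in exact:
        got = extracted[col]
        want = truth[col]
        mask = np.isfinite(want)
        assert np.allclose(got[mask], want[mask]), col

    for col in ["mCG_gene", "mCHG_gene", "mCHH_gene", "mCG_upstream", "mCHH_downstream"]:
        mask = np.isfinite(truth[col]) & np.isfinite(extracted[col])
        r = np.corrcoef(truth.loc[mask, col], extracted.loc[mask, col])[0, 1]
        assert r >= 0.95, (col, r)


def test_truth_feature_table_shape_and_classes():
    ds = generate_dataset(SyntheticConfig(n_pairs=120, seed=4), with_tracks=False)
    table = ds.truth_feature_table()
    n_cond = 6  # 3 tissues x 2 treatments
    n_expressed = int(ds.truth["expressed"].sum())
    assert len(table) == n_expressed * n_cond
    assert list(table.columns[:46]) == CATALOG.names
    assert np.isfinite(table[CATALOG.numeric_names].to_numpy()).all()
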