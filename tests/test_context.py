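"""Interval arithmetic: methylation means, TE occupancy/affinity, TFBS
sharing, and the breakpoint randomization test — checked against per-base
brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapase import (
    FlankSpec,
    MethylIndex,
    breakpoint_te_randomization,
    gene_flank,
    nearest_te_distance,
    region_methylation_mean,
    te_occupancy,
    te_pair_features,
    tfbs_pair_features,
)
from hapase.context import merge_intervals
from hapase.pairing import GeneModel


def make_sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "context", "n_methylated", "n_total"])
    df["frequency"] = df["n_methylated"] / df["n_total"]
    return df


def make_tes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "te_class", "superfamily", "family"])


def gene(gid="g1", chrom="c1", strand="+", start=10_001, end=13_000,
         exons=((10_001, 11_000), (12_001, 13_000))):
    return GeneModel(gid, "A", chrom, strand, start, end, exons)


# -- methylation -------------------------------------------------------------

def test_region_mean_and_coverage_filter():
    sites = make_sites([
        ("c1", 101, "+", "CG", 2, 10),   # 0.2
        ("c1", 151, "+", "CG", 4, 10),   # 0.4
        ("c1", 171, "+", "CG", 4, 4),    # below 5-read floor -> excluded
        ("c1", 181, "+", "CHH", 10, 10),  # other context
        ("c2", 121, "+", "CG", 10, 10),  # other chromosome
    ])
    assert region_methylation_mean(sites, "c1", 0, 1000, "CG") == pytest.approx(0.3)
    assert np.isnan(region_methylation_mean(sites, "c1", 0, 1000, "CHG"))
    # coverage-weighted alternative
    w = region_methylation_mean(sites, "c1", 0, 1000, "CG", coverage_weighted=True)
    assert w == pytest.approx((2 + 4) / 20)


def test_methyl_index_matches_reference_operation():
    rng = np.random.default_rng(4)
    rows = []
    for _ in range(400):
        rows.append((
            "c1", int(rng.integers(1, 5000)), "+",
            rng.choice(["CG", "CHG", "CHH"]),
            0, int(rng.integers(1, 30)),
        ))
    sites = make_sites([(c, p, s, x, int(rng.integers(0, t + 1)), t) for c, p, s, x, _, t in rows])
    idx = MethylIndex(sites, min_coverage=5)
    for start, end in [(0, 5000), (100, 400), (2500, 2600), (4999, 5000)]:
        for context in ("CG", "CHG", "CHH"):
            ref = region_methylation_mean(sites, "c1", start, end, context)
            got = idx.mean("c1", (start, end), context)
            if np.isnan(ref):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(ref)


# -- occupancy / distance ----------------------------------------------------

def brute_force_coverage(intervals, start, end):
    covered = np.zeros(end - start, dtype=bool)
    for s, e in intervals:
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            covered[lo - start : hi - start] = True
    return covered.sum()


def test_occupancy_examples():
    assert te_occupancy((0, 1000), make_tes([]), "c1") == 0.0
    tes = make_tes([("c1", 100, 200, "LTR", "Gypsy", "Gypsy"),
                    ("c1", 150, 300, "LTR", "Copia", "Copia")])
    assert te_occupancy((0, 1000), tes, "c1") == pytest.approx(0.2)
    assert te_occupancy((0, 1000), make_tes([("c1", 0, 5000, "LTR", "Gypsy", "Gypsy")]), "c1") == 1.0


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(0, 9900), st.integers(1, 600)), max_size=15),
    st.integers(0, 5000),
    st.integers(1, 5000),
)
def test_occupancy_matches_per_base_brute_force(iv, start, width):
    end = start + width
    tes = make_tes([("c1", s, s + w, "LTR", "Gypsy", "Gypsy") for s, w in iv])
    expected = brute_force_coverage([(s, s + w) for s, w in iv], start, end) / width
    assert te_occupancy((start, end), tes, "c1") == pytest.approx(expected)
    merged = merge_intervals([(s, s + w) for s, w in iv])
    assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))


def test_nearest_te_distance_coordinate_conversion():
    g = gene(start=1001, end=2000, exons=((1001, 2000),))
    # gene ends at 1-based 2000 (half-open 2000); TE starts at 0-based 2100
    tes = make_tes([("c1", 2100, 2400, "LTR", "Gypsy", "Gypsy")])
    assert nearest_te_distance(g, tes) == 100
    assert nearest_te_distance(g, make_tes([("c1", 1500, 1600, "L", "G", "G")])) == 0
    assert np.isnan(nearest_te_distance(g, make_tes([("c2", 0, 10, "L", "G", "G")])))


# -- flanks / strand ---------------------------------------------------------

def test_flank_strand_awareness():
    plus = gene(strand="+")
    minus = gene(strand="-")
    assert gene_flank(plus, FlankSpec("upstream", 2000)) == (8000, 10000)
    assert gene_flank(plus, FlankSpec("downstream", 2000)) == (13000, 15000)
    # reversing the strand swaps upstream and downstream exactly
    assert gene_flank(minus, FlankSpec("upstream", 2000)) == gene_flank(plus, FlankSpec("downstream", 2000))
    assert gene_flank(minus, FlankSpec("downstream", 2000)) == gene_flank(plus, FlankSpec("upstream", 2000))
    # clipping at the chromosome start
    near_start = gene(start=501, end=1500, exons=((501, 1500),))
    assert gene_flank(near_start, FlankSpec("upstream", 2000)) == (0, 500)


def test_te_pair_features_identity_and_planted_difference():
    ga = gene("a1")
    gg = gene("g1")
    tes = make_tes([("c1", 9000, 9500, "LTR", "Copia", "Copia"),
                    ("c1", 12_100, 12_300, "DNA", "MITE", "MITE")])
    same = te_pair_features(ga, gg, tes, tes)
    diff_keys = [k for k in same if k not in ("TE_shared_number",)]
    assert all(same[k] == 0 for k in diff_keys)
    assert same["TE_shared_number"] == 2

    # a Gypsy insertion in A's upstream 2 kb only
    tes_a = pd.concat([tes, make_tes([("c1", 8200, 8900, "LTR", "Gypsy", "Gypsy")])], ignore_index=True)
    out = te_pair_features(ga, gg, tes_a, tes)
    assert out["TE_unique_number"] == 1
    assert out["TE_occupation_upstream2kb"] > 0


def test_te_exon_overlap_matches_brute_force():
    ga = gene("a1", exons=((10_001, 11_000), (11_501, 12_000), (12_501, 13_000)), end=13_000)
    gg = gene("g1", exons=((10_001, 13_000),), end=13_000)
    tes_a = make_tes([("c1", 10_500, 11_600, "LTR", "Gypsy", "Gypsy"),
                      ("c1", 12_900, 13_200, "DNA", "MITE", "MITE")])
    tes_g = make_tes([])
    out = te_pair_features(ga, gg, tes_a, tes_g)
    exon_overlap = sum(
        brute_force_coverage([(10_500, 11_600), (12_900, 13_200)], s - 1, e)
        for s, e in ga.exons
    )
    assert out["TE_length_inside_exon"] == exon_overlap
    assert out["TE_number_inside_exon"] == 3  # all three exons hit
    intron_overlap = sum(
        brute_force_coverage([(10_500, 11_600), (12_900, 13_200)], s - 1, e)
        for s, e in ga.introns
    )
    assert out["TE_length_inside_intron"] == intron_overlap


def test_tfbs_set_arithmetic():
    ga, gg = gene("a1"), gene("g1")

    def hits(motifs):
        return pd.DataFrame(
            [("c1", 8100 + 20 * i, 8112 + 20 * i, m, 9.9, 1e-6) for i, m in enumerate(motifs)],
            columns=["chrom", "start", "end", "motif_id", "score", "p_value"],
        )

    assert tfbs_pair_features(ga, gg, hits(["MYB1", "WRKY2"]), hits(["MYB1"])) == (1, 1)
    assert tfbs_pair_features(ga, gg, hits(["M1", "M2"]), hits(["M1", "M2"])) == (2, 0)
    assert tfbs_pair_features(ga, gg, hits([]), hits([])) == (0, 0)
    # hits outside the upstream window are ignored
    far = pd.DataFrame([("c1", 20_000, 20_012, "FAR1", 9.9, 1e-6)],
                       columns=["chrom", "start", "end", "motif_id", "score", "p_value"])
    assert tfbs_pair_features(ga, gg, far, far) == (0, 0)


# -- randomization test ------------------------------------------------------

def test_randomization_observed_matches_brute_force():
    rng = np.random.default_rng(9)
    starts = rng.integers(0, 99_000, size=20)
    tes = make_tes([("c1", int(s), int(s) + int(rng.integers(100, 900)), "LTR", "Gypsy", "Gypsy")
                    for s in starts])
    bps = pd.DataFrame({"chrom": ["c1"] * 10, "position": rng.integers(200, 99_800, size=10)})
    res = breakpoint_te_randomization(bps, tes, {"c1": 100_000}, window=150, n_perm=19, seed=1)
    # brute force per-base window overlap
    expected = 0
    for p in bps["position"]:
        lo, hi = max(0, p - 1 - 150), min(100_000, p - 1 + 151)
        expected += int(
            any(s < hi and e > lo for s, e in zip(tes["start"], tes["end"]))
        )
    assert res["observed"] == expected
    assert 1 / 20 <= res["p"] <= 1.0


def test_randomization_planted_signal_gives_minimal_p():
    bps = pd.DataFrame({"chrom": ["c1"] * 8, "position": np.arange(10_000, 90_000, 10_000)})
    tes = make_tes([("c1", int(p) - 10, int(p) + 10, "LTR", "Gypsy", "Gypsy") for p in bps["position"]])
    res = breakpoint_te_randomization(bps, tes, {"c1": 10_000_000}, window=150, n_perm=99, seed=2)
    assert res["observed"] == 8
    assert res["p"] == pytest.approx(1 / 100)


def test_randomization_null_calibration():
    """With uniformly placed TEs the empirical p is approximately uniform.

    The scenario uses enough windows and TEs that the overlap count has real
    resolution; the >= tie convention still biases p slightly upward, which
    the tolerance accommodates.
    """
    rng = np.random.default_rng(3)
    bps = pd.DataFrame(
        {"chrom": ["c1"] * 60, "position": rng.integers(1000, 999_000, size=60)}
    )
    ps = []
    for k in range(200):
        starts = rng.integers(0, 998_000, size=150)
        tes = make_tes([("c1", int(s), int(s) + 1000, "LTR", "Gypsy", "Gypsy") for s in starts])
        res = breakpoint_te_randomization(bps, tes, {"c1": 1_000_000}, window=150, n_perm=49, seed=k)
        ps.append(res["p"])
    assert abs(np.mean(ps) - 0.5) < 0.1
    assert min(ps) >= 1 / 50
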