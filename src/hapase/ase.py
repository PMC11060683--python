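"""Allele expression quantification, allelic differential-expression testing,
and the five-way ASE categorization (NE / Diff00 / Diff0 / Diff2 / Diff8).

A pair x condition call is NE when neither allele passes the TPM expression
threshold in any replicate of that condition; otherwise Diff00 when the
BH-adjusted p exceeds alpha, and Diff0 / Diff2 / Diff8 by unsigned fold
change (FC <= 2, 2 < FC < 8, FC >= 8).

The allelic test is a negative-binomial Wald-type test on median-of-ratios
normalized counts: per-pair method-of-moments dispersions are shrunk toward a
mean-dispersion trend alpha(mu) = a0/mu + a1 fitted across all pairs, and the
statistic compares the two allele means with a 0.5 continuity correction on
the summed-count scale (which keeps the null p-values uniform at small
replicate numbers); two-sided p from the standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClassificationThresholds",
    "CATEGORIES",
    "compute_tpm",
    "size_factors",
    "allele_de_test",
    "bh_adjust",
    "classify_pair",
    "category_from_ratio",
    "call_ase",
    "category_specific_pairs",
]

CATEGORIES = ("NE", "Diff00", "Diff0", "Diff2", "Diff8")

#: response classes used for modeling (NE rows are excluded)
MODEL_CLASSES = ("Diff00", "Diff0", "Diff2", "Diff8")


@dataclass(frozen=True)
class ClassificationThresholds:
    expressed_tpm: float = 0.5
    alpha: float = 0.05
    fc_low: float = 2.0
    fc_high: float = 8.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (1.0 < self.fc_low < self.fc_high):
            raise ValueError("need 1 < fc_low < fc_high")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a genes x samples count matrix.

    rate_i = count_i / length_i(kb); TPM_i = 1e6 * rate_i / sum(rates).
    An all-zero sample yields an all-zero column (with a warning).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise KeyError(f"genes without effective length, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style) per sample."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    finite = np.isfinite(log).all(axis=1)
    if not finite.any():
        warnings.warn("no gene has positive counts in every sample; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    ref = log[finite].mean(axis=1)
    sf = np.exp(np.median(log[finite] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0/mu + a1 across pairs."""
    mu_safe = np.maximum(mu, floor)
    X = np.column_stack([1.0 / mu_safe, np.ones_like(mu_safe)])
    coef, *_ = np.linalg.lstsq(X, alpha_mom, rcond=None)
    return np.maximum(X @ coef, floor)


def allele_de_test(
    counts_a: np.ndarray,
    counts_g: np.ndarray,
    pseudocount: float = 0.5,
    shrink_weight: float = 0.2,
    continuity: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial allelic test on normalized replicate counts.

    ``counts_a`` / ``counts_g`` are (n_pairs, n_replicates) arrays of
    size-factor-normalized counts (1-D input is treated as a single pair).
    Returns a DataFrame with columns log2fc, p, mean_a, mean_g, dispersion.
    Pairs need >= 2 replicates per allele; otherwise p is NaN (untestable).
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    g = np.atleast_2d(np.asarray(counts_g, dtype=float))
    if a.shape[0] != g.shape[0]:
        raise ValueError("allele count matrices disagree on the number of pairs")
    na, ng = a.shape[1], g.shape[1]
    ma, mg = a.mean(axis=1), g.mean(axis=1)
    log2fc = np.log2((ma + pseudocount) / (mg + pseudocount))
    if na < 2 or ng < 2:
        return pd.DataFrame(
            {"log2fc": log2fc, "p": np.nan, "mean_a": ma, "mean_g": mg, "dispersion": np.nan}
        )
    va = a.var(axis=1, ddof=1)
    vg = g.var(axis=1, ddof=1)
    mp = 0.5 * (ma + mg)
    vpool = 0.5 * (va + vg)
    mu_safe = np.maximum(mp, dispersion_floor)
    alpha_mom = np.maximum((vpool - mp) / mu_safe**2, dispersion_floor)
    alpha_trend = _dispersion_trend(mp, alpha_mom, dispersion_floor)
    alpha_hat = shrink_weight * alpha_mom + (1.0 - shrink_weight) * alpha_trend
    v = (mp + alpha_hat * mp**2)
    var_diff = v / na + v / ng
    cc = continuity * 0.5 * (1.0 / na + 1.0 / ng)
    z = np.maximum(np.abs(ma - mg) - cc, 0.0) / np.sqrt(np.maximum(var_diff, 1e-300))
    p = 2.0 * stats.norm.sf(z)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "mean_a": ma, "mean_g": mg, "dispersion": alpha_hat}
    )


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unadjusted."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def classify_pair(
    tpm_a: np.ndarray,
    tpm_g: np.ndarray,
    padj: float,
    fc: float,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> str:
    """Category of one pair x condition from replicate TPMs, padj and FC.

    ``fc`` is the unsigned fold change 2**|log2fc| (>= 1).
    """
    if fc < 1.0:
        raise ValueError("fc must be the unsigned fold change (>= 1)")
    tpm_a = np.asarray(tpm_a, dtype=float)
    tpm_g = np.asarray(tpm_g, dtype=float)
    t = thresholds
    if (tpm_a <= t.expressed_tpm).all() and (tpm_g <= t.expressed_tpm).all():
        return "NE"
    if not np.isfinite(padj) or padj > t.alpha:
        return "Diff00"
    if fc <= t.fc_low:
        return "Diff0"
    if fc < t.fc_high:
        return "Diff2"
    return "Diff8"


def category_from_ratio(
    log2_ratio: float,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    expressed: bool = True,
) -> str:
    """Noise-free expected category for a planted log2 allelic ratio.

    Unexpressed pairs are NE; an exactly-zero ratio is Diff00 (no allelic
    signal to detect); otherwise the FC bins apply with significance assumed.
    """
    if not expressed:
        return "NE"
    if log2_ratio == 0.0:
        return "Diff00"
    fc = 2.0 ** abs(log2_ratio)
    if fc <= thresholds.fc_low:
        return "Diff0"
    if fc < thresholds.fc_high:
        return "Diff2"
    return "Diff8"


def call_ase(
    counts: pd.DataFrame,
    lengths: pd.Series,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Full per-condition ASE calling over a pair table.

    ``samples`` has columns sample_id, tissue, treatment, replicate; a
    condition is one (tissue, treatment).  Testing is per condition with BH
    adjustment pooled within the condition; the expression (NE) rule uses TPM
    in that condition's replicates.

    Returns one row per pair x condition with columns pair_id, tissue,
    treatment, mean_tpm_a, mean_tpm_g, log2fc, fc, p, padj, category.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    missing = [s for s in samples.index if s not in counts.columns]
    if missing:
        raise KeyError(f"samples without count columns: {missing[:5]}")
    tpm = compute_tpm(counts, lengths)
    rows = []
    for (tissue, treatment), cond in samples.groupby(["tissue", "treatment"], sort=True):
        cols = list(cond.index)
        sub = counts[cols]
        sf = size_factors(sub)
        norm = sub.div(sf, axis=1)
        a = norm.loc[pairs["gene_a"]].to_numpy()
        g = norm.loc[pairs["gene_g"]].to_numpy()
        res = allele_de_test(a, g, pseudocount=thresholds.pseudocount)
        padj = bh_adjust(res["p"].to_numpy())
        tpm_a = tpm.loc[pairs["gene_a"], cols].to_numpy()
        tpm_g = tpm.loc[pairs["gene_g"], cols].to_numpy()
        fc = 2.0 ** np.abs(res["log2fc"].to_numpy())
        for i, pair_id in enumerate(pairs["pair_id"]):
            rows.append(
                {
                    "pair_id": pair_id,
                    "tissue": tissue,
                    "treatment": treatment,
                    "mean_tpm_a": float(tpm_a[i].mean()),
                    "mean_tpm_g": float(tpm_g[i].mean()),
                    "log2fc": float(res["log2fc"].iloc[i]),
                    "fc": float(fc[i]),
                    "p": float(res["p"].iloc[i]),
                    "padj": float(padj[i]),
                    "category": classify_pair(tpm_a[i], tpm_g[i], padj[i], fc[i], thresholds),
                }
            )
    return pd.DataFrame(rows)


def category_specific_pairs(calls: pd.DataFrame) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Category-exclusive pair sets across conditions plus the full matrix.

    A pair is exclusive to category c iff its set of categories over all its
    conditions equals {c}.  Returns ({category: sorted pair ids}, matrix)
    where the matrix is pair_id x condition with category entries.
    """
    cond = calls["tissue"].astype(str) + ":" + calls["treatment"].astype(str)
    matrix = calls.assign(condition=cond).pivot(
        index="pair_id", columns="condition", values="category"
    )
    exclusive: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for pair_id, row in matrix.iterrows():
        cats = set(row.dropna())
        if len(cats) == 1:
            exclusive[cats.pop()].append(pair_id)
    for c in exclusive:
        exclusive[c].sort()
    return exclusive, matrix
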