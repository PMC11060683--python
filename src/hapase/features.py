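"""The 46-feature predictor catalog and feature-table assembly.

Six feature categories: (1) 21 methylation differences — 7 regions {gene
body, exons, introns, upstream 2 kb, downstream 2 kb, first exon, first
intron} x 3 contexts {CG, CHG, CHH}; (2) 9 TE occupancy/affinity features;
(3) 8 sequence-divergence features (lengths, Ka, Ks, Ka/Ks, TFBS sharing);
(4) 6 structural features (exon/intron counts and TE-in-gene overlap);
(5) Tissue; (6) Treatment.  All between-allele numeric features are absolute
differences; Tissue and Treatment are integer-coded categoricals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureCatalog",
    "CATALOG",
    "MODEL1_FEATURES",
    "methylation_feature_name",
    "assemble_features",
    "correlation_thin",
    "encode_categoricals",
]

METHYL_REGIONS = (
    "gene",
    "exon",
    "intron",
    "upstream",
    "downstream",
    "first_exon",
    "first_intron",
)
METHYL_CONTEXTS = ("CG", "CHG", "CHH")

CATEGORY_NAMES = {
    1: "methylation_difference",
    2: "te_occupancy_affinity",
    3: "sequence_divergence",
    4: "structural_divergence",
    5: "tissue",
    6: "treatment",
}


def methylation_feature_name(context: str, region: str) -> str:
    return f"m{context}_{region}"


def _build_catalog() -> list[tuple[str, int, str]]:
    entries: list[tuple[str, int, str]] = []
    for region in METHYL_REGIONS:
        for ctx in METHYL_CONTEXTS:
            entries.append(
                (
                    methylation_feature_name(ctx, region),
                    1,
                    f"|delta| mean {ctx} methylation frequency, {region} region",
                )
            )
    entries += [
        ("TE_gene_distance", 2, "|delta| distance from gene to nearest TE (bp)"),
        ("TE_shared_number", 2, "TE families shared by both alleles (upstream 2kb + gene body)"),
        ("TE_unique_number", 2, "TE families unique to one allele (symmetric difference)"),
        ("TE_occupation_upstream2kb", 2, "|delta| TE coverage fraction, upstream 2 kb"),
        ("TE_occupation_upstream5kb", 2, "|delta| TE coverage fraction, upstream 5 kb"),
        ("TE_occupation_upstream10kb", 2, "|delta| TE coverage fraction, upstream 10 kb"),
        ("TE_occupation_downstream2kb", 2, "|delta| TE coverage fraction, downstream 2 kb"),
        ("TE_occupation_downstream5kb", 2, "|delta| TE coverage fraction, downstream 5 kb"),
        ("TE_occupation_downstream10kb", 2, "|delta| TE coverage fraction, downstream 10 kb"),
        ("Gene_length", 3, "|delta| gene span length (bp)"),
        ("Exon_length", 3, "|delta| summed exon length (bp)"),
        ("Intron_length", 3, "|delta| summed intron length (bp)"),
        ("Ka", 3, "nonsynonymous substitutions per nonsynonymous site"),
        ("Ks", 3, "synonymous substitutions per synonymous site"),
        ("Ka_Ks", 3, "Ka/Ks ratio (missing when Ks = 0)"),
        ("TFBS_shared", 3, "TFBS motifs shared in upstream 2 kb"),
        ("TFBS_unique", 3, "TFBS motifs unique to one allele in upstream 2 kb"),
        ("Exon_number", 4, "|delta| exon count"),
        ("Intron_number", 4, "|delta| intron count"),
        ("TE_number_inside_exon", 4, "|delta| count of exons overlapping >= 1 TE"),
        ("TE_length_inside_exon", 4, "|delta| TE-overlap length within exons (bp)"),
        ("TE_number_inside_intron", 4, "|delta| count of introns overlapping >= 1 TE"),
        ("TE_length_inside_intron", 4, "|delta| TE-overlap length within introns (bp)"),
        ("Tissue", 5, "tissue of the RNA-seq sample (integer-coded)"),
        ("Treatment", 6, "treatment of the RNA-seq sample (integer-coded)"),
    ]
    return entries


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered catalog of the 46 predictors and their 6 categories."""

    entries: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        cats = {e[1] for e in self.entries}
        if len(names) != 46 or len(set(names)) != 46:
            raise AssertionError("feature catalog must hold exactly 46 unique features")
        if cats != set(range(1, 7)):
            raise AssertionError("feature catalog must span exactly categories 1-6")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def numeric_names(self) -> list[str]:
        return [e[0] for e in self.entries if e[0] not in ("Tissue", "Treatment")]

    @property
    def categorical_names(self) -> list[str]:
        return ["Tissue", "Treatment"]

    def category_of(self, name: str) -> int:
        for n, c, _ in self.entries:
            if n == name:
                return c
        raise KeyError(name)

    def n_categories(self) -> int:
        return len({e[1] for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "category", "description"]).assign(
            category_name=lambda d: d["category"].map(CATEGORY_NAMES)
        )


CATALOG = FeatureCatalog(tuple(_build_catalog()))

#: the 15-predictor preset of the reduced 4-class model
MODEL1_FEATURES = [
    "mCHG_gene",
    "Ks",
    "Ka_Ks",
    "TE_occupation_upstream10kb",
    "TE_occupation_downstream10kb",
    "Exon_length",
    "Gene_length",
    "mCHH_downstream",
    "mCHH_upstream",
    "TE_gene_distance",
    "TFBS_shared",
    "TE_length_inside_exon",
    "Tissue",
    "Treatment",
    "TE_shared_number",
]

RESPONSE_COLUMNS = ["category", "tpm_diff"]


def encode_categoricals(
    table: pd.DataFrame, columns: Sequence[str] = ("Tissue", "Treatment")
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Deterministic integer codes from sorted labels; returns the mapping."""
    out = table.copy()
    mappings: dict[str, dict[str, int]] = {}
    for col in columns:
        labels = sorted(out[col].astype(str).unique())
        mapping = {lab: i for i, lab in enumerate(labels)}
        out[col] = out[col].astype(str).map(mapping)
        mappings[col] = mapping
    return out, mappings


def assemble_features(
    pairs: pd.DataFrame,
    ase_calls: pd.DataFrame,
    pair_features: pd.DataFrame,
    impute: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """One modeling row per (pair, condition) with a non-NE call.

    ``pair_features`` is one row per pair_id carrying all 44 numeric
    predictors (methylation, TE, divergence, structure, TFBS); Tissue and
    Treatment come from the call's condition and are integer-coded.  Missing
    numeric values (undefined Ka/Ks, methylation regions without qualifying
    sites, TE-free chromosomes) are imputed by column median, with the
    missingness recorded in the returned report.

    Returns (table, report); the table is indexed pair_id:tissue:treatment
    and carries exactly the 46 catalog predictors plus the responses
    ``category`` and ``tpm_diff``.
    """
    numeric = CATALOG.numeric_names
    feats = pair_features.set_index("pair_id") if "pair_id" in pair_features.columns else pair_features
    missing_pairs = sorted(set(ase_calls["pair_id"]) - set(feats.index))
    if missing_pairs:
        raise KeyError(f"pairs without feature rows: {missing_pairs[:10]}")
    absent = [c for c in numeric if c not in feats.columns]
    if absent:
        raise KeyError(f"feature columns missing from pair_features: {absent}")

    calls = ase_calls.loc[ase_calls["category"] != "NE"].copy()
    table = feats.loc[calls["pair_id"], numeric].reset_index(drop=True)
    table["Tissue"] = calls["tissue"].to_numpy()
    table["Treatment"] = calls["treatment"].to_numpy()
    table, mappings = encode_categoricals(table)
    table["category"] = calls["category"].to_numpy()
    table["tpm_diff"] = np.abs(
        calls["mean_tpm_a"].to_numpy() - calls["mean_tpm_g"].to_numpy()
    )
    table.index = (
        calls["pair_id"].astype(str)
        + ":"
        + calls["tissue"].astype(str)
        + ":"
        + calls["treatment"].astype(str)
    )
    table.index.name = "row_id"
    table = table[CATALOG.names + RESPONSE_COLUMNS]

    missingness = {}
    if impute:
        for col in numeric:
            n_missing = int(table[col].isna().sum())
            if n_missing:
                med = float(table[col].median())
                if not np.isfinite(med):
                    med = 0.0
                table[col] = table[col].fillna(med)
                missingness[col] = {"n_imputed": n_missing, "median": med}
    report = {
        "n_rows": int(len(table)),
        "n_predictors": len(CATALOG.names),
        "n_feature_categories": CATALOG.n_categories(),
        "categorical_codes": mappings,
        "imputation": missingness,
    }
    return table, report


def correlation_thin(
    table: pd.DataFrame,
    importance_ranking: Sequence[str],
    r_threshold: float = 0.7,
    p_threshold: float = 0.001,
) -> list[str]:
    """Importance-guided correlation thinning of the numeric predictors.

    Features are visited in descending importance; a feature is dropped when
    it is strongly correlated (|Pearson r| >= r_threshold with two-sided
    p < p_threshold) with an already-retained, higher-ranked feature.
    Categorical predictors (Tissue, Treatment) are always retained; constant
    columns have undefined correlations and are kept with a warning.
    """
    numeric = [f for f in importance_ranking if f in CATALOG.numeric_names]
    unknown = [f for f in CATALOG.numeric_names if f not in importance_ranking and f in table.columns]
    # features never ranked (e.g. zero importance) go last, in catalog order
    order = numeric + unknown
    kept: list[str] = []
    for f in order:
        if f not in table.columns:
            raise KeyError(f"feature {f!r} absent from table")
        x = table[f].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"{f}: constant column, correlation undefined; retained")
            kept.append(f)
            continue
        drop = False
        for g in kept:
            y = table[g].to_numpy(dtype=float)
            if np.nanstd(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            if abs(r) >= r_threshold and p < p_threshold:
                drop = True
                break
        if not drop:
            kept.append(f)
    return kept + [c for c in CATALOG.categorical_names if c in table.columns]
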