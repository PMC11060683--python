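"""Synthetic haplotype-pair datasets with planted, configurable ASE effects.

The generator emulates the structure of a haplotype-resolved diploid
transcriptomics study: paired gene models on two haplotypes (A and G) sharing
a chromosome layout, per-site CG/CHG/CHH methylation frequencies, TE
landscapes, TFBS hit tables, and negative-binomial expression counts over a
tissue x treatment x replicate sample grid.

Per pair, every catalog feature receives a planted value; the planted log2
allelic ratio is sum_f beta_f * z(feature_f) + Normal(0, ratio_noise_sd),
where z() standardizes the planted feature differences across pairs so that
effect sizes are comparable across heterogeneous units.  Allele counts are
drawn negative-binomially around the haplotype means implied by the ratio.
A configurable fraction of pairs is unexpressed on both alleles (NB mean 0.05
counts per replicate) and a fraction carries an exactly-zero ratio, so the
noise-free expected categories span all of NE/Diff00/Diff0/Diff2/Diff8.

Planted TE, TFBS, divergence and structural values are computed from the
generated annotations with the same operations the extraction stage uses, so
truth and extraction agree exactly; methylation truth is the analytic mean of
per-site true levels, which site-level binomial sampling then blurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import context as ctx
from .ase import ClassificationThresholds, category_from_ratio, compute_tpm
from .divergence import CodonAlignment, compute_ka_ks
from .features import CATALOG, encode_categoricals, methylation_feature_name
from .pairing import GeneModel

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "planted_truth"]

_NONSTOP_CODONS = None  # filled lazily


@dataclass(frozen=True)
class SyntheticConfig:
    n_pairs: int = 300
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    mean_gene_length: int = 3000
    exons_per_gene: tuple[int, int] = (2, 6)
    effect_sizes: dict = field(
        default_factory=lambda: {
            # planted drivers mirror the reported importance ordering
            "mCHG_gene": 1.0,
            "Ks": 0.8,
            "Ka_Ks": 0.6,
            "TE_occupation_upstream10kb": 0.5,
            "TE_occupation_downstream10kb": 0.4,
        }
    )
    baseline_log2_expression: float = 6.5
    nb_dispersion: float = 0.1
    ratio_noise_sd: float = 0.8
    frac_unexpressed_pairs: float = 0.05
    frac_null_pairs: float = 0.30
    tissues: tuple[str, ...] = ("leaf", "root", "internode")
    treatments: tuple[str, ...] = ("NH", "BR")
    replicates_per_condition: int = 3
    methylation_site_spacing: int = 30
    methylation_mean_coverage: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not self.tissues or not self.treatments:
            raise ValueError("tissue and treatment lists must be non-empty")
        for frac in (self.frac_unexpressed_pairs, self.frac_null_pairs):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.ratio_noise_sd < 0:
            raise ValueError("ratio_noise_sd must be >= 0")
        unknown = set(self.effect_sizes) - set(CATALOG.numeric_names)
        if unknown:
            raise ValueError(f"effect_sizes reference unknown features: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes_a: list
    genes_g: list
    cds: dict
    pairs_truth: pd.DataFrame
    methylation_a: Optional[pd.DataFrame]
    methylation_g: Optional[pd.DataFrame]
    te_a: pd.DataFrame
    te_g: pd.DataFrame
    tfbs_a: pd.DataFrame
    tfbs_g: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    truth: pd.DataFrame
    chrom_lengths: dict

    def truth_feature_table(
        self, thresholds: ClassificationThresholds = ClassificationThresholds()
    ) -> pd.DataFrame:
        """Modeling table built from planted truth: one row per expressed
        pair x condition, the 46 catalog predictors, and the responses
        ``category`` (noise-free expected) and ``tpm_diff`` (realized)."""
        numeric = CATALOG.numeric_names
        truth = self.truth.set_index("pair_id")
        tpm = compute_tpm(self.counts, self.lengths)
        sm = self.samples.set_index("sample_id")
        rows = []
        for (tissue, treatment), cond in sm.groupby(["tissue", "treatment"], sort=True):
            cols = list(cond.index)
            ta = tpm.loc[self.pairs_truth["gene_a"], cols].mean(axis=1).to_numpy()
            tg = tpm.loc[self.pairs_truth["gene_g"], cols].mean(axis=1).to_numpy()
            for i, pair_id in enumerate(self.pairs_truth["pair_id"]):
                rec = truth.loc[pair_id]
                if not rec["expressed"]:
                    continue
                row = {f: rec[f] for f in numeric}
                row.update(
                    {
                        "row_id": f"{pair_id}:{tissue}:{treatment}",
                        "Tissue": tissue,
                        "Treatment": treatment,
                        "category": rec["expected_category"],
                        "tpm_diff": abs(ta[i] - tg[i]),
                    }
                )
                rows.append(row)
        table = pd.DataFrame(rows).set_index("row_id")
        table, _ = encode_categoricals(table)
        for col in numeric:  # impute the planted NaNs (Ka/Ks undefined etc.)
            if table[col].isna().any():
                med = table[col].median()
                table[col] = table[col].fillna(med if np.isfinite(med) else 0.0)
        return table[CATALOG.names + ["category", "tpm_diff"]]


def _nonstop_codons() -> list[str]:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        import itertools

        from .divergence import _aa

        _NONSTOP_CODONS = [
            "".join(c)
            for c in itertools.product("TCAG", repeat=3)
            if _aa("".join(c)) != "*"
        ]
    return _NONSTOP_CODONS


_TFBS_COLUMNS = ["chrom", "start", "end", "motif_id", "score", "p_value"]

_TE_FAMILIES = ["Gypsy", "Copia", "LTR_unknown", "MITE", "hAT", "LINE"]
_TE_WEIGHTS = [0.30, 0.20, 0.15, 0.15, 0.10, 0.10]
_TE_CLASS = {
    "Gypsy": "LTR",
    "Copia": "LTR",
    "LTR_unknown": "LTR",
    "MITE": "DNA",
    "hAT": "DNA",
    "LINE": "LINE",
}

_METHYL_BASE = {"CG": 0.50, "CHG": 0.22, "CHH": 0.03}
_METHYL_WITHIN_SD = {"CG": 0.10, "CHG": 0.08, "CHH": 0.015}
_METHYL_DIFF_SD = {"CG": 0.10, "CHG": 0.10, "CHH": 0.02}


def _make_exons(rng: np.random.Generator, cfg: SyntheticConfig, start: int) -> list[tuple[int, int]]:
    lo, hi = cfg.exons_per_gene
    k = int(rng.integers(lo, hi + 1))
    mean_exon = max(120, int(0.7 * cfg.mean_gene_length / k))
    mean_intron = max(80, int(0.3 * cfg.mean_gene_length / max(k - 1, 1)))
    exons = []
    pos = start
    for j in range(k):
        elen = int(rng.integers(int(0.5 * mean_exon), int(1.5 * mean_exon) + 1))
        exons.append((pos, pos + elen - 1))
        pos += elen
        if j < k - 1:
            pos += int(rng.integers(int(0.5 * mean_intron), int(1.5 * mean_intron) + 1))
    return exons


def _perturb_exons(
    rng: np.random.Generator, exons: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Structural perturbation of the G copy: resize, drop or append an exon."""
    exons = [list(e) for e in exons]
    action = rng.random()
    if action < 0.45:
        pass  # identical structure
    elif action < 0.80:
        j = int(rng.integers(0, len(exons)))
        delta = int(rng.integers(-100, 301))
        s, e = exons[j]
        exons[j] = [s, max(s + 50, e + delta)]
        shift = exons[j][1] - e
        for jj in range(j + 1, len(exons)):
            exons[jj][0] += shift
            exons[jj][1] += shift
    elif action < 0.90 and len(exons) > 1:
        exons.pop()
    else:
        last = exons[-1]
        gap = int(rng.integers(80, 401))
        elen = int(rng.integers(100, 401))
        exons.append([last[1] + gap + 1, last[1] + gap + elen])
    return [tuple(e) for e in exons]


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    from .divergence import _aa

    mask = rng.random(len(cds)) < rate
    if not mask.any():
        return cds
    seq = list(cds)
    bases = "TCAG"
    for pos in np.flatnonzero(mask):
        others = [b for b in bases if b != seq[pos]]
        alt = others[int(rng.integers(0, 3))]
        c0 = 3 * (pos // 3)
        trial = seq[c0 : c0 + 3]
        trial[pos - c0] = alt
        if _aa("".join(trial)) != "*":  # never introduce a stop
            seq[pos] = alt
    return "".join(seq)


def _site_grid(start: int, end: int, spacing: int, offset: int) -> np.ndarray:
    """Deterministic 0-based site positions in [start, end)."""
    first = start + offset
    if first >= end:
        return np.array([start], dtype=int) if end > start else np.array([], dtype=int)
    return np.arange(first, end, spacing, dtype=int)


class _MethylPlan:
    """Per-gene true methylation levels by region class, for one haplotype."""

    def __init__(self, gene: GeneModel, levels: dict, spacing: int):
        self.gene = gene
        self.levels = levels  # keys: ("upstream"|"downstream"|("exon",j)|("intron",j)) -> {ctx: level}
        self.spacing = spacing

    def _regions(self) -> list[tuple[object, int, int]]:
        g = self.gene
        s0, e0 = g.start - 1, g.end
        up = ctx.gene_flank(g, ctx.FlankSpec("upstream", 2000))
        down = ctx.gene_flank(g, ctx.FlankSpec("downstream", 2000))
        out = [("upstream", *up), ("downstream", *down)]
        for j, (es, ee) in enumerate(g.exons):
            out.append((("exon", j), es - 1, ee))
        for j, (is_, ie) in enumerate(g.introns):
            out.append((("intron", j), is_ - 1, ie))
        return out

    def site_counts(self, contexts=("CG", "CHG", "CHH")) -> dict:
        counts = {}
        for key, s, e in self._regions():
            counts[key] = {
                c: len(_site_grid(s, e, self.spacing, 7 * i))
                for i, c in enumerate(contexts)
            }
        return counts

    def planted_means(self) -> dict:
        """Analytic regional mean true levels per (region name, context)."""
        counts = self.site_counts()
        out = {}
        for context in _METHYL_BASE:
            exon_keys = [k for k in self.levels if isinstance(k, tuple) and k[0] == "exon"]
            intron_keys = [k for k in self.levels if isinstance(k, tuple) and k[0] == "intron"]

            def wmean(keys):
                w = np.array([counts[k][context] for k in keys], dtype=float)
                v = np.array([self.levels[k][context] for k in keys], dtype=float)
                if w.sum() == 0:
                    return float("nan")
                return float(np.average(v, weights=w))

            out[("upstream", context)] = self.levels["upstream"][context]
            out[("downstream", context)] = self.levels["downstream"][context]
            out[("exon", context)] = wmean(exon_keys)
            out[("intron", context)] = wmean(intron_keys) if intron_keys else float("nan")
            out[("gene", context)] = wmean(exon_keys + intron_keys)
            out[("first_exon", context)] = self.levels[("exon", 0)][context]
            out[("first_intron", context)] = (
                self.levels[("intron", 0)][context] if intron_keys else float("nan")
            )
        return out

    def emit_sites(self, rng: np.random.Generator, mean_coverage: int) -> pd.DataFrame:
        rows = {c: [] for c in ("chrom", "position", "strand", "context", "n_methylated", "n_total")}
        for key, s, e in self._regions():
            for i, context in enumerate(_METHYL_BASE):
                pos = _site_grid(s, e, self.spacing, 7 * i)
                if len(pos) == 0:
                    continue
                level = self.levels[key][context]
                n_total = 5 + rng.poisson(max(mean_coverage - 5, 1), size=len(pos))
                n_meth = rng.binomial(n_total, level)
                rows["chrom"].extend([self.gene.chrom] * len(pos))
                rows["position"].extend((pos + 1).tolist())  # back to 1-based
                rows["strand"].extend(["+"] * len(pos))
                rows["context"].extend([context] * len(pos))
                rows["n_methylated"].extend(n_meth.tolist())
                rows["n_total"].extend(n_total.tolist())
        df = pd.DataFrame(rows)
        df["frequency"] = df["n_methylated"] / df["n_total"]
        return df


def _methyl_levels_pair(rng: np.random.Generator, gene_a: GeneModel, gene_g: GeneModel):
    """Correlated true levels for both haplotypes of one pair."""
    keys_a = ["upstream", "downstream"] + [("exon", j) for j in range(len(gene_a.exons))] + [
        ("intron", j) for j in range(len(gene_a.introns))
    ]
    keys_g = ["upstream", "downstream"] + [("exon", j) for j in range(len(gene_g.exons))] + [
        ("intron", j) for j in range(len(gene_g.introns))
    ]
    levels_a: dict = {}
    levels_g: dict = {}
    for key in sorted(set(keys_a) | set(keys_g), key=str):
        la, lg = {}, {}
        for context in _METHYL_BASE:
            base = np.clip(
                _METHYL_BASE[context] + rng.normal(0, _METHYL_WITHIN_SD[context]), 0.01, 0.99
            )
            diff = rng.normal(0, _METHYL_DIFF_SD[context])
            la[context] = float(np.clip(base + diff / 2, 0.01, 0.99))
            lg[context] = float(np.clip(base - diff / 2, 0.01, 0.99))
        if key in keys_a:
            levels_a[key] = la
        if key in keys_g:
            levels_g[key] = lg
    return levels_a, levels_g


def _gen_te_pair(
    rng: np.random.Generator, gene_a: GeneModel, gene_g: GeneModel
) -> tuple[list[tuple], list[tuple]]:
    """TE rows (chrom, start, end, class, superfamily, family) per haplotype."""
    lo = max(0, gene_a.start - 1 - 10_000)
    hi = max(gene_a.end, gene_g.end) + 10_000

    def draw(n):
        starts = rng.integers(lo, max(lo + 1, hi - 200), size=n)
        lens = rng.integers(200, 3001, size=n)
        fams = rng.choice(_TE_FAMILIES, size=n, p=_TE_WEIGHTS)
        return starts, starts + lens, fams

    n_shared = rng.poisson(2.5)
    s_s, s_e, s_f = draw(n_shared)
    rows_a = [(gene_a.chrom, int(s), int(e), _TE_CLASS[f], f, f) for s, e, f in zip(s_s, s_e, s_f)]
    rows_g = list(rows_a)
    for rows in (rows_a, rows_g):
        n_u = rng.poisson(1.2)
        u_s, u_e, u_f = draw(n_u)
        rows.extend(
            (gene_a.chrom, int(s), int(e), _TE_CLASS[f], f, f) for s, e, f in zip(u_s, u_e, u_f)
        )
    return rows_a, rows_g


def _chromtes_from_rows(rows: list[tuple]) -> "ctx._ChromTes":
    starts = np.array([r[1] for r in rows], dtype=int)
    ends = np.array([r[2] for r in rows], dtype=int)
    fams = np.array([r[5] for r in rows], dtype=object)
    return ctx._ChromTes(starts, ends, fams)


def _gen_tfbs_pair(
    rng: np.random.Generator, gene_a: GeneModel, gene_g: GeneModel, pool: list[str]
) -> tuple[list[tuple], list[tuple], int, int]:
    """TFBS hit rows per haplotype plus the (shared, unique) motif counts."""
    n_shared = min(rng.poisson(4), len(pool))
    shared = list(rng.choice(pool, size=n_shared, replace=False))
    rest = [m for m in pool if m not in shared]

    def uniques():
        n = min(rng.poisson(1.5), len(rest))
        return list(rng.choice(rest, size=n, replace=False)) if n else []

    def hits(gene, motifs):
        ws, we = ctx.gene_flank(gene, ctx.FlankSpec("upstream", 2000))
        return [
            (gene.chrom, (start := int(rng.integers(ws, max(ws + 1, we - 12)))), start + 12,
             m, float(rng.uniform(5, 15)), float(rng.uniform(1e-8, 1e-5)))
            for m in motifs
        ]

    ua, ug = uniques(), uniques()
    set_a, set_g = set(shared + ua), set(shared + ug)
    return (
        hits(gene_a, shared + ua),
        hits(gene_g, shared + ug),
        len(set_a & set_g),
        len(set_a ^ set_g),
    )


def generate_dataset(config: SyntheticConfig, with_tracks: bool = True) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given config.seed.

    ``with_tracks=False`` skips emission of the per-site methylation tables
    (the planted truth is identical either way), which makes large-n
    generation for modeling benchmarks fast.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    cursors = {c: 12_000 for c in chroms}

    genes_a: list[GeneModel] = []
    genes_g: list[GeneModel] = []
    cds: dict[str, str] = {}
    motif_pool = [f"TF{i + 1:04d}" for i in range(30)]
    te_a_parts, te_g_parts, tf_a_parts, tf_g_parts = [], [], [], []
    methyl_plans: list[tuple[_MethylPlan, _MethylPlan]] = []
    feature_rows = []
    pair_ids = []

    for i in range(cfg.n_pairs):
        chrom = chroms[i % len(chroms)]
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        exons_a = _make_exons(rng, cfg, start)
        exons_g = _perturb_exons(rng, exons_a)
        pid = f"p{i + 1:05d}"
        ga = GeneModel(f"gA{i + 1:05d}", "A", chrom, strand, exons_a[0][0], exons_a[-1][1], tuple(exons_a))
        gg = GeneModel(f"gG{i + 1:05d}", "G", chrom, strand, exons_g[0][0], exons_g[-1][1], tuple(exons_g))
        genes_a.append(ga)
        genes_g.append(gg)
        pair_ids.append(pid)
        # spacing keeps each pair's 10 kb flanks clear of the neighbours' TEs,
        # so planted and re-extracted TE features agree exactly
        cursors[chrom] = max(ga.end, gg.end) + int(rng.integers(24_000, 30_000))

        # CDS pair with a per-pair mutation rate
        pool = _nonstop_codons()
        n_cod = int(np.clip(sum(e - s + 1 for s, e in exons_a) // 3, 30, 400))
        cds_a = "".join(rng.choice(pool, size=n_cod))
        rate = float(min(0.15, rng.exponential(0.01)))
        cds_g = _mutate_cds(rng, cds_a, rate)
        cds[ga.gene_id] = cds_a
        cds[gg.gene_id] = cds_g

        # planted methylation
        levels_a, levels_g = _methyl_levels_pair(rng, ga, gg)
        plan_a = _MethylPlan(ga, levels_a, cfg.methylation_site_spacing)
        plan_g = _MethylPlan(gg, levels_g, cfg.methylation_site_spacing)
        methyl_plans.append((plan_a, plan_g))
        means_a, means_g = plan_a.planted_means(), plan_g.planted_means()

        # tracks for TE / TFBS
        te_pa, te_pg = _gen_te_pair(rng, ga, gg)
        tf_pa, tf_pg, tf_shared, tf_unique = _gen_tfbs_pair(rng, ga, gg, motif_pool)
        te_a_parts.extend(te_pa)
        te_g_parts.extend(te_pg)
        tf_a_parts.extend(tf_pa)
        tf_g_parts.extend(tf_pg)

        # planted feature values (same operations as the extraction stage)
        row: dict[str, float] = {"pair_id": pid}
        for region in ("gene", "exon", "intron", "upstream", "downstream", "first_exon", "first_intron"):
            for context in _METHYL_BASE:
                a = means_a[(region, context)]
                g = means_g[(region, context)]
                row[methylation_feature_name(context, region)] = (
                    abs(a - g) if np.isfinite(a) and np.isfinite(g) else float("nan")
                )
        row.update(
            ctx._te_features_impl(
                ga, gg, _chromtes_from_rows(te_pa), _chromtes_from_rows(te_pg)
            )
        )
        row["TFBS_shared"] = float(tf_shared)
        row["TFBS_unique"] = float(tf_unique)
        div = compute_ka_ks(CodonAlignment(cds_a, cds_g))
        row["Ka"] = div.ka
        row["Ks"] = div.ks
        row["Ka_Ks"] = div.ratio if div.ratio is not None else float("nan")
        from .divergence import structure_features

        row.update(structure_features(ga, gg))
        feature_rows.append(row)

    features = pd.DataFrame(feature_rows).set_index("pair_id")
    features = features[CATALOG.numeric_names]

    # planted log2 allelic ratio from standardized feature differences
    z = features.copy()
    for col in z.columns:
        med = z[col].median()
        z[col] = z[col].fillna(med if np.isfinite(med) else 0.0)
        sd = z[col].std(ddof=0)
        z[col] = (z[col] - z[col].mean()) / sd if sd > 0 else 0.0
    ratio = np.zeros(cfg.n_pairs)
    for feat, beta in cfg.effect_sizes.items():
        ratio += beta * z[feat].to_numpy()
    if cfg.ratio_noise_sd > 0:
        ratio += rng.normal(0, cfg.ratio_noise_sd, size=cfg.n_pairs)

    null_mask = rng.random(cfg.n_pairs) < cfg.frac_null_pairs
    ratio[null_mask] = 0.0
    unexpressed = rng.random(cfg.n_pairs) < cfg.frac_unexpressed_pairs

    # sample grid and NB counts
    sample_rows = []
    for tissue in cfg.tissues:
        for treatment in cfg.treatments:
            for r in range(1, cfg.replicates_per_condition + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{tissue}_{treatment}_R{r}",
                        "tissue": tissue,
                        "treatment": treatment,
                        "replicate": r,
                    }
                )
    samples = pd.DataFrame(sample_rows)
    n_cond = len(cfg.tissues) * len(cfg.treatments)
    reps = cfg.replicates_per_condition

    base = 2.0 ** (cfg.baseline_log2_expression + rng.normal(0, 1.2, size=cfg.n_pairs))
    cond_factor = 2.0 ** rng.normal(0, 0.3, size=(cfg.n_pairs, n_cond))
    mu_a = base[:, None] * cond_factor * 2.0 ** (ratio[:, None] / 2.0)
    mu_g = base[:, None] * cond_factor * 2.0 ** (-ratio[:, None] / 2.0)
    mu_a[unexpressed, :] = 0.05
    mu_g[unexpressed, :] = 0.05
    mu_a = np.repeat(mu_a, reps, axis=1)
    mu_g = np.repeat(mu_g, reps, axis=1)
    r_nb = 1.0 / cfg.nb_dispersion
    counts_a = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_a))
    counts_g = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_g))

    ids_a = [g.gene_id for g in genes_a]
    ids_g = [g.gene_id for g in genes_g]
    counts = pd.DataFrame(
        np.vstack([counts_a, counts_g]),
        index=ids_a + ids_g,
        columns=samples["sample_id"],
    )
    counts.index.name = "gene_id"
    lengths = pd.Series(
        [sum(e - s + 1 for s, e in g.exons) for g in genes_a + genes_g],
        index=ids_a + ids_g,
        name="effective_length",
        dtype=float,
    )

    thresholds = ClassificationThresholds()
    truth = features.reset_index().copy()
    truth.insert(1, "planted_log2_ratio", ratio)
    truth.insert(2, "expressed", ~unexpressed)
    truth.insert(
        3,
        "expected_category",
        [
            category_from_ratio(r, thresholds, expressed=not u)
            for r, u in zip(ratio, unexpressed)
        ],
    )

    methylation_a = methylation_g = None
    if with_tracks:
        parts_a = [pa.emit_sites(rng, cfg.methylation_mean_coverage) for pa, _ in methyl_plans]
        parts_g = [pg.emit_sites(rng, cfg.methylation_mean_coverage) for _, pg in methyl_plans]
        methylation_a = pd.concat(parts_a, ignore_index=True)
        methylation_g = pd.concat(parts_g, ignore_index=True)

    pairs_truth = pd.DataFrame({"pair_id": pair_ids, "gene_a": ids_a, "gene_g": ids_g})
    chrom_lengths = {c: cfg.chrom_length for c in chroms}
    for c in chroms:  # extend if the layout overran the configured length
        needed = max(
            [g.end + 14_000 for g in genes_a + genes_g if g.chrom == c], default=0
        )
        chrom_lengths[c] = max(chrom_lengths[c], needed)

    return SyntheticDataset(
        config=cfg,
        genes_a=genes_a,
        genes_g=genes_g,
        cds=cds,
        pairs_truth=pairs_truth,
        methylation_a=methylation_a,
        methylation_g=methylation_g,
        te_a=pd.DataFrame(te_a_parts, columns=ctx.TE_COLUMNS),
        te_g=pd.DataFrame(te_g_parts, columns=ctx.TE_COLUMNS),
        tfbs_a=pd.DataFrame(tf_a_parts, columns=_TFBS_COLUMNS),
        tfbs_g=pd.DataFrame(tf_g_parts, columns=_TFBS_COLUMNS),
        counts=counts,
        lengths=lengths,
        samples=samples,
        truth=truth,
        chrom_lengths=chrom_lengths,
    )


def planted_truth(
    dataset: SyntheticDataset,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Per-pair planted truth with the expected category recomputed from the
    noise-free planted ratios under the given classification thresholds."""
    truth = dataset.truth.copy()
    truth["expected_category"] = [
        category_from_ratio(r, thresholds, expressed=e)
        for r, e in zip(truth["planted_log2_ratio"], truth["expressed"])
    ]
    return truth
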