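"""End-to-end orchestration: simulate -> pair -> quantify/classify ->
extract features -> thin -> train models 0-3 -> explain, with a
machine-readable JSON report.

Every random draw descends from one global seed through fixed offsets
(simulation: seed; model fitting: seed + 1; splitting: seed + 2), so changing
the global seed changes all stochastic outputs and changing anything else
changes nothing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .ase import (
    CATEGORIES,
    ClassificationThresholds,
    call_ase,
    category_specific_pairs,
    compute_tpm,
)
from .context import FlankSpec, MethylIndex, gene_flank, gene_span0, te_pair_features, tfbs_pair_features
from .divergence import pair_divergence, structure_features
from .features import CATALOG, MODEL1_FEATURES, assemble_features, correlation_thin, methylation_feature_name
from .model import AseBoostModel, BoostParams, SplitSpec
from .pairing import collinearity_filter, reciprocal_best_pairs
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("hapase")

__all__ = ["PipelineConfig", "run_pipeline", "extract_pair_features"]


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    min_chain: int = 3
    min_coverage: int = 5
    thinning_preset: Optional[str] = "model1"  # None -> recompute by correlation
    r_threshold: float = 0.7
    p_threshold: float = 0.001
    boost: BoostParams = field(default_factory=BoostParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    outdir: str = "hapase_out"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            for key in ("exons_per_gene", "tissues", "treatments"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "effect_sizes" in syn:
                syn["effect_sizes"] = dict(syn["effect_sizes"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "thresholds" in raw:
            kwargs["thresholds"] = ClassificationThresholds(**raw["thresholds"])
        if "boost" in raw:
            kwargs["boost"] = BoostParams(**raw["boost"])
        if "split" in raw:
            kwargs["split"] = SplitSpec(**raw["split"])
        for key in (
            "min_chain",
            "min_coverage",
            "thinning_preset",
            "r_threshold",
            "p_threshold",
            "outdir",
            "log_level",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def param_hash(self) -> str:
        """Hash of the analysis parameters (output location and logging are
        not part of the analysis identity)."""
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def extract_pair_features(
    pairs: pd.DataFrame,
    genes_a,
    genes_g,
    cds: dict,
    methylation_a: Optional[pd.DataFrame],
    methylation_g: Optional[pd.DataFrame],
    te_a: pd.DataFrame,
    te_g: pd.DataFrame,
    tfbs_a: pd.DataFrame,
    tfbs_g: pd.DataFrame,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """All 44 numeric predictors per pair, recomputed from the tracks."""
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_g = {g.gene_id: g for g in genes_g}
    idx_a = MethylIndex(methylation_a, min_coverage) if methylation_a is not None else None
    idx_g = MethylIndex(methylation_g, min_coverage) if methylation_g is not None else None

    def region_intervals(gene):
        s0, e0 = gene_span0(gene)
        exons = [(s - 1, e) for s, e in gene.exons]
        introns = [(s - 1, e) for s, e in gene.introns]
        return {
            "gene": [(s0, e0)],
            "exon": exons,
            "intron": introns,
            "upstream": [gene_flank(gene, FlankSpec("upstream", 2000))],
            "downstream": [gene_flank(gene, FlankSpec("downstream", 2000))],
            "first_exon": exons[:1],
            "first_intron": introns[:1],
        }

    rows = []
    for _, pr in pairs.iterrows():
        ga, gg = by_id_a[pr["gene_a"]], by_id_g[pr["gene_g"]]
        row: dict[str, float] = {"pair_id": pr["pair_id"]}
        if idx_a is not None:
            regs_a, regs_g = region_intervals(ga), region_intervals(gg)
            for region in regs_a:
                for context in ("CG", "CHG", "CHH"):
                    ma = idx_a.mean(ga.chrom, regs_a[region], context) if regs_a[region] else float("nan")
                    mg = idx_g.mean(gg.chrom, regs_g[region], context) if regs_g[region] else float("nan")
                    row[methylation_feature_name(context, region)] = (
                        abs(ma - mg) if np.isfinite(ma) and np.isfinite(mg) else float("nan")
                    )
        else:
            for region in region_intervals(ga):
                for context in ("CG", "CHG", "CHH"):
                    row[methylation_feature_name(context, region)] = float("nan")
        row.update(te_pair_features(ga, gg, te_a, te_g))
        shared, unique = tfbs_pair_features(ga, gg, tfbs_a, tfbs_g)
        row["TFBS_shared"] = float(shared)
        row["TFBS_unique"] = float(unique)
        div = pair_divergence(cds[ga.gene_id], cds[gg.gene_id], ga.gene_id, gg.gene_id)
        row["Ka"] = div.ka
        row["Ks"] = div.ks
        row["Ka_Ks"] = div.ratio if div.ratio is not None else float("nan")
        row.update(structure_features(ga, gg))
        rows.append(row)
    return pd.DataFrame(rows)[["pair_id"] + CATALOG.numeric_names]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on a synthetic dataset and write outputs + report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    phash = config.param_hash()
    logger.info("pipeline start (seed=%d, params=%s)", config.seed, phash)

    # -- simulate ------------------------------------------------------------
    syn = replace(config.synthetic, seed=config.seed)
    ds = generate_dataset(syn)
    paths = hio.write_dataset(ds, out / "data")
    logger.info("simulated %d pairs on %d chromosomes", syn.n_pairs, syn.n_chromosomes)

    # -- pair (read annotations back from disk) ------------------------------
    genes_a = hio.read_gff3_genes(paths["genes_a.gff3"], haplotype="A")
    genes_g = hio.read_gff3_genes(paths["genes_g.gff3"], haplotype="G")
    cds = hio.read_fasta(paths["cds.fasta"])
    groups = {c: c for c in ds.chrom_lengths}
    rbh = reciprocal_best_pairs(genes_a, genes_g, cds, same_chrom_groups=groups)
    pairs_list = collinearity_filter(rbh, genes_a, genes_g, min_chain=config.min_chain)
    hio.write_pairs(pairs_list, out / "pairs.tsv")
    pairs = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs_list],
            "gene_a": [p.gene_a for p in pairs_list],
            "gene_g": [p.gene_g for p in pairs_list],
        }
    )
    logger.info("pairing: %d RBH, %d collinear", len(rbh), len(pairs))
    if pairs.empty:
        raise RuntimeError("stage pairing produced no pairs")

    # -- quantify & classify -------------------------------------------------
    tpm = compute_tpm(ds.counts, ds.lengths)
    tpm.to_csv(out / "tpm.tsv", sep="\t")
    calls = call_ase(ds.counts, ds.lengths, ds.samples, pairs, config.thresholds)
    calls.to_csv(out / "ase_calls.tsv", sep="\t", index=False)
    exclusive, matrix = category_specific_pairs(calls)
    matrix.to_csv(out / "category_matrix.tsv", sep="\t")
    category_counts = calls["category"].value_counts().to_dict()

    # -- features ------------------------------------------------------------
    pair_features = extract_pair_features(
        pairs,
        genes_a,
        genes_g,
        cds,
        ds.methylation_a,
        ds.methylation_g,
        ds.te_a,
        ds.te_g,
        ds.tfbs_a,
        ds.tfbs_g,
        min_coverage=config.min_coverage,
    )
    table, feat_report = assemble_features(pairs, calls, pair_features)
    header = f"# stage=features params={phash}\n"
    with open(out / "feature_table.tsv", "w") as fh:
        fh.write(header)
        # %.17g round-trips float64 exactly through the text format
        table.to_csv(fh, sep="\t", float_format="%.17g")

    # -- model 0 and thinning ------------------------------------------------
    boost = replace(config.boost, seed=config.seed + 1)
    split = replace(config.split, seed=config.seed + 2)
    results = {}
    m0 = AseBoostModel.from_feature_table(table, "model0", params=boost, split=split).fit()
    results["model0"] = m0
    if config.thinning_preset:
        retained = list(MODEL1_FEATURES)
        thin_info = {"mode": f"preset:{config.thinning_preset}", "retained": retained}
    else:
        ranking = list(m0.feature_importance().index)
        retained = correlation_thin(table, ranking, config.r_threshold, config.p_threshold)
        thin_info = {"mode": "correlation", "retained": retained}
    with open(out / "thinning.json", "w") as fh:
        json.dump(thin_info, fh, indent=2)

    # -- models 1-3 ----------------------------------------------------------
    for preset in ("model1", "model2", "model3"):
        m = AseBoostModel.from_feature_table(table, preset, params=boost, split=split)
        if config.thinning_preset is None:
            m = AseBoostModel(
                m.table, retained, m.response, m.params, m.split
            )
        results[preset] = m.fit()

    shap_info = results["model1"].shap(top_k=5)
    shap_summary = shap_info["mean_abs_attribution"]
    shap_summary.rename("mean_abs_attribution").to_csv(out / "shap_summary.tsv", sep="\t")

    report = {
        "seed": config.seed,
        "param_hash": phash,
        "n_pairs_simulated": int(syn.n_pairs),
        "n_pairs_rbh": len(rbh),
        "n_pairs_collinear": int(len(pairs)),
        "category_counts": {c: int(category_counts.get(c, 0)) for c in CATEGORIES},
        "category_exclusive_sizes": {c: len(v) for c, v in exclusive.items()},
        "feature_table": feat_report,
        "thinning": thin_info,
        "models": {name: res.report() for name, res in results.items()},
        "shap_top5": shap_info["top_features"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("pipeline done -> %s", out / "report.json")
    return report
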