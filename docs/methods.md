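# Methods

This note documents the statistical and algorithmic choices behind each
stage, the defaults that matter, what the synthetic data do and do not
emulate, and known limitations.

## Allele pairing

Candidate pairs are reciprocal best hits (RBH) between the two haplotype
gene sets. Genes are represented by their translated CDS (one representative
mRNA per gene, the longest CDS; CDS lengths not divisible by 3 are trimmed
by 1–2 trailing nucleotides with a warning; sequences with internal stop
codons are skipped with a warning). Candidates are scored by global protein
alignment with unit scoring — match 1, mismatch 0, gap open −2, gap extend
−0.5 — which is deterministic and needs no substitution-matrix or
codon-frequency estimation; the score-only pass is used for best-hit
selection and the full alignment identity (matches / alignment columns) is
reported as `homology_score` for retained pairs. Ties are broken by (score,
closeness of genome-wide ordinal rank, lexicographic gene id), so a perfect
duplicate resolves deterministically to the positionally closer copy.

RBH pairs are then restricted to collinear chains: within each
(chromosome_A, chromosome_G) combination, pairs are ordered by the A gene's
per-chromosome ordinal and a chain extends while the G ordinals stay
strictly monotonic in one direction. Chains shorter than `min_chain`
(default 3, the smallest run that distinguishes a chain from a stray hit)
are dropped; inverted blocks survive as decreasing chains. No further
manual-curation heuristics are modeled.

Coordinates are 1-based inclusive at GFF3 boundaries and 0-based half-open
for all internal interval math; the conversion happens exactly once at I/O.

## Expression quantification and the allelic test

TPM uses the standard definition (counts over length in kb, scaled to 10⁶
per sample); all-zero samples produce all-zero columns with a warning. A
gene is *expressed* in a condition when its TPM exceeds 0.5 in at least one
replicate of that condition; a pair is `NE` when neither allele is
expressed. The expression rule is evaluated per condition (rather than
globally over all samples) because category composition is reported per
tissue/treatment.

The allelic test works per condition on median-of-ratios normalized counts
(size factors estimated from all genes of the condition's samples). Per
pair, a method-of-moments dispersion is computed from the replicate
variances pooled across the two alleles, and shrunk toward a mean–dispersion
trend α(μ) = a₀/μ + a₁ fitted by least squares across all pairs. The
shrinkage weight on the per-pair estimate is 0.2: with three replicates the
per-pair moment estimate is extremely noisy and positively correlated with
the observed allele difference, and larger weights visibly inflate the null
tail (the KS-uniformity test below fails). The test statistic compares the
two allele means directly,

    z = max(|m_A − m_G| − c, 0) / sqrt(v(μ̂)/n_A + v(μ̂)/n_G),

with v(μ) = μ + α̂μ², μ̂ the pooled mean, and a continuity correction
c = 0.5·(1/n_A + 1/n_G)/2 that accounts for count discreteness; the
two-sided p comes from the standard normal. This mean-difference (score-
type) form was chosen over the log-scale delta-method statistic because the
latter is measurably miscalibrated at n = 3 (the log of a mean of three
skewed NB draws is not close enough to normal, and discreteness biases even
exact NB tail probabilities); the implemented statistic passes a
Kolmogorov–Smirnov uniformity check on 10,000 null pairs across every
simulation seed probed. The reported effect size is still
log2fc = log₂((m_A + 0.5)/(m_G + 0.5)); the 0.5 pseudocount avoids infinite
fold changes at zero means.

Benjamini–Hochberg adjustment is pooled within each condition across all
tested pairs (delegated to `statsmodels`, verified against a hand step-up
oracle). Categories: `NE` first; `Diff00` when adjusted p > 0.05 (or the
pair is untestable, < 2 replicates); otherwise `Diff0` / `Diff2` / `Diff8`
by FC ≤ 2, 2 < FC < 8, FC ≥ 8, with FC unsigned. Both boundary values are
classified inclusively downward/upward exactly as written (FC = 2 → Diff0,
FC = 8 → Diff8).

## Sequence divergence

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions from the standard genetic code averaged over the two sequences,
multi-difference codons averaged over all minimal mutational pathways with
equal weights (pathways through stop codons are excluded, falling back to
all pathways when every pathway is blocked; substitutions *to* stop codons
count as nonsynonymous in site counting), proportions corrected by
Jukes–Cantor d = −(3/4)·ln(1 − 4p/3). Counting is table-driven (64-entry
site table, 64×64 pathway table built once at import) and verified
exhaustively against an independently written pathway-enumeration oracle on
all ≤ 2-difference codon pairs. When p ≥ 3/4 the correction is undefined
and the result is flagged saturated; Ka/Ks is missing whenever Ks = 0 — a
common situation for nearly identical alleles — and imputation is deferred
to the feature-table stage. A maximum-likelihood codon model (with
transition/transversion bias and codon frequencies) would be the natural
upgrade; counting was chosen because it is fully specifiable and
oracle-testable, and the ratio enters the downstream model only as a
monotone predictor.

Codon alignment is the protein global alignment threaded back onto
nucleotides, so gaps always appear in codon-sized, frame-aligned runs;
gap-containing codon columns are excluded from site counting.

## Genomic context features

All interval features are computed on merged (union) coverage; "TE
occupancy" of a flank is covered length over clipped flank length. Flanks
are strand-aware (upstream = 5′ of the TSS), so reversing a gene's strand
swaps upstream and downstream features exactly. Nearest-TE distance is the
bp gap to the closest TE on the chromosome (0 on overlap, missing when the
chromosome has no TE). Shared/unique TE counts are defined on TE *family
labels* present in the upstream-2kb ∪ gene-body region of each allele,
since TE identity across haplotype coordinate systems is not otherwise
defined. Methylation region means are unweighted means of per-site
frequencies over sites with ≥ 5 reads (a coverage-weighted variant is
available behind a flag); a sorted per-(chromosome, context) index provides
the same answer as the reference single-region operation in O(log n) per
query, and the two are asserted equal in tests.

The breakpoint randomization test counts breakpoint ± 150 bp windows
overlapping ≥ 1 TE and compares against TEs re-placed uniformly at random
per chromosome, preserving count and length (placed TEs may overlap); the
empirical p is (1 + #{null ≥ observed})/(n_perm + 1), so its floor is
1/(n_perm + 1). Because the statistic is a small integer count, the ≥ tie
convention makes p slightly conservative; calibration checks use scenarios
with enough windows that this bias is small.

## Feature table

Exactly 46 predictors in 6 categories (21 methylation + 9 TE + 8 sequence
divergence + 6 structural + Tissue + Treatment); the catalog asserts its own
arithmetic at import. All between-allele numeric features are absolute
differences — the response is unsigned (|FC| bins), so orientation carries
no consistent information; a signed variant would require fixing a
haplotype orientation convention and is intentionally not the default.
Missing values (undefined Ka/Ks, methylation regions with no qualifying
site, TE-free chromosomes, single-exon genes without introns) are imputed by
column median, which is rank-preserving for tree models; imputation counts
are recorded in the assembly report. Tissue and Treatment are deterministic
integer codes from sorted labels, with the mapping written to the report.
Rows are pair × condition with a non-NE call.

Correlation thinning visits numeric features in descending model-0
importance and drops a feature when |Pearson r| ≥ 0.7 with two-sided
p < 0.001 (Fisher z) against an already-retained feature; categoricals are
always retained, constant columns are kept with a warning. The published
15-feature reduced predictor set is also available as a fixed preset
(`model1`), so the reduced models are exactly reproducible independent of
the thinning parameterization.

Feature tables serialize to TSV with `%.17g` precision, which round-trips
float64 bit-exactly (use `float_precision="round_trip"` when re-reading
with pandas).

## Modeling

`AseBoostModel` / `AseBoostResults` follow the model/results-object
convention: the model object holds the table, predictor list, response and
hyperparameters; `fit()` returns a results object with metrics, importances,
ROC curves, a text `summary()` and TreeSHAP attributions. Defaults are
η = 0.3, γ = 0.001, max_depth = 2, up to 100,000 rounds; boosting stops
after 200 rounds without validation improvement. Early stopping monitors a
validation subset (20%) carved from the 70% training split — never the test
set, which would leak; 30% of rows are held out for evaluation, stratified
by class for classification (falling back to an unstratified split with a
warning when a class has fewer than 4 rows). Multiclass AUC is one-vs-rest
per class, macro-averaged; "mean sensitivity" is macro-averaged recall.
Importance is gain-based, normalized to sum 1, ties broken lexicographically.
Model 2's binary response groups {Diff0, Diff2, Diff8} against {Diff00};
Model 3 regresses on the absolute TPM difference (the sign of the
difference is not modeled, consistent with the unsigned features). Shapley
values are tree-path-dependent TreeSHAP attributions computed by the
boosting library (`pred_contribs`); per row, base value + attributions
reproduce the margin to ~10⁻⁶ relative tolerance, which the tests assert.
Determinism holds at fixed seed with one thread (the default).

## Synthetic data

The generator emulates the *structure* of a haplotype-resolved study: both
haplotypes share a chromosome layout and each pair derives from a common
template gene, which guarantees collinearity for pairing tests while
allowing controlled divergence (exon resizing/insertion/deletion on one
haplotype, per-pair CDS mutation rates drawn from an exponential with mean
1%, correlated TE landscapes with shared and haplotype-unique insertions,
motif sets with shared and unique TFBS, per-region methylation levels with
context-specific baselines near 0.50/0.22/0.03 for CG/CHG/CHH and
between-allele differences with sd 0.10/0.10/0.02). Genes are spaced ≥ 24 kb
apart so each pair's 10 kb flanks are clear of its neighbours' TEs, which
makes planted and re-extracted interval features agree exactly.

Planted feature values for TE, TFBS, divergence and structural features are
computed *with the same operations the extraction stage uses*, so truth and
extraction agree exactly; methylation truth is the analytic (site-count
weighted) mean of per-site true levels, and the emitted tracks sample
binomial counts at a deterministic site grid (default spacing 30 bp,
coverage ~20; the truth/extraction correlation approaches 1 as density and
coverage grow). The planted log2 allelic ratio is Σ β_f·z(feature_f) +
N(0, σ), with features z-scored across pairs so effect sizes are comparable
across heterogeneous units. Default σ = 0.8; default effects follow the
importance ordering the downstream model is expected to recover (mCHG_gene
strongest, then Ks, Ka/Ks, TE occupancy in the 10 kb flanks). A configurable
fraction of pairs (default 30%) gets an exactly-zero ratio (the noise-free
Diff00 stratum) and a fraction (default 5%) is unexpressed on both alleles
(NB mean 0.05 counts/replicate). Counts are negative-binomial (default
dispersion 0.1) around per-allele means 2^(±ratio/2) times a log-normal
per-pair baseline (log2 mean 6.5, sd 1.2) and per-condition factor (log2 sd
0.3); the default condition grid is 3 tissues × 2 treatments × 3
replicates, the smallest grid exercising both categorical features.

What the synthetic data do **not** emulate: sequence-level realism (codon
usage, TE sequence content), read-level sampling and mapping bias,
condition-dependent allelic ratios (the planted ratio is constant across
conditions, so Tissue/Treatment carry no planted signal), and real library
-size granularity — with only a few hundred genes, a single stray count can
exceed the TPM 0.5 threshold, so planted-unexpressed pairs occasionally
classify as Diff00 rather than NE. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not biological realism of any
particular marginal distribution; the feature marginals are fixtures, not
claims about real data.

The noise-free expected category applies the classification thresholds to
the planted ratio directly: NE if unexpressed, Diff00 iff the ratio is
exactly 0, otherwise the FC bins with significance assumed.

## Problem sizes and benchmarks

The planted-driver benchmark uses 5,000 pairs in a single condition (one
modeling row per pair, so held-out rows are genuinely unseen pairs) with one
dominant effect (β = 2.5 on mCHG_gene, σ = 0.1), repeated over 10 seeds; the
zero-signal benchmark uses the same shape with no effects and σ = 0.8.
Statistical calibration uses 10,000 null pairs at NB(μ = 100, α = 0.1) with
3 replicates; randomization calibration uses 200 runs of 60 windows × 150
TEs on a 1 Mb chromosome with 49 permutations. These sizes keep the whole
verification suite at desk scale while leaving the Monte-Carlo tolerances
meaningful.

## Known limitations

- The allelic test's normal reference is an approximation; at very low
  counts (μ below ~10) discreteness re-emerges and p-values become
  conservative despite the continuity correction.
- NG86 ignores transition/transversion bias and codon frequencies, which
  biases Ka and Ks absolutely (though much less so their ranks).
- Pairing is O(n²) alignments per chromosome group; for genome-scale inputs
  supply `same_chrom_groups` (chromosome-matched assemblies) or pre-binned
  candidates.
- A "near-best hit" relaxation (as used by some homology-pairing tools to
  rescue tandem duplicates) is not implemented; strict RBH slightly
  under-pairs duplicated genes.
- Only two haplotypes are supported; polyploid designs would need a
  different pairing formulation.
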