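# Methods

This note documents the statistical models, the synthetic-data
generator, default parameters, numerical choices and known limitations
of `zeaqtl`.

## Mixed-model association (P3D/EMMAX)

Each response (a gene's rank-normalized expression, or the kernel
phenotype) is modeled as `y = Xb + g·β + u + ε` with `Var(u) = σ²_g K`
and `Var(ε) = σ²_e I`. The kinship `K` is the min-rescaled
identity-by-state matrix: with homozygous dosages `d ∈ {0, 2}`, the raw
similarity is the mean shared-allele fraction `S_ij = mean(1 − |d_i −
d_j|/2)` and `K = (S − min S)/(1 − min S)`, so the least related pair
maps to 0 and identity to 1. (The exact rescaling used by TASSEL's
"Normalized_IBS" is not published; role-equivalence, not numerical
equivalence, is intended.)

Variance components are estimated under the null (no SNP) model by REML:
after rotating by the eigenvectors of `K`, the profile criterion is a
one-dimensional function of `δ = σ²_e/σ²_g`, minimized over
`log₁₀ δ ∈ [−6, 6]` (bounded scalar minimization, tolerance 1e-6).
They are then fixed for every SNP test of that response ("P3D"), which
reduces each test to generalized least squares: whitening is diagonal in
the rotated basis, so a whole genotype matrix is tested with vectorized
residualized regressions. Variance components are refit per response.
With `K = I` only the total variance is identified; the scan is then
exactly an OLS t-test, a reduction asserted in the tests. P3D against
exact per-SNP REML refits agrees within |Δlog₁₀ p| < 0.5 on simulated
panels (asserted). p-values floor at 1e-300.

Covariates: top 3 genotype PCs (SVD of centered dosages, scaled by
singular values; computed on complete-call SNPs with MAF > 0.05) plus 10
hidden expression factors for eQTL scans; PCs only for the phenotype
MLM; none for the phenotype GLM. Hidden factors are residual PCA — each
gene regressed on the PCs, top left singular vectors of the residual
matrix, variance-ordered and exactly orthogonal to the covariates — a
deterministic substitute for Bayesian factor models (PEER); the QTT
model uses the top 2.

## eQTL calling

Genome-wide Benjamini–Hochberg selection (FDR 0.05, own step-up
implementation, cross-checked in tests against statsmodels and an
exhaustive oracle) is applied to the pooled p-values of a stage's scan;
the realized cutoff is reported. Per gene, significant SNPs chain into
clusters when consecutive gaps are strictly below 5 kb; clusters need at
least 3 members; the region spans first to last member and the lead SNP
minimizes p (ties: leftmost). A stricter diameter-bounded variant
(no member pair ≥ 5 kb apart) is available via `diameter=True`;
adjacency chaining is the default because it is the more procedural of
the two published phrasings. Candidate regions of one gene whose lead
SNPs have r² > 0.1 are pruned keeping the smaller lead p; equal p keeps
the larger joint effect, defined here (the term is otherwise
unspecified) as the multiple-regression R² of the gene's expression on
the candidate's member dosages (pseudo-inverse for rank deficiency).
Pruning order (p ascending, joint effect descending, position) makes the
result independent of input order. Locality: a region within 20 kb of
the gene span (1-based inclusive interval gap; overlap = 0) is local,
else distant. Genomic category of a region: exon > intron > "utr1kb"
(within 1 kb of any TSS/TES) > intergenic, by any-overlap; per-SNP
categorization uses CDS > UTR > intron > intergenic.

## Cross-stage comparison

eQTLs of the two stages merge by transitive interval intersection per
chromosome, each connected component keeping the maximal span; the
operation is idempotent and order-invariant (fuzz-tested). A merged
region is *shared* when it has source eQTLs at both stages, else
stage-specific; sharing is decided at the region level (per-gene
sharing available). For each shared region and gene significant at both
stages, the allelic effect at each stage's lead SNP is the
major-over-minor-allele mean FPKM ratio (major = more frequent
homozygous class; pseudo-count 0.01 when a mean is non-positive); a pair
is *inverse* when the two log₂ fold changes have strictly opposite signs
(optional magnitude threshold, default 0). The same lead-SNP need not be
identical at both stages, only the region and gene. Local enrichment of
a subset uses a 1-df goodness-of-fit chi-square against the background
local fraction. Multi-target eQTLs are regions associated with strictly
more than 3 genes at either stage. TSS distances are anchored at the
region midpoint (lead-SNP anchor available), strand-oriented, binned at
5 kb.

## Trait integration

QTT: ordinary least squares of expression on phenotype, 3 PCs and 2
hidden factors; two-sided t-test on the phenotype coefficient α;
direction = sign(α). Collinear hidden-factor columns are dropped with a
warning. Selection: p < 0.05 and median FPKM > 1 (the published filter
does not state the scale; FPKM is the default and configurable). GWAS
evidence uses the GLM scan at the fixed 1.29e-6 cutoff; genes are
"covered" when a significant SNP lies within the gene span (flank
configurable, default 0). Candidates are the three-way intersection
(monotone in each input); haplotype contrasts use Welch's t-test between
the two homozygous classes at a lead SNP.

## Motif enrichment

RRACH (`[GA][GA]AC[TAC]`) and URUAY (`T[GA]TA[TA]`) are scanned on cDNA
(U written as T) with an overlap-tolerant window scan; `N` never
matches. A gene carries a motif in a region (mRNA or 3'UTR, the latter
being the 3'-terminal UTR-length slice of each transcript) when any of
its transcripts matches. Enrichment of a target set within the
background universe (default: all genes with sequence) is the upper-tail
hypergeometric probability, exact against enumeration in tests.

## The synthetic-data generator

The generator emulates the study design, not maize biology in full:

* **Population.** Fully homozygous lines (dosages {0, 2}), assigned
  round-robin to subpopulations. Each 5-kb LD block has an ancestral
  frequency p₀ ~ U(0.1, 0.9) and per-subpopulation frequencies from a
  Balding–Nichols Beta with divergence F (default 0.15); SNPs within a
  block copy a block-latent allele with a 3% per-SNP flip, yielding mean
  within-block r² ≈ 0.8. No coalescent genealogy, no recombination
  gradients, no allele-frequency spectrum realism.
* **Expression.** Abundance = per-gene baseline U(5, 15) + planted
  effects · dosage/2 + hidden-factor contributions (loadings N(0, 0.6),
  factor values N(0, 1)) + N(0, 1) noise; clipped at 0 for the FPKM
  representation; counts are a Poisson thinning at a per-line depth.
  Baselines sit well above zero so the clip almost never distorts a
  planted (possibly negative) shift. Real count overdispersion,
  length/GC bias and mean–variance coupling are not modeled, so passing
  recovery tests demonstrate pipeline correctness, not robustness to
  real RNA-seq artifacts.
* **Planted eQTLs.** One per gene; cis SNPs are chosen *inside* the gene
  span (hence always within the 20-kb local window, and discoverable by
  gene-body GWAS coverage), trans SNPs on a different chromosome;
  planted SNPs require realized MAF ≥ 0.2 and an LD block of ≥ 3 SNPs so
  the 3-SNP cluster rule is satisfiable. Effect magnitude is exactly
  `eqtl_effect_sd` (default 1.5 expression-SD) with random sign; shared
  effects repeat at both stages, inverse effects flip sign at stage 2.
* **Phenotype.** Kernel length = Σ w·FPKM over QTT genes (|w| = 1,
  random sign, QTT genes drawn from cis-planted genes) + N(0,
  `phenotype_noise_sd`).
* **Motifs.** Transcript backbones are scrubbed of both motif patterns
  (iterated window mutation), then a motif instance is planted in the
  3'UTR of carrier genes — designated targets (n_genes/10 of the genes)
  with probability 0.9, background genes 0.5. The truth table records
  the *realized* carrier sets rescanned after planting, because plant
  junctions can occasionally create an incidental match of the other
  pattern; realized sets make recount checks exact.
* **Determinism.** One `numpy` Generator seeded from the config; equal
  seeds give byte-identical output files (matrices serialized at 17
  significant digits and re-read with round-trip float parsing).

Default study conditions: 300 lines, 3 subpopulations, 5 chromosomes ×
1,000 SNPs, 500 genes, 40 cis + 20 trans planted eQTLs (40 shared of
which 8 inverse, 10 + 10 stage-specific), 2 hidden factors, 8 QTT genes,
2% missing genotype calls.

### The two power regimes

Under the defaults (effect 1.5 SD, phenotype driven by 8 transcripts,
unit noise) the eQTL arm has essentially full power, but the per-SNP
effect on the phenotype is diluted by the other transcripts' variance:
the GLM GWAS finds nothing at 1.29e-6 — qualitatively reproducing the
published kernel-length GWAS, which was null under the MLM and only
informative through integration. Demonstrating the full integration
chain therefore uses a strong-effect regime chosen by a pre-run power
calculation (effect 3.0 SD, 3 QTT genes, phenotype noise 0.5: expected
per-SNP GLM t ≈ 7 at n = 300), under which planted QTT genes pass all
three evidence filters.

## Genotype QC choices

Heterozygous calls are masked to missing before rate computations; SNPs
with heterozygote rate > 10%, missing rate > 60% or MAF < 2% (strict)
are dropped. Imputation is per-SNP modal fill (ties → major allele,
allele-count ties → reference): deterministic and honest about being far
less accurate than haplotype-based imputation — imputation quality is
not an analysis target here, and the substitution is logged. Panel
merging takes the union of loci, primary calls winning at overlaps,
warning on ref/alt conflicts.

## Numerical and testing notes

* `rank_normalize` follows R's `ppoints` convention: offset 3/8 for
  n ≤ 10, 0.5 otherwise; ties share averaged ranks; all-equal input
  maps to zeros.
* The size-factor estimator (median-of-ratios over all-positive genes)
  is invariant to a global rescaling of all lines — the reference
  rescales too — and tests assert exactly that, alongside the
  single-line rescaling behaviour.
* Kinship is checked for positive semi-definiteness; a diagonal jitter
  of at most 1e-8 is added and logged if needed.
* BH under a complete null with continuous independent p-values has
  expected false-discovery proportion *exactly* α·m₀/m; a strict
  "mean FDP ≤ α" check over finitely many replicates would therefore
  fail a correct implementation about half the time. The null-behaviour
  test asserts (a) the mean fraction of hypotheses selected is ≤ α
  (it is ~α/m under the null) and (b) the replicate-mean FDP equals its
  theoretical value within three Monte-Carlo standard errors.
* Test problem sizes: unit tests use a 120-line/450-SNP/60-gene panel;
  recovery tests use the default 300/5,000/500 study scale, which keeps
  the whole suite under a few minutes on one CPU.

## Known limitations

* Modal imputation and residual-PCA hidden factors are deliberate
  simplifications of BEAGLE and PEER; numerical equivalence with the
  published pipeline is not claimed anywhere.
* LD is block-wise exchangeable; there is no distance-decay of r²
  within or across blocks, so LD-pruning is exercised only in the
  regime of clearly linked vs clearly unlinked candidates.
* The simulator plants at most one eQTL per gene; multi-eQTL
  architectures reach the pruning logic only through chance overlaps
  (and through crafted unit-test fixtures).
* Fold-change-based inverse detection assumes positive expression
  scales; heavily zero-inflated genes would need the pseudo-count path
  more often than the simulator produces.
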