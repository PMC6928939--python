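# Methods

## Model and pipeline

The pipeline treats each subcortical **module volume** as a
quantitative trait. The chain is: genotype QC → ICV normalization →
structure clustering → per-module GWAS → anchored SNP×SNP interaction
scan → degree-based selection of interactive SNPs. Key modelling
assumptions:

- **Additive coding.** Genotypes are minor-allele dosages in {0, 1, 2};
  all association models are linear in dosage. Missing dosages are
  mean-imputed per SNP at scan time (QC statistics never impute), with
  an exact case-deletion mode available (`assoc_scan(...,
  case_deletion=True)`).
- **ICV normalization.** `ROI_norm = ROI_raw − ε·(ICV_raw − ICV_mean)`
  with ε the OLS slope fitted on normal controls only — the
  volume-to-head-size relationship is taken from the physiological
  group because it need not be stable under atrophy — and ICV_mean the
  grand mean over all samples. The adjustment is location-equivariant
  in ICV and leaves samples at the grand-mean ICV untouched.
- **Clustering.** Complete-linkage agglomeration on d = 1 − |r|
  (absolute Pearson correlation of normalized volumes). The absolute
  value matters: ventricular volumes anti-correlate with tissue
  volumes, and magnitude, not sign, is what groups structures;
  d = 1 − r is available via `distance="corr"`. The tree is cut into
  exactly k clusters (default 5).
- **GWAS.** Per SNP, `trait ~ 1 + dosage + age + sex + education`, with
  the t-test on the dosage coefficient. The scan residualizes the trait
  and all dosages against the covariate block once
  (Frisch–Waugh–Lovell) and is numerically identical to per-SNP fits.
- **Interaction test.** The t statistic of the product term in
  `trait ~ 1 + g1 + g2 + g1·g2 + covariates`, computed as the partial
  correlation between trait and product residuals given {intercept,
  covariates, g1, g2}, with df = n − q − 1 (q conditioning columns).
  Products are formed on raw dosage codes; the projection does all
  centring, so results match the explicit full-model fit to machine
  precision. The anchored scan conditions each anchor once and folds
  each partner into the conditioning set by the three-variable
  partial-correlation identity, making the genome-wide pass a handful
  of matrix products. Anchor–anchor pairs are not tested: the degree
  tables count anchor↔non-anchor edges only.
- **Selection.** Significant SNPs: p < 1×10⁻⁴ (strict). Main-effect
  SNPs: five smallest p. Interaction edges: p < 5×10⁻⁴ (strict).
  Interactive-effect SNPs: top three partners by degree; ties break by
  smallest edge p, then lexicographic id, so selection is invariant to
  edge-list order.

## QC thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| sample/variant call rate | ≥ 0.90 | fraction of non-missing calls |
| HWE exact α | 5×10⁻⁷ | exclusion if p ≤ α; females only on X |
| MAF | ≥ 0.10 | folded minor-allele frequency |
| PI_HAT | > 0.2 | related-pair exclusion threshold |
| LD pruning | 50 / 5 / 0.8 | window, step, r² cap |
| sex-check t_male / t_female | 0.05 / 0.15 | X-het rate cut-offs |

Filter order: sample call rate → sex concordance → relatedness, then
variant call rate → HWE → MAF, then pruning; each removal carries the
first applicable reason, and QC is idempotent on its own output. The
Hardy–Weinberg test is the conditional exact test on the heterozygote
count given allele counts (log-factorial implementation, verified
exhaustively against big-integer enumeration for all tables n ≤ 200).
PI_HAT uses IBS method-of-moments with genome-wide allele frequencies
scaled by each pair's non-missing count; PLINK's finite-sample bias
corrections are omitted as unnecessary for the
duplicate-versus-unrelated discrimination the pipeline needs, and only
the final PI_HAT (not the intermediate moment estimates) is clamped to
[0, 1] to keep the null estimate unbiased. With fewer than ~1,000
variants the estimate is noisy (a warning fires below 50); the
pipeline computes it on all autosomal variants before pruning.

LD pruning removes, within each sliding window (pairs visited in index
order), the lower-MAF member of any pair with r² above the cap (tie:
later position); with the window spanning a whole chromosome it
reduces to the brute-force greedy rule, which the tests exploit as an
oracle.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not human genetics in detail:

- **Genotypes**: independent biallelic SNPs in HWE, MAF ~
  Uniform(0.1, 0.5); optional LD blocks by Markov haplotype copying
  (allele copied from the left neighbour with probability ρ = 0.9,
  else redrawn at the block's shared MAF), giving geometric r² decay;
  an X-flagged chromosome (5% of SNPs) where males carry one haplotype
  (reported as homozygous calls), so sex is encoded in X
  heterozygosity. Chromosome/position metadata are synthetic
  (contiguous runs over chromosomes 1–22, 5 kb spacing).
- **Phenotypes**: per structure, a typical adult volume (per-side,
  mm³), plus ε·(ICV − 1.5×10⁶) scaling with ICV ~ N(1.5×10⁶, 1.5×10⁵)
  mm³ truncated positive and ε = typical volume / mean ICV
  (proportional head-size scaling); a per-module latent factor
  (relative sd 0.03, loading = typical volume) inducing within-module
  correlation ≈ 0.9 at the default noise (sd 1% of typical volume);
  planted main effects (added per allele to every member phenotype),
  planted interaction effects on **centred**-dosage products (so
  interaction betas do not leak into marginal scans); small
  age/sex/education effects; Gaussian residuals. Demographics (AD
  fraction 177/388, age ~ 75.5 ± 6, education ~ 15.4 ± 3, MMSE and
  CDR-SB score distributions per group) follow the published AD/NC
  cohort summaries.
- **Defects** (for QC tests): per-sample/per-SNP missingness,
  duplicated samples, flipped reported sex, SNPs with forced genotype
  counts (HWE violations), forced-low-MAF SNPs.

The **strong-signal preset** plants 5 graded main-effect SNPs and 2
interaction-partner SNPs per module, each partner interacting with 3
distinct anchors (mirroring the multi-anchor degrees the selection
rewards). Effect sizes are stated in units of the base trait sd
(factor + noise): strongest main 2.6 base-sd per allele, grading down
6% per rank; each interaction edge 1.3 base-sd per sd of product.
Because every planted effect inflates the trait variance all others
are measured against, realised standardized effects are roughly a
quarter of the nominal values; the defaults keep the weakest planted
main around |t| ≈ 5 at n = 400–500, above the genome-wide noise floor.
Planted SNPs are drawn outside LD blocks with MAF ≥ 0.3: balanced
dosages have negligible skewness, so products of pairs sharing a SNP
stay nearly uncorrelated and the pairwise interaction fits are
unbiased — at skewed MAF, third-moment correlations between the many
planted terms visibly attenuate pairwise estimates.

What the generator does **not** model: realistic human LD maps or
allele-frequency spectra, population structure, genotyping batch
effects, non-Gaussian volume distributions, hemispheric asymmetry,
diagnosis-dependent atrophy of specific modules. Passing the recovery
tests therefore shows the pipeline is correct and well calibrated
under its own modelling assumptions, not that it would have power on
any particular real cohort.

## Numerical choices

- Monomorphic SNPs (zero residual dosage variance) are flagged and
  reported with p = 1, se = ∞, never dropped silently; collinear
  interaction products likewise return (0, 1).
- p-values are floored at the smallest positive double within the
  tests and at 10⁻³⁰⁰ for −log₁₀ transforms in the Manhattan tables.
- The HWE p-value counts tables with probability ≤ observed × (1 +
  10⁻¹²) so exact ties land on both sides identically.
- Clustering is an explicit O(n³) agglomeration (n = 35) with a
  deterministic tie-break — the smallest cluster-index pair merges
  first — and module ids are renumbered in order of first appearance;
  scipy's implementation is used as an independent cross-check in the
  tests rather than as the implementation, to control tie behaviour.
- The interaction test orders (g1, g2) canonically before projecting,
  making it exactly symmetric in its arguments.
- Two runs with the same config and seed produce byte-identical
  tables; all randomness flows from integer seeds through
  `numpy.random.default_rng` / `SeedSequence`.

## Problem sizes

The default end-to-end synthetic study runs 500 samples × 5,000 SNPs
(about 10 s on one CPU, dominated by the relatedness matrix products
and the per-variant HWE loop); calibration checks use 1,000 null SNPs
at n = 500 for the GWAS and 1,500 null pairs at n = 400 for the
interaction test, sized so the α = 0.05 rejection rate is testable
against binomial 99% bounds. The exhaustive HWE sweep covers every
genotype table with n ≤ 200 by enumerating the ~20,000 (n, rare-count)
conditional classes once each.

## Known limitations

- The relatedness estimator is not a substitute for PLINK `--genome`
  on real data (no finite-sample corrections, no per-pair allele
  frequencies); at a few hundred variants its PI_HAT noise approaches
  the 0.2 exclusion threshold.
- The anchored scan tests partners marginally (one pair at a time);
  with several strong overlapping planted interactions the pairwise
  estimates can be attenuated relative to the joint model, which is a
  property of the method, not of the implementation.
- X-chromosome association is not sex-stratified; X SNPs are excluded
  from the scans (autosomes only), and X handling is limited to the
  sex check and female-only HWE.
- Module counts other than k = 5 are supported but untested against
  any anatomical expectation.
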