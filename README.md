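# qtmod — quantitative-trait-module GWAS of subcortical brain volumes

`qtmod` implements a module-based genetic analysis of structural brain
phenotypes, of the kind used to study Alzheimer's disease (AD) against
normal controls (NC). Instead of running one GWAS per brain structure,
it groups the 35 Freesurfer-segmented subcortical volumes into a small
number of co-varying **modules** (limbic system, corpus callosum,
thalamus–cerebellum–brainstem, neostriatum, ventricular system), uses
each module's summed volume as a quantitative trait, and finds both
**main-effect** SNPs and **interactive-effect** SNPs for each module.
It is aimed at imaging-genetics practitioners who want the whole chain
— genotype QC, volume normalization, module clustering, association
and epistasis scans — as one tested, reproducible pipeline, plus a
synthetic-data generator with planted ground truth for validating it.

## The method

1. **Genotype QC** (PLINK-style thresholds): samples need call rate
   ≥ 90%, concordant genetic/reported sex (X-heterozygosity), and no
   relative with PI_HAT > 0.2 (IBS method-of-moments; one member of
   each related pair is dropped). Variants need call rate ≥ 90%,
   Hardy–Weinberg exact p > 5×10⁻⁷ and MAF ≥ 10%, and are then
   LD-pruned with the `indep-pairwise 50 5 0.8` rule.
2. **ICV normalization.** Head size is removed by the residual
   adjustment

   ROIⁱ_norm = ROIⁱ_raw − εᵢ · (ICV_raw − ICV_mean)

   where εᵢ is the OLS slope of structure *i*'s raw volume on total
   intracranial volume fitted **in the NC group only**, and ICV_mean is
   the mean ICV over all samples.
3. **Module clustering.** Pearson correlations of normalized volumes
   across samples; complete-linkage agglomeration on the dissimilarity
   d = 1 − |r|; the tree is cut into k = 5 modules; a module's trait is
   the per-sample sum of its members' normalized volumes.
4. **Module GWAS.** Per SNP, OLS of trait ~ intercept + dosage + age +
   sex + education; two-sided t-test on the dosage term; SNPs with
   p < 1×10⁻⁴ are significant; the five smallest-p SNPs are the
   module's main-effect SNPs.
5. **Anchored epistasis scan.** Every (main-effect SNP, partner) pair
   is tested for a product-term effect in trait ~ intercept + g₁ + g₂ +
   g₁g₂ + covariates, computed as a partial correlation so one anchor
   is screened against the genome in a single matrix pass; pairs with
   p < 5×10⁻⁴ are kept as network edges.
6. **Interactive-SNP selection.** Partners are ranked by degree (number
   of distinct anchors they interact with); the top three are the
   module's interactive-effect SNPs.

## Worked example

```python
from qtmod import RunConfig, run_pipeline

cfg = RunConfig(out_dir="demo_run", seed=7, n_samples=400, n_snps=1500,
                n_ld_blocks=3)           # strong-signal synthetic preset
report = run_pipeline(cfg)

print(report["modules"]["sizes"])
print(report["per_module"]["1"]["main_effect_snps"])
print(report["recovery"]["module_ari"],
      report["recovery"]["main_effect_in_top"])
```

prints

```
{1: 6, 2: 11, 3: 4, 4: 5, 5: 9}
['snp001211', 'snp000389', 'snp000685', 'snp000231', 'snp000298']
1.0 25
```

Reading: the 35 phenotypes were cut into five modules of sizes
6/11/4/5/9 (the planted anatomical grouping, adjusted Rand index 1.0
against truth); module 1's five main-effect SNPs are listed with
p-values from 2.5×10⁻¹² up, and all 25 planted main-effect SNPs across
the five modules were ranked in their module's top five. The run
directory holds every stage's tables: QC report, normalized volumes,
correlation matrix, partition, per-module GWAS and Manhattan tables,
interaction edge lists and the interactive-SNP selections.

The same stages are available as subcommands:

```bash
qtmod simulate --n-samples 400 --n-snps 1500 --seed 7 --out run/sim
qtmod qc       --geno run/sim/genotypes --out run/qc
qtmod modules  --pheno run/sim/phenotypes.tsv --k 5 --out run/mod
qtmod gwas     --geno run/qc/genotypes_qc --traits run/mod/module_traits.tsv \
               --pheno run/sim/phenotypes.tsv --module 1 --out run/gwas
qtmod epistasis --geno run/qc/genotypes_qc --traits run/mod/module_traits.tsv \
               --pheno run/sim/phenotypes.tsv --module 1 \
               --anchors run/gwas/anchors.txt --out run/epi
qtmod network  --edges run/epi/interactions_module1.tsv --top 3 --out run/net
qtmod run      --config run.yaml      # the whole pipeline from YAML
```

Genotypes travel as PLINK-style text `.ped`/`.map` (or a TSV dosage
matrix), phenotypes and results as TSV, reports as JSON.

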