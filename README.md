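# gutdiv

Analysis pipeline linking the nutrient concentration of a host's diet to the
abundance and diversity of its gut microbiota, built around 16S rRNA
amplicon OTU tables from *Drosophila melanogaster* populations kept on diets
differing only in yeast concentration (4%, 10% or 27% w/v, four replicate
populations each, plus one mock negative-control sample).

The chain it implements:

1. **Mock-anchored OTU filtering.** *Wolbachia* reads (the intracellular
   symbiont dominates the amplicon pool) are partitioned out by taxonomy.
   OTUs must be present in ≥ 3 gut samples with ≥ 24 reads in total, and
   their estimated absolute abundance
   `a_ij = reads_ij / total reads_j × conc_j` (with `conc_j` the 16S DNA
   concentration of sample *j* relative to the mock, from qPCR) must exceed
   the mock's ≥ 10-fold in ≥ 3 gut samples.
2. **Multi-rarefaction diversity.** All diversity statistics are computed on
   many tables independently rarefied (hypergeometric subsampling) to the
   smallest sample's read total — 1000 runs for alpha diversity (Shannon
   *H*, Faith's PD, abundance-weighted PD), 100 for beta diversity
   (Bray–Curtis, weighted UniFrac) — and reported as mean ± SD or as
   median [min–max] across runs, so rarefaction noise is propagated rather
   than averaged away.
3. **Permutational tests.** PERMANOVA (pseudo-*F* on the Gower-centered
   matrix of −½D², yeast % as a continuous covariate, significance by
   covariate permutation), the centroid-based homogeneity-of-dispersions
   permutation test, and the multivariate variance Σdᵢ²/(n−1) of replicate
   communities around their diet centroid in 2-D NMDS space.
4. **Dual absolute abundance.** The microbiota:*Wolbachia* read ratio and
   efficiency-corrected qPCR ΔCt ratios
   (`(1+E_ref)^Ct_ref / (1+E_target)^Ct_target`) of Acetobacteraceae and
   Firmicutes 16S copies against the host rp49 gene; both log₁₀-transformed
   and regressed on yeast concentration.

Because the real sequencing data live in external archives, the package
ships a fully specified synthetic-experiment generator
(`gutdiv.simulate`) that reproduces the study's design and assumed
statistical structure — *Wolbachia*-dominated read pools, a log-linear
abundance gradient spanning read ratios ≈ 0.003 → 1.1 across diets,
Dirichlet-multinomial compositions whose evenness falls with yeast content,
reagent-level mock contamination, and qPCR Ct values derived from the same
ground truth — so every stage is testable end to end with known truth.

## Worked example

The `analysis/` scripts run the full chain on one synthetic experiment:

```
python analysis/01_simulate_experiment.py
python analysis/02_filter_otus.py
python analysis/03_alpha_diversity.py
python analysis/04_beta_diversity.py
python analysis/05_abundance.py
python analysis/06_robustness.py
```

Output of steps 2–5 (seed 11):

```
filtering: 83 input OTUs -> 68 pass prevalence -> 51 retained (26 were
detected in the mock, 17 removed as putative contamination)
  seeded contaminants removed: 17/17

alpha diversity over 1000 rarefactions at depth 1206 reads:
  shannon      4%:  3.117  27%:  1.455 (53.3% decline)  slope -0.0677, p = 7.07e-06
  pd           4%: 12.049  27%:  5.945 (50.7% decline)  slope -0.2416, p = 6.23e-05
  weighted_pd  4%:  4.333  27%:  1.306 (69.9% decline)  slope -0.1177, p = 1.89e-04

beta diversity over 100 rarefactions (median [min-max] across runs):
  bray_curtis:      adonis F = 1.99 [1.90-2.11], p = 0.010, R2 = 0.17
  weighted_unifrac: adonis F = 1.40 [1.28-1.63], p = 0.197, R2 = 0.12

microbiota:Wolbachia read ratio by diet (mean over 4 replicates):
  4% yeast: 0.0065   10% yeast: 0.0424   27% yeast: 0.5938
  read_ratio: b = +0.0855, adj R2 = 0.85, p = 1.29e-05
```

Reading: the two-step filter removed all 17 seeded contaminant OTUs while
keeping the genuine community; alpha diversity falls by half or more from
the 4% to the 27% diet while total microbiota abundance rises by roughly
two orders of magnitude; community composition shifts with diet are
detectable with Bray–Curtis but not with the phylogeny-aware weighted
UniFrac at this effect size. Statistics are medians and ranges over
independent rarefactions, so the uncertainty due to subsampling is visible
in the report itself.

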