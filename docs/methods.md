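# Methods

## The inference chain

The package treats one question — how does the nutrient concentration of a
host diet shape the abundance and diversity of the gut microbial
community? — as a chain of five stages, each exposed as library functions
and composed by `gutdiv.pipeline.run_pipeline`.

**Wolbachia partitioning.** Universal 16S primers amplify the intracellular
symbiont *Wolbachia*, which is not part of the gut community but can
dominate the read pool, especially where true microbiota abundance is low.
OTUs whose RDP-style lineage contains the genus name (case-insensitive
substring, robust to rank-prefix formatting) are removed and their
per-sample read totals kept aside; reads are conserved exactly. A reserved
row id `__wolbachia__` is honoured for tables that store the symbiont as a
pre-summed total rather than an OTU row.

**Two-step filtering.** Step 1 removes spurious OTUs: retained OTUs must be
present (> 0 reads) in at least 3 gut samples and carry at least 24 reads
summed over the gut samples; the mock sample is excluded from both
criteria. Step 2 removes contamination: each OTU's absolute abundance is
estimated as relative read abundance times the sample's total 16S DNA
concentration measured by qPCR relative to the mock (so the mock's own
concentration is 1 by construction), and an OTU is kept only if that
abundance is at least 10-fold the mock's in at least 3 gut samples. All
three thresholds are inclusive (≥). An OTU absent from the mock passes
step 2 whenever it is present in 3 gut samples — 10 × 0 = 0 would make the
rule vacuous, so the behaviour is made explicit. The step order is fixed
(prevalence first) and recorded in the report, along with a per-OTU
decision trail. When the count table holds only the microbiota reads while
the qPCR concentration refers to total 16S DNA (including *Wolbachia*),
the caller passes the full per-sample read totals as the denominator;
the two conventions cancel so that `a_ij` estimates the same mock-relative
quantity either way.

**Multi-rarefaction.** Rarefaction subsamples each sample without
replacement (multivariate hypergeometric) to a common depth, by default the
smallest sample's total ("auto"); a fraction of that depth (e.g. 0.75) is a
supported robustness variant. Because a single rarefaction is an arbitrary
draw, every statistic is computed on many independently rarefied tables —
1000 for alpha, 100 for beta by default — and summarised as mean ± SD
(alpha, per sample) or median and [min, max] (test statistics, including
p-values). No cross-run combination rule is applied to p-values; the range
is reported as-is. Per-run seeds are stretched deterministically from one
master seed, so an ensemble is reproducible from a single integer. Both
distance metrics share the same beta ensemble.

**Diversity indices.** Shannon diversity H = −Σ p ln p (natural log;
base-2/10 available). Faith's PD is the branch length of the subtree
spanning the present OTUs, including the path to the root (a rootless
variant is available). Abundance-weighted PD follows the weighted-Faith
form PD_w = S · (Σ_b l_b A_b)/(Σ_b A_b) with A_b the mean relative
abundance of present OTUs below branch b and S the number of present OTUs;
the un-normalised Σ l_b A_b variant is exposed behind a flag because the
literature uses both. No rRNA copy-number correction is applied anywhere.
All indices are evaluated through a precomputed branch × OTU incidence
matrix, which turns a 1000-run ensemble into dense linear algebra.

**Distances, ordination, tests.** Bray–Curtis Σ|x−y|/Σ(x+y) (scipy) and
weighted UniFrac Σ_b l_b |p_b(x) − p_b(y)|, normalised by
Σ_b l_b (p_b(x)+p_b(y)) by default, raw form available. PERMANOVA uses the
Gower-centered inner-product matrix G = −½ J D² J; for the single
continuous covariate (yeast %) the model sum of squares reduces to u'Gu
with u the centred, normalised covariate, F = SS_model / (SS_resid/(n−2)),
and the p-value counts covariate permutations with F* ≥ F under the
(1+hits)/(1+n_perm) rule (999 permutations by default; exact enumeration
for small n). The dispersion test embeds samples by PCoA retaining
negative eigenvalues, measures each sample's distance to its group
centroid with the imaginary-axis correction (positive-axis squared
distance minus negative-axis squared distance, floored at 0), and permutes
group labels of those distances under a one-way ANOVA F. The multivariate
variance Σdᵢ²/(n−1) of replicate communities about their diet centroid is
computed in 2-D NMDS space (per the figure convention; PCoA coordinates
can be supplied instead). NMDS minimises Kruskal stress-1 by nonmetric
SMACOF (scikit-learn) over several random starts plus one PCoA-seeded
start, keeping the best.

**Abundance quantification.** The read route divides the filtered
microbiota read total by the *Wolbachia* total per sample. The qPCR route
uses the efficiency-corrected ΔCt model
ratio = (1+E_ref)^Ct_ref / (1+E_target)^Ct_target, technical replicates
averaged on the Ct scale first; a perfect-efficiency mode is available
since reports do not always state whether correction was applied. Both
ratios are log₁₀-transformed and regressed on yeast % (OLS, adjusted R²,
two-sided t-test on the slope), with a categorical ANOVA + Tukey HSD
variant alongside. Samples with a zero numerator are flagged and excluded
from the log regression, never silently dropped.

## The synthetic-experiment generator

`gutdiv.simulate.simulate_experiment` draws complete data sets — counts,
mock, tree, taxonomy, qPCR, ground truth — from a generative model whose
defaults encode the study design: 3 diets × 4 replicate populations, 66
genuine OTUs plus 17 reagent-contaminant OTUs plus one *Wolbachia* OTU.

Diet enters through exactly three knobs, matching the three phenomena the
analysis is meant to detect:

- `ratio_by_diet = (0.003, 0.03, 1.1)` — the expected
  microbiota:*Wolbachia* ratio per diet. Per-replicate ratios scatter
  log-normally around these anchors (`log10_ratio_sd = 0.3`, a free
  parameter: no within-diet overdispersion estimate exists to pin it). The
  implied true abundance slope is the least-squares slope of log₁₀(anchor)
  on yeast %, ≈ 0.107 decades per percentage point, i.e. ≈ 2.5 orders of
  magnitude from 4% to 27%.
- `dirichlet_by_diet = (50, 10, 2)` — the Dirichlet concentration around a
  shared geometric base community (`base_decay = 0.94`, ~66 ranked OTUs
  with the top ten holding most of the mass). Falling concentration along
  the yeast gradient produces the alpha-diversity decline (~50% for
  Shannon at these values) while keeping the same expected composition.
- `wolbachia_quantity` (constant across samples) converts ratios to
  absolute microbiota quantities, from which reads are allocated
  multinomially and qPCR Ct values are derived via the inverse of the
  efficiency-corrected ΔCt model plus Gaussian cycle noise
  (`ct_noise_sd = 0.15` cycles, a typical technical-replicate scatter).

Contaminant OTUs carry a constant absolute reagent load in every sample
including the mock — which is what makes the mock-relative 10-fold rule
work, and which also means they are *relatively* prominent exactly where
true abundance is low (the 4% diet), as in real data. The mock additionally
receives trace leaks (10⁻³ of mean gut quantity) of the 9 most abundant
genuine OTUs, so 26 of the OTUs reaching step 2 are detected in the mock
while only the 17 true contaminants should fall to the filter.
`reads_per_sample = 600 000` and the 0.003 anchor put the smallest
microbiota sample near 1.8 k reads, the depth regime of the study;
`SimulationConfig.null()` removes all diet dependence for calibration work.

What the generator does **not** emulate: taxonomic identity of real OTUs,
sequence-level error and chimeras, copy-number variation,
*Wolbachia*-titre responses to diet, and — importantly — homogeneous
within-diet dispersion: making high-yeast communities spikier necessarily
also makes them more variable between replicates, so the generator
produces heterogeneous dispersions where the original system showed none.
Tests passing on this generator therefore demonstrate correct machinery
and recoverable effects at realistic sizes, not distributional fidelity of
every statistic to the real data.

## Numerical and design choices

- Permutation p-values include the observed statistic ((1+hits)/(1+N)),
  so the smallest attainable p is 1/(N+1) and p = 0 is impossible.
- The dispersion test uses group centroids, not vegan's default spatial
  medians, because the variance definition is stated in terms of centroid
  distances. The implementation reproduces R vegan
  `betadisper(type="centroid")` + `permutest` exactly (cross-validated in
  the test suite). A caveat documented there: at very small group sizes
  (4 replicates per diet) the centroid variant is liberal — its type-I
  error is ≈ 0.12 at α = 0.05 under the null generator, a property of the
  published procedure itself (vegan's centroid variant shows the same
  rate), not of this implementation.
- PCoA keeps negative eigenvalues; distances to centroids subtract the
  negative-axis contribution and floor at 0 before the square root, which
  prevents NaNs on strongly non-Euclidean Bray–Curtis matrices.
- NMDS defaults: k = 2, 20 restarts (4 inside the pipeline loop, where 200
  fits per report are needed), convergence tolerance 1e-4 on stress.
  Isotonic-regression ties are averaged.
- "Most abundant on average" for the top-N robustness variant means the
  mean of per-sample relative abundances (depth-robust); pooled read
  ranking is available behind a flag. Ties break by total reads, then id.
- Rarefied ensembles are stored as a dense (runs × OTUs × samples) integer
  array; at the default problem size (≈ 50 OTUs × 12 samples × 1000 runs)
  this is a few megabytes.
- The acceptance script runs the pipeline at the full 1000/100/999 setting
  on one simulated experiment; the calibration and recovery studies in the
  test suite use 1000 null simulations and 500 recovery simulations at the
  12-sample design, sizes at which binomial/SE bands are tight enough to
  be meaningful while the whole suite stays desk-scale.

## Known limitations

- One continuous predictor only; no multi-factor or stratified PERMANOVA.
- No alternative depth standardisations (coverage-based approaches) and no
  statistical decontamination models — only the mock-anchored rule.
- The dispersion test's small-sample liberality above means its p-values
  at the 4-replicate design should be read qualitatively.
- The exact weighted-PD estimator used by any given study is often
  unrecoverable from methods text; both common variants are implemented
  and the normalised weighted-Faith form is the default.
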