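# Methods

## Model and assumptions

`mrscreen` performs two-sample Mendelian randomization: per-SNP
association estimates for an exposure (here, the relative abundance of a
gut-bacterial taxon) and an outcome (a disorder or trait) come from two
non-overlapping GWAS, and the causal effect b of exposure on outcome is
estimated from the relation β_Yj ≈ b·β_Xj across instruments j.  Validity
rests on the three instrumental-variable assumptions: each instrument is
(1) associated with the exposure, (2) independent of exposure–outcome
confounders, and (3) affects the outcome only through the exposure
(exclusion restriction).  The five estimators trade efficiency against
robustness to violations of (3):

- **Wald ratio** (k = 1): β_Y/β_X with first-order delta SE σ_Y/|β_X|.
  The first-order approximation ignores the β_X denominator noise, which
  is why instrument strength is always reported alongside.
- **IVW**: origin-constrained weighted least squares, weights 1/σ²_Yj;
  efficient but biased by any directional pleiotropy.
- **Profile-likelihood MLE**: the joint normal likelihood in (b, γ_1…γ_k)
  with γ profiled out analytically; unlike IVW it models exposure-side
  measurement error, removing regression-dilution bias when instruments
  are modest.
- **MR-Egger**: frees the intercept, which absorbs (and estimates) the
  average directional pleiotropy under the InSIDE assumption; p-values use
  t with k−2 df.
- **Weighted median**: consistent while valid instruments carry > 50% of
  the weight; SE from a parametric bootstrap.
- **MR-PRESSO**: identifies instruments whose residual about leave-one-out
  IVW fits is extreme relative to a parametric null, and iteratively
  prunes them.

The screen applies IVW as the primary decision statistic — the other
estimators annotate concordance (sign agreement plus nominal
significance) — and controls multiplicity per taxonomic level with
0.05/(number of taxa tested at that level); the six levels are phylum,
class, order, family, genus, species.  The reverse screen swaps roles and
uses a single 0.05/(number of reverse pairs) threshold.  These divisors
are the raw counts of tested taxa; an effective-number override
(`ScreenConfig.effective_counts`) exists for users who prefer a
correlation-adjusted count.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| selection threshold | 1 × 10⁻⁵ | suggestive genome-wide level; microbiome GWAS yield too few 5 × 10⁻⁸ hits per taxon |
| clumping r² / window | 0.1 / 500 kb | approximate instrument independence; pairs beyond the window are treated as independent, |pos difference| ≤ 500,000 triggers the r² check |
| weak-instrument flag | F < 10 | conventional cutoff for meaningful weak-instrument bias |
| PRESSO simulations | n_sim = 1000 | smallest attainable p is 1/(n_sim+1) ≈ 0.001, enough resolution for the 0.05 stopping rule |
| PRESSO stopping rule | global p > 0.05 (strict) | p = 0.05 exactly continues pruning |
| WME bootstrap | n_boot = 1000 | SE stable to ~2% run-to-run at k ≈ 10–30 |
| confounder filter | p < 0.05, any trait | nominal-level exclusion of instruments associated with listed confounder traits |

## Numerical choices

- **IVW/Egger SEs** use the multiplicative random-effects convention: the
  fixed-effect SE is scaled by max(1, residual SD), so under-dispersion
  never shrinks the SE below its fixed-effect value.  This matches the
  dominant convention in the field's R tooling (algebraically,
  `se / min(1, sigma)` applied to the classical WLS SE).  It makes both
  tests mildly conservative under exact homogeneity (measured IVW type-I
  ≈ 0.04–0.05 at k = 20 in the acceptance run).
- **MLE** maximizes the profile log-likelihood on b ∈ [−50, 50]
  (standardized effects make |b| ≫ 10 implausible) by bounded scalar
  minimization with tolerance 1e-10; the SE is the inverse square root of
  the negative curvature, estimated by a central second difference with
  step 1e-4·max(1, |b̂|).  A dense-grid oracle in the tests guards the
  bracket and the optimizer.
- **Weighted median** interpolates the sorted ratios at cumulative weight
  0.5 (s_j = Σ_{i≤j} w_i − w_j/2), clamping at the extremes.  The
  parametric bootstrap redraws both β_X and β_Y from their reported
  normals and recomputes the weights per replicate.  This canonical
  bootstrap is conservative under strict homogeneity — the bootstrap
  population convolves the between-ratio spread with a second copy of the
  per-ratio noise — so its null rejection rate at 0.05 measures ≈ 0.02–0.03
  rather than 0.05; this is a property of the published estimator, not of
  this implementation.
- **MR-PRESSO** removal order is the initial ascending outlier-p ranking
  (re-ranking after each removal available via `rerank=True`).  The
  outlier p-values are discrete with floor 1/(n_sim+1); ties — common at
  the floor when several SNPs look extreme, including clean SNPs whose
  leave-one-out slopes are contaminated by true outliers — are broken by
  descending observed weighted residual, the quantity the outlier test
  ranks.  Outlier p-values are Bonferroni-multiplied by k for reporting;
  the recursion's stopping criterion uses the global p only.  Pruning
  stops with an `UncorrectablePleiotropyError` if fewer than 4 instruments
  would remain while the global test is still significant; the screen
  reports such pairs with a status code and falls back to estimates on the
  instruments pruned so far.
- **Steiger** compares R² = Σ 2f(1−f)β² on the two sides (the same closed
  form for binary and continuous traits; liability-scale refinement is out
  of scope) and tests √R²_X vs √R²_Y as Fisher-transformed correlations at
  the two (median per-SNP) sample sizes.
- **Harmonization** resolves allele swaps (negate β_Y, reflect the
  frequency) and strand flips (complement both outcome alleles), dropping
  anything irreconcilable.  Because all palindromic SNPs are deleted
  up front, frequency-based strand inference is never needed; frequencies
  are carried only for diagnostics and Steiger.  Duplicated identifiers
  are removed entirely (all copies) on either side.
- **Clumping** is greedy in ascending p, ties broken by (chromosome,
  position, identifier); SNPs absent from the LD reference are kept as
  their own index with a warning (`strict_missing=True` drops them),
  mirroring the behaviour of the standard clumping tool.
- p-values are two-sided throughout and floored at the smallest positive
  double rather than 0.
- Summary-statistics parsing uses Python's correctly-rounded float
  conversion so that write→read round-trips are bit-exact.

## The synthetic generator

`SimScenario`/`simulate_pair` emulate the statistical structure of a
standardized-phenotype GWAS pair: per-SNP SEs follow 1/√(2f(1−f)n), MAFs
are uniform on (0.05, 0.5], latent instrument effects are rescaled so the
realized Σ 2f(1−f)γ² equals the target R² exactly, and observed betas are
drawn around their truths at the closed-form SEs.  Scenario defaults
mirror the strongest exposure–outcome pair of the reference study design
(13 instruments, R² = 2.61%, n_exposure = 18,473, n_outcome = 46,351,
b = 0.24).  Pleiotropy regimes: none; balanced (α ~ N(0, s²));
directional (α aligned with the exposure-increasing allele,
sign(γ)·N(s, (s/2)²) — without the sign alignment, random effect-allele
coding would cancel the mean shift); gross outliers (±10 outcome-SEs on a
designated fraction).  LD is AR(1) within blocks on one pseudo-chromosome
per block, SNPs 10 kb apart so the clumping window is exercised;
designated fractions of SNPs receive palindromic alleles, complemented
outcome alleles, or duplicated identifiers.  Instrument magnitudes are
drawn U(0.5, 1.5) before rescaling so no planted instrument is
vanishingly weak; they are strong enough that p < 10⁻⁵ selection retains
most of them ("above threshold by construction"), and `from_pool=True`
instead lets selection act on a genome-wide pool, winner's curse included.

The screen bench (`simulate_screen_bench`) gives every feature a disjoint
SNP set and every outcome trait its own instruments that are null on all
features — the traits are heritable in their own right — so reverse
screening selects trait loci rather than only feature-mediated SNPs, as
it would against real disorder GWAS.

What the generator does **not** emulate: logistic/liability scale for
binary traits (effects are standardized-linear on both sides), LD between
an instrument's summary statistics and its neighbours' (LD affects
clumping input only), multi-ancestry frequency structure, sample overlap
between the two GWAS, and winner's curse under default settings.  Passing
tests therefore demonstrate correctness of the algorithms under the
stated generative model, not robustness to these real-data features.

## Problem sizes used in validation

The acceptance script and test suite use 1000 replicates for calibration
and recovery checks (Monte-Carlo SE on a rejection rate ≈ 0.007; on a
mean effect ≈ 0.001–0.002), 100–200 seeded runs for MR-PRESSO detection
rates, 400–500 replicates for distributional (KS) and directionality
checks, and 5–8 seeds × 36 pairs for full-screen benches.  These sizes
put Monte-Carlo noise well below every asserted margin.

## Known limitations

- The Wald-ratio and IVW SEs ignore exposure-side noise (first-order);
  the MLE is provided precisely to quantify that gap, and recovery tests
  bound the IVW attenuation at the default conditions to < 0.02 absolute.
- With b ≠ 0, exposure-side noise makes the residual variance about the
  IVW fit exceed σ²_Y by b²σ²_X, so Q and the PRESSO global test become
  slightly anticonservative for strong causal effects with
  n_outcome ≫ n_exposure; at the study-scale conditions used here the
  effect is small (pruning terminates correctly in ≥ 93% of contaminated
  runs and removes nothing in clean ones).
- Correlated instruments are handled only by exclusion (clumping), not by
  a generalized (correlation-aware) IVW; proxy lookup for instruments
  missing from the outcome GWAS is not implemented.
- The per-level Bonferroni correction treats taxa as independent; nested
  taxa (a genus inside a family) share instruments, so the screen's
  significant sets can contain such duplicates by design.
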