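# Methods

This note records the models implemented in `ibdpd`, the defaults and why
they were chosen, the numerical machinery, and what the synthetic-data
tests do and do not demonstrate.

## Qualifying-variant cascade

A variant qualifies under the deleterious model iff all of the following
hold, evaluated in the fixed order impact → MSC → GDI → MAF (the first
failed rule is recorded per variant):

1. **Impact**: the sequence-ontology consequence is in the high-impact
   list (start/stop lost, stop gained, splice acceptor/donor, protein
   altering, start/stop retained, frameshift) or the moderate-impact list
   (missense, in-frame insertion/deletion).  When several terms are
   attached, the most severe wins.
2. **MSC**: moderate-impact variants need CADD strictly greater than the
   lower bound of the gene's 95% mutation-significance-cutoff interval;
   high-impact variants skip this rule.
3. **GDI**: the gene damage index must be strictly below the
   general-disease cutoff, default 13.84 (config, not a constant).
4. **Population MAF**: the maximum allele frequency over all provided
   (source, population) entries must be below 1%.  Entries absent from the
   annotation are treated as frequency 0: a variant unseen in a reference
   population is evidence of rarity, not of commonness.

The synonymous neutral model applies rules 3–4 to synonymous variants
only.  Because the cascade is a conjunction, rule order affects only the
provenance label, never membership.

## Firth regression

Newton iterations on the Jeffreys-penalized binomial likelihood
l(β) + ½ log det X'WX, using the modified score
U\*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij with h_i the weighted-hat
leverages.  Convergence at max |U\*| < 1e-8 or step < 1e-10, at most 100
iterations with up to 25 step-halvings whenever a step would decrease the
penalized likelihood.  Wald p-values are the default (matching the
variant-level association style of genome-tool output); standard errors
come from the inverse Fisher information at the penalized optimum.  On a
saturated 2×2 table the estimate coincides with the half-cell-corrected
odds ratio, which the tests use as a closed-form oracle, and a coarse
grid search of the penalized surface provides an independent check.  A
penalized likelihood-ratio alternative (drop-column refit) is available
for separation-heavy settings.

Wald tests with Firth standard errors are conservative at very small
minor-allele counts; the MAC ≥ 3 / case MAC ≥ 1 entry filter keeps the
variant-level scan out of the worst of that regime, and the calibration
test is run at common-variant counts where the Wald approximation is the
method's stated operating point.

## SKAT, burden and SKAT-O

The null model is an ordinary ML logistic regression of phenotype on
covariates (statsmodels GLM), with a Firth fallback when the covariate
model itself separates.  For a gene with dosage matrix G (missing dosages
imputed to the variant mean) and weights w_j — default the Beta(1, 25)
density at the folded cohort MAF; flat weights selectable —

    Q_rho = r' Z R_rho Z' r,  Z = G diag(w),  R_rho = (1-rho) I + rho 11'.

Under the null, Q_rho ~ Σ_k λ_k χ²_1 with λ_k the eigenvalues of
R_rho^{1/2} (Z' P0 Z) R_rho^{1/2}, P0 = V − VX(X'VX)⁻¹X'V.  The rho grid
is {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.

**Mixture tails.**  P(Σλχ² > q) is computed by numerical inversion of the
characteristic function (Imhof's formula).  The oscillatory integrand is
integrated by composite Simpson on [0, U] with U chosen so that the
integration-by-parts bound on the truncated tail, (2/q)/(U·ρ(U)), falls
below tolerance (1e-9 for reported p-values), and node density tracking
the oscillation frequency q/2.  A single eigenvalue short-circuits to the
exact scaled chi-square.  A moment-matched (modified Liu) surrogate is the
fallback if inversion misbehaves, and supplies starting points for
quantile inversion.

**Minimum-p combination.**  Writing the weighted score s ~ N(0, Σ) as its
burden projection η = 1's/m plus an orthogonal remainder, every Q_rho
decomposes into a common η² term with slope τ(ρ) plus (1−ρ) times one
shared remainder variable W, where W | η is a *noncentral* chi-square
mixture on the remainder spectrum.  The SKAT-O p-value is one minus the
probability that every Q_rho stays below its level-T quantile
(T = min_ρ p_ρ), integrated over the 1-df chi-square of η with the
conditional tail evaluated exactly by a batched noncentral CF inversion.
Evaluating the conditional exactly (rather than through a variance-
rescaled central surrogate) is what keeps the combined p accurate in the
bulk as well as the tail; a 2×10⁵-draw Gaussian Monte Carlo of the same
event agrees to ~1e-3.

**Small-sample calibration.**  When the gene's total minor-allele count is
below 40 (configurable), the Gaussian quadratic-form null is replaced by a
carriers-only parametric bootstrap: Bernoulli phenotypes of the carrier
samples are redrawn from their fitted probabilities (8000 draws, seeded),
giving the joint empirical null of all Q_rho at once.  Two details make
this exact rather than merely approximate.  First, the observed residuals
obey the fitting constraint X'r = 0, so bootstrap scores are compared as
Z'r_b − A·Xc'(y_b − y_obs) with A = Z'VX(X'VX)⁻¹ — the one-step-refit
correction conditional on the non-carrier phenotypes, which vanishes for
the observed configuration and keeps the observed value exchangeable with
the draws.  Second, the null is heavily atomic at these counts, and ties
are resolved by the randomized-p convention: one seeded jitter realization
per draw, shared across the rho grid (independent per-rho randomizations
would bias the minimum over the grid).  The resulting null p-value
distribution is uniform where the exact, super-uniform convention would
deflate genomic-control estimates.  Per-rho p-values and the minimum-p
combination are both taken against this jittered null; beyond the
bootstrap resolution (p ≤ 0.01) a mean/variance/skewness-matched shifted
chi-square fitted to the bootstrap sample extrapolates each per-rho tail
smoothly and the analytic combination takes over.  A residual-permutation
mode (rank-based min-p over the grid, vectorized across permutations)
provides the independent calibration oracle used in the tests.

**Diagnostics.**  λ_GC is the median 1-df chi-square quantile of the
p-values over 0.4549.  The neutral-model check runs SKAT-O on the
synonymous qualifying sets and reports λ_GC, QQ data and genes beyond
Bonferroni.  Note that λ_GC estimated from a few hundred genes has a
standard error of order 0.1–0.2; band-style judgements (0.9–1.1) are made
on pooled sets of ≥ ~1500 genes.

## Cohort QC

- **HWE**: exact test by full enumeration of heterozygote counts
  compatible with the allele counts; the p-value sums configurations no
  more probable than the observed one.
- **Common-variant selection**: cohort MAF > 5%, HWE p ≥ 1e-6,
  missingness ≤ 20% (sample/variant missingness thresholds configurable).
- **LD pruning**: greedy sliding window (50 variants, step 5, r² > 0.2
  removes the later variant); full-pairwise via window=None.
- **PCA**: dosage columns mean-imputed, centred by 2p̂ and scaled by
  √(2p̂(1−p̂)); scores are top singular vectors scaled by singular values,
  sign fixed by making each component's largest-absolute loading positive.
- **Heterozygosity outliers**: samples with heterozygote counts above
  mean + z·SD over a gene set, default z = 4 (the underlying criterion in
  the source analysis is qualitative; z is config).

## Network clustering (NHC-style)

Case gene sets (genes in which a case carries ≥ 1 qualifying allele) are
clustered by scanning the PPI edge-weight threshold from 0.99 down to
0.70 in steps of 0.01: at each threshold, connected components of the
induced subgraph with ≥ 3 genes carried by ≥ 2 distinct cases are emitted
at the first threshold where both conditions hold; a component that
merely grows at lower thresholds is re-emitted only when it gains a new
carrier case.  This descending-threshold scheme is this package's
concrete realization of network-based heterogeneity clustering; all
parameters are exposed.  Cluster burden is a Firth regression of case
status on the cluster carrier indicator plus covariates (Fisher's exact
test available when covariates are off), and clusters whose significant
enrichment (BH-adjusted p < 0.05) matches a supplied control-embedded
pathway list are flagged, not dropped.

## Prioritization

- Candidate pool: SKAT-O genes at p < 0.01 plus genes of significant
  (p < 0.05), non-control-embedded, non-degenerate clusters.
- ORA: hypergeometric upper tail per term against a stated universe,
  Benjamini–Hochberg adjusted.
- Distance-to-set: minimum distance to a member (self excluded) — the
  gene-connectome convention; mean-of-mean selectable.  D_candidate is the
  mean over candidates; within-set values use each member against the
  rest.  The resampling null draws same-size gene sets uniformly from the
  distance matrix's genes minus the known panel (the universe is
  configurable), 10,000 iterations by default, with the add-one estimator
  p = (1 + #{D_random ≤ D_candidate})/(n_iter + 1) so p is never 0.
- Importance scores: per source, a candidate's raw count is the number of
  distinct known-panel genes co-occurring with it in significant terms
  (p < 0.01) or adjacent in a network above a weight cutoff; raw counts
  are max-normalized within (source, panel) and summed over sources for
  the IBD, PD and combined panels.

## PheWAS

Phecode semantics: case iff ≥ 1 mapped diagnosis; excluded iff a non-case
holds a diagnosis inside the phecode's exclusion range (a flag disables
exclusions for a strict mode); control otherwise.  Phecodes with < 20
cases are skipped; controls are randomly downsampled (seeded) to ≤ 99 per
case; excluded samples never serve as controls.  Each (gene, phecode)
runs SKAT-O with the small-sample calibration active and is judged
against 0.05 / (number of phecodes tested).  A small 33-phecode toy map
(including the Parkinson and IBD-subtype phecodes) ships with the package.

## Synthetic cohort generator

The generator is the package's stand-in for the restricted study data and
defines the conditions every statistical test runs under:

- **Design**: 67 cases / 426 controls by default; two subpopulations in
  equal parts with Balding–Nichols drift (per-population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F), F = 0.05), matching the mild European
  substructure of such cohorts.  Only sites observed in the cohort enter
  the VCF, as joint calling would produce.
- **Genes**: 200 genes, Poisson(12) candidate coding variants and
  Poisson(6) synonymous variants per gene with log-uniform ancestral
  frequencies on [1e-3, 1e-2]; after drift and ascertainment this yields
  ≈ 2–3 observed qualifying variants per gene, the density of the
  motivating study.  300 common variants (MAF 5–50%) carry the population
  structure for PCA.
- **Annotations**: qualifying variants get consequences/CADD/population
  frequencies that pass the cascade; decoys fail exactly one named rule
  (impact, MSC or MAF, cycled), and ten designated high-GDI genes fail
  the GDI rule gene-wide.  The truth table records each variant's causal
  flag and planted failure.
- **Disease model**: logistic on carrier indicators of causal genes
  (dosage-linear behind a flag), intercept tuned by bisection to the
  configured case fraction; causal-gene variant frequencies are rescaled
  to a target control carrier frequency (default 5%) and kept panmictic
  so the planted effect size is realized reliably.
- **Networks and sets**: stochastic-block-model PPI (8 modules of 6,
  within-module weights 0.9–1.0 at p = 0.95, background weights 0.3–0.7
  at p = 0.02); module 0 holds the causal genes.  Distances are all-pairs
  shortest paths under edge length −log(weight), sentinel 50 for
  disconnected pairs.  GMT collections contain one planted term per
  module plus random filler terms; known-panel lists include part of the
  planted module.
- **EHR**: per-phecode logistic prevalence with a carrier odds ratio on
  designated genes; diagnoses are emitted as ICD-9/10 codes from the toy
  map.

What passing tests show — and do not.  The generator produces independent
sites (no LD beyond none), clean annotations, exactly two populations,
and carrier-based effects; calibration and recovery results therefore
demonstrate the statistical machinery, not robustness to LD structure,
annotation error, fine-scale admixture or sequencing artifacts.  Problem
sizes in the test suite (cohorts of ~500, 120–800 genes, 20 end-to-end
replicates, 10⁴ permutations, 10³–10⁴ resampling iterations) were chosen
as the smallest at which the targeted properties are statistically
identifiable — e.g. λ_GC bands need ≥ ~1500 pooled genes.

## Known limitations

- The SKAT-O combination treats per-rho dependence as Gaussian even when
  per-rho marginals come from the bootstrap tail fit; at very small MAC
  and very small p, calibration relies on the shifted-chi-square
  extrapolation (validated against permutation in the bulk).
- Wald-based Firth p-values are conservative at MAC near the entry
  filter; the penalized-likelihood-ratio alternative tightens this but is
  not the default.
- The NHC realization here is parameter-compatible but not byte-level
  faithful to any external clustering software.
- Phecode exclusion-range semantics use one interval per phecode; real
  phecode maps occasionally carry multiple ranges.
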