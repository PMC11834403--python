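# Methods

This note documents the statistical models behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices a user may want to override.

## The estimation problem

Monthly amplicon relative abundances are compositional draws from a
community whose members may be conditionally dependent (interacting). The
package models the *latent log-abundance* vector at each time point as

    y_t = baseline + seasonal(t) + drift(t) + ε_t,   ε_t ~ N(0, Σ)

and treats the sparse support of Θ = Σ⁻¹ as the interaction network:
Θ_ij ≠ 0 means ASVs i and j covary *given all other taxa and measured
covariates*, which screens out the abundant indirect associations that
plain correlation networks report. The chain CLR → GAM residualization →
nonparanormal → graphical lasso is an estimator of that support from
count data with seasonal confounding and non-Gaussian margins.

## Synthetic data

`generate_community` draws the model above directly:

- **Calendar**: samples on the first of each month (default 177 months
  from 2003-09), with a configurable fraction of months dropped at random
  (default 0.31, matching a roughly one-third miss rate over a 15-year
  monthly campaign). Date arithmetic is in real days, so the 30.4-day
  month-lag conversion is exercised nontrivially.
- **Seasonality**: a fraction of ASVs (default 0.5) get an annual
  sinusoid of amplitude `seasonal_amplitude` (default 1.0 log units) with
  random phase; long-term drift is a per-ASV Gaussian random walk
  (default step SD 0.05/month).
- **Interactions**: `n_planted_edges` random pairs (degree-capped at 3 so
  a unit-diagonal precision with off-diagonals of magnitude
  `partial_corr_strength` = 0.4 stays positive definite; 30% of edges get
  a negative sign). If the constructed matrix is not positive definite it
  is diagonally inflated and renormalized with a warning — realized
  partial correlations are then weaker than requested.
- **Counts**: multinomial with `library_size` trials (default 1e5) over
  the softmax of the latent vector. This induces exactly the closure
  artifacts the CLR is meant to remove. Overdispersion beyond multinomial
  (PCR/copy-number noise) is *not* modeled; the noise model is a
  config-level stand-in, so passing recovery tests bound performance
  under multinomial noise only, not under real amplicon overdispersion.
- **Taxonomy**: eight-rank PR2-style lineages assigned so that every
  database-matching rule is reachable: parasitism edges get a Syndiniales
  Group I/II/III parasite (no genus), symbiosis edges alternate
  Acantharea-Clade-F / polycystine hosts and MAST-3 clades, remaining
  edges and filler ASVs get unique genus-resolved lineages.
- **Determinism**: one master seed; each stage (structure, latents,
  counts, month drops, environment, database, taxonomy) derives its own
  child stream, so artifacts are bit-reproducible and individual stages
  can be replayed.

The environment generator emits 24 variables by default (8 seasonal
sinusoids, 12 white-noise, 4 "drivers" that are linear in designated
ASVs' latent series), with a missing-cell mask for the imputation stage.
The toy interaction database covers `db_coverage` of the planted edges at
the granularity their taxonomy requires, plus decoy records about absent
taxa; an edge whose endpoints both lack genus resolution cannot be
expressed under any matching rule and is skipped with a warning.

## Preprocessing

- **Prevalence filter**: keep ASVs non-zero in at least 20% of samples
  (inclusive bound), applied per depth.
- **CLR**: zeros are removed before the log-ratio by a pseudocount
  (`c = 1` for count tables, half the smallest nonzero value for
  relative-abundance tables, nothing if the table has no zeros) or by
  multiplicative replacement. The choice is reported in results because
  zero handling is the one genuinely arbitrary step of the transform.
- **Environment**: iterative chained imputation with an
  extremely-randomized-trees regressor (seeded; linear and mean
  imputers available), then z-scoring (ddof = 1) to mean 0, variance 1.

## Temporal analyses

Month lags are `|Δdays| / 30.4`, binned round-half-up to integers;
zero-day pairs are excluded (no temporal information). Mantel uses
Spearman correlation of the strictly-upper-triangular distances with
joint row/column permutation of the second matrix, one-sided (positive
association) by default, and either the add-one estimator
`p = (1 + #extreme)/(1 + B)` or exact enumeration of all n! permutations
for n ≤ 8. The add-one estimator is mildly conservative-to-neutral; its
type-I rate at B = 199 measures ≈ 0.05 over 500 null replicates. ANOSIM
ranks distances with average ties; R = (r̄_between − r̄_within)/(M/2).
PCA for the PC1-distance regression runs on the standardized table
(correlation PCA); PC1's sign is fixed by its largest-magnitude loading,
which distances ignore anyway.

## RDA and forward selection

`rda_fit` projects the column-centered community matrix on the centered
predictors via QR; R² is the trace ratio, adjusted by the Ezekiel factor
(n−1)/(n−m−1); axes come from the SVD of the fitted matrix (numerically
stabler than eigen-decomposing ŶᵀŶ). Forward selection adds the
candidate maximizing adjusted R², subject to a double stop:

1. the candidate model must improve on the current model *and* stay
   within the global (all-candidate) model's adjusted R² — the scope
   guard that limits stepwise optimism;
2. the added term's residual-permutation p-value (permuting reduced-model
   residuals, pseudo-F statistic, add-one estimator, default 999
   permutations), Bonferroni-multiplied by the number of candidates still
   in play, must be below α = 0.05.

Because adjusted R² exactly cancels chance gains in expectation, the
scope guard is a near-tie whenever the selected subset already captures
*all* explainable variance; in that regime selection may stop one term
early. This is a property of the scope-guarded procedure itself, not of
this implementation, and is immaterial when, as in real environmental
tables, the non-selected candidates retain some signal. Both the
permutation scheme and the Bonferroni denominator are exposed as
arguments.

## Detrending and Gaussianization

Each feature is residualized against a Gaussian-identity additive model:
a penalized cyclic cubic spline of day-of-year (k = 6 basis functions,
period one year) plus an unpenalized low-df cubic B-spline of elapsed
time (k = 5) for the long-term trend. The penalty weight defaults to a
fixed α = 1.0; per-feature selection by generalized cross-validation is
available (`gcv=True`) but costs an order of magnitude more time and
changes residuals negligibly on monthly series of this length. With
these defaults a pure annual sinusoid loses > 95% of its variance while
white noise retains > 90% — the two contracts that matter for network
input. Features whose spline fit fails fall back to harmonic regression
(annual sin/cos + linear trend) with a warning. Identification requires
≥ 12 samples spanning more than a year.

Residuals are then mapped through the truncated-ECDF nonparanormal
transform: average-tie ranks r/n, clamped to [δ, 1−δ] with
δ = 1/(4 n^¼ √(π ln n)), normal quantile, rescaled to unit sample
variance. The transform depends on data only through ranks, hence is
exactly invariant under strictly increasing marginal maps. The pipeline
order CLR → detrend → nonparanormal is enforced by type: the transform
accepts only a `DetrendedMatrix`.

## Graphical lasso and StARS

The solver is block coordinate descent on the covariance side: cycling
over columns, each update solves the lasso subproblem
min ½βᵀW₁₁β − s₁₂ᵀβ + λ‖β‖₁ by coordinate descent, with the diagonal
unpenalized (W_ii = S_ii at optimum). Convergence is declared when the
maximum column change falls below `tol × mean |off-diagonal S|`; the KKT
residual (|S−W| ≤ λ off-support, S−W = −λ·sign(Θ) on support) is checked
after every solve and the solver raises rather than return an unconverged
estimate. At λ = 0 the solution is S⁻¹ directly. λ paths are log-spaced
over 30 values from λ_max = max|S_ij| down to 0.1·λ_max.

StARS draws 50 subsamples of size b = ⌊10√n⌋ (capped at n−1) without
replacement, solves the full path on each with warm starts, and computes
the mean edge instability D(λ) = mean over pairs of 2θ̂(1−θ̂). D is
monotonized by running maximum from the sparse end, and the *smallest* λ
(densest graph) with monotonized D ≤ β = 0.05 is refit on the full data.
If no λ qualifies, the λ_max (empty or near-empty) graph is returned with
a warning. β, b, the path bounds and the subsample count are all
arguments; the defaults follow standard stability-selection practice.
Under the default β the selected graph deliberately errs toward
over-selection: on synthetic truth it recovers essentially all planted
edges at the cost of a comparable number of extras (precision ≈ 0.5 at
F1 ≈ 0.6), consistent with how stability selection trades precision for
recall at this threshold.

## Annotation

Each ASV contributes candidate match keys: Syndiniales group,
radiolarian host class (Acantharea Clade F or polycystines), MAST clade —
in that precedence — and genus (case-insensitive, separators normalized,
species/strain suffixes ignored). An edge is supported if any database
record matches some key pair under a rule, testing both orderings; the
special rules are reported in preference to genus–genus when several
match. One record may support many ASV-level edges (multi-copy marker
genes make this the norm for Syndiniales); record multiplicity from
duplicate collapsing is retained. Database types symbiosis and
"unresolved" are reported as a single `other_symbioses` category;
`reported_types` is a set because a pair may match records of different
types. Recall summaries count, per category: database records, records
whose both keys are realizable by at least one network-input ASV, and
supported edges found. Unsupported edges are ranked by |Spearman| of the
partners' CLR series, with |SCC| ≥ 0.64 flagged strong (inclusive bound);
constant series make SCC undefined and are excluded with a flag.

## Problem sizes

The test and verification battery runs at desk scale by design: networks
of 30 features over ~150 months (10 replicate seeds), 50 StARS
subsamples × 30 λ values, 500 null replicates × 199 permutations for
test calibration, and exhaustive permutation enumeration on ≤ 6-sample
fixtures. These sizes were chosen so that every stochastic claim is
averaged over enough replicates to be stable while the whole battery
remains a single short run; the estimators themselves have no
size-specific code paths.

## Known limitations

- The multinomial count model understates real amplicon noise
  (overdispersion, copy-number variation); recovery rates on synthetic
  data are therefore an upper bound on real-data performance.
- The GAM family is Gaussian-identity on CLR values; a count-family
  variant applied upstream of CLR is out of scope.
- Undirected conditional dependence cannot distinguish interaction
  direction or type; typing comes only from the database match.
- The scope-guard near-tie described above can truncate forward
  selection by one term when the signal saturates.
- Cross-depth merging intersects edge sets by feature id; it assumes the
  two networks' ASV id spaces are harmonized upstream.
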