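# Methods

## The measurement and the model

Tandem treatment of the same DNA with bisulfite (BS) and oxidative
bisulfite (oxBS), each hybridised to a methylation array, yields per CpG
and sample a quadruple of methylated and total fluorescence intensities
`(S_BS, R_BS, S_oxBS, R_oxBS)`. The BS arm converts unmethylated
cytosine only, so its methylated fraction reads 5mC + 5hmC; the oxBS arm
first oxidises 5hmC so that only 5mC survives conversion. Writing
`(π1, π2, π3)` for the unmethylated, 5mC and 5hmC proportions at a CpG —
a point on the 2-simplex — the arm-level methylated fractions
`β_k = S_k / R_k` have means

    μ_BS = π2 + π3,        μ_ox = π2.

`oxyhmc` models the two observed fractions as independent beta variates
with those means and precision `θ_k = c · R_k` (default `c = 1`): the
total intensity acts as an effective pseudo-count weight, so brighter
probes constrain the fit more strongly. The constrained maximum
likelihood estimate of `(π1, π2, π3)` under `π_j ≥ 0`, `Σ π_j = 1` is
the package's core estimator (`PairedBisulfiteModel.fit()`); the
classical naive subtraction `π3 = max(0, β_BS − β_oxBS)` is retained as
the comparison method (`naive_subtract`, `PairedBisulfiteModel.naive()`).

The exact form of the intensity-noise density for this assay is not
identifiable from array summaries; the beta likelihood with
intensity-scaled precision is this package's own choice, validated by
recovery properties on simulated data (below), and `c` is exposed should
a different coupling between intensity and precision be preferred.

### Optimisation

The joint log-likelihood is *separable* in `(μ_BS, μ_ox)` and each term
is strictly concave (the score `∂ℓ/∂μ = θ[logit β − (ψ(θμ) − ψ(θ(1−μ)))]`
is strictly decreasing in `μ`), while the constraint region
`0 ≤ μ_ox ≤ μ_BS ≤ 1` is convex. The constrained global optimum is
therefore computed exactly rather than by a generic multi-start
quasi-Newton search: each arm's unique unconstrained maximiser is found
by an 80-step bisection of the monotone score; if the maximisers violate
`μ_ox ≤ μ_BS` (oxBS fraction above BS fraction, i.e. no 5hmC evidence)
the optimum lies on the boundary face `μ_ox = μ_BS` and one further
bisection of the pooled score finishes the solve, returning `π3 = 0`
with the boundary flag set. All solves are vectorised; a cohort of
1.2 million CpG–sample entries fits in roughly ten seconds on one core.
Tests confirm the solver matches (to 1e-4) an exhaustive simplex grid
search at step 0.001 and reduces to naive subtraction as `R → 10^6`.

Numerical guards: observed fractions are clamped to `[1e-6, 1−1e-6]`
before the likelihood (infinite densities at 0/1), solves stay `1e-12`
inside the simplex faces, and `π3 ≤ 1e-8` raises the boundary flag.
Invalid entries (missing, `R ≤ 0`, `S > R`) become missing values with
`converged = False` in the cohort fit instead of aborting it.

## Downstream analyses

**High-5hmC delineation.** Probes are ranked by cohort-mean 5hmC and
the top fraction (default 1%) forms the high set. The ~9% threshold
reported for such sets is an *output* of the rule, never a parameter.
Ties at the threshold break toward lexicographically smaller probe ids
so selection is deterministic. Recurrence counts, per-CpG Spearman
correlation between 5hmC and 5mC (average ranks under ties; undefined
under zero variance), per-stratum percentile tables (linear
interpolation between closest ranks) with pairwise Kruskal–Wallis tests
at a Bonferroni-adjusted alpha (`0.05/6 = 8.3E-03` for four strata), TSS
metaplots over half-open 50 bp bins spanning ±2 kb, and TSS-distance
category proportions complete the landscape module.

**Enrichment.** The background is always the post-filter retained probe
set, never the genome. A probe at 1-based position `p` overlaps a BED
interval `(start, end)` iff `start < p ≤ end`; overlap is boolean (a
probe overlapping several intervals counts once). Association between
"high" and "in feature" is tested with the Cochran–Mantel–Haenszel
statistic stratified by the four CpG-density strata — CpG density
strongly shapes 5hmC levels, so the pooled 2×2 is confounded —
with `OR_MH = Σ a_k d_k/n_k / Σ b_k c_k/n_k`, Robins–Breslow–Greenland
confidence intervals and the 1-df chi-square with no continuity
correction. 0.5 is added to all cells for the OR/CI only when a cell is
zero (flagged in output). Fisher's exact test (sample odds ratio; the
estimator is recorded in output metadata) serves the unstratified case,
and multi-set collections receive Benjamini–Hochberg q-values, sorted
by q then descending OR. Expression tertile association uses a 3×2
chi-square of tertile × contains-high-5hmC.

**Clustering.** Samples are clustered on their high-set 5hmC profiles
with a recursively partitioned beta mixture: at each node a
two-component mixture of independent per-CpG beta densities is fitted
by EM, and a split is accepted iff it lowers the BIC
(`−2ℓ + p·ln n`, `p = 2J` for one leaf vs `4J + 1` for two) and both
children hold at least `min_leaf` (default 3) samples. This is a
hard-assignment simplification of the classical recursively partitioned
mixture model; the validation surface is cluster recovery on synthetic
data, not equality with the original algorithm. Leaves are numbered by
increasing mean, so leaf 1 is always the low-5hmC cluster, and the two
root-level sides define the low/high dichotomy that the survival model
uses regardless of deeper splits.

Two numerical points matter here. First, the weighted per-CpG beta
M-step uses damped Newton iterations with objective backtracking,
warm-started from the previous EM iteration's parameters — the M-step
can then never decrease the mixture likelihood, and monotonicity is
asserted at every EM iteration. Second, product-beta mixtures have
degenerate optima in which a one-sample component drives its
concentrations to the parameter bound and dominates the likelihood;
root splits therefore try three deterministic starts (k-means on the
logit values, a mean-split, and a seeded balanced partition) and prefer
the best fit whose hard split satisfies the leaf-size constraint.
Values are clamped to `[1e-6, 1−1e-6]` before all beta likelihoods.

**Survival.** Cox proportional-hazards regression (Efron ties, via
lifelines) of overall survival on the low-cluster indicator adjusted
for age at diagnosis and sex; clinically excluded samples (e.g. a
methylator-phenotype outlier) are dropped first. Convergence and
separation warnings are surfaced on the result object, never silently
discarded. The median split of the per-sample total-5hmC index (mean
π3 over all retained probes; values at the median go to "low") supports
the contrast between pattern-based and total-level survival analyses.

## The synthetic cohort generator

The generator (`oxyhmc.simulate`) emulates the structure of a
glioblastoma tandem-array cohort; its defaults are the package's study
conditions and are not tuned per analysis:

| parameter | default | rationale |
|---|---|---|
| stratum fractions (island/shore/shelf/ocean) | 0.31/0.23/0.10/0.36 | approximate 450K-array composition |
| stratum Dirichlet means (π1, π2, π3) | island (0.862, 0.130, 0.008); shore (0.637, 0.350, 0.013); shelf (0.429, 0.550, 0.021); ocean (0.345, 0.630, 0.025) | 5mC and 5hmC lowest in islands/shores, highest in shelf/ocean; global 5hmC ≈ 1% with the majority of CpGs near zero |
| Dirichlet concentration | 2.5 | corner-heavy, bimodal per-stratum beta distributions as methylation arrays show |
| 5hmC sample scales (low/high cluster) | 0.3 / 1.0 | global 5hmC loss in the low cluster without commensurate 5mC change |
| totals `R_k` | Gamma(shape 10, mean 2000), per arm | heavy right tail of fluorescence totals (`lognormal` switchable in config) |
| arm fraction noise | Beta, precision 200 | array-scale beta-value noise |
| target feature OR | 3 (base rate 0.15) | enhancer-scale enrichment |
| survival | exponential, baseline median 14.5 months, HR 3 for the low cluster, 20% uniform censoring | glioblastoma-scale survival with a strong cluster effect |
| ages | N(65, 10), +9 years in the low cluster | older low-5hmC cluster |

Sample-level 5hmC scaling multiplies π3 and renormalises the triple,
preserving the π1:π2 ratio. Region sets are built as ±250 bp windows
around member probes, with member counts drawn *exactly* (not Bernoulli)
at the rates implied by the target odds ratio within the high and
non-high groups, independently of stratum — so the within-stratum odds
ratio equals the target and the realised value is tight around it.
Probe coordinates keep ≥600 bp inter-probe gaps so a window never
captures a neighbouring probe. Censoring times are uniform on `(0, τ]`
with `τ` solved numerically so the expected censored fraction matches
the configured rate. All randomness descends from one seed through
`SeedSequence` spawning; identical configs give bit-identical cohorts.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: two-channel probe chemistry and
probe-type (I/II) differences, batch and normalisation artefacts,
cellular heterogeneity, spatially correlated methylation along the
genome, and real enhancer/TFBS geometry (intervals are probe-anchored
windows). Recovery results certify the estimator and the downstream
machinery under the stated noise model, not the assay itself.

## Problem sizes used in validation

Validation runs use desk-scale problem sizes chosen to preserve the
study's *ratios*: estimator recovery on 500 CpGs × 30 samples (RMSE of
π3 below 0.03 at depth 2000 / precision 200); full-array delineation on
387,617 synthetic means (top 1% → 3,876); enrichment power with one
planted OR=3 set among 49 nulls over 20,000 CpGs × 50 replicates;
clustering on 40,000 CpGs so the 1,000–4,000 stability sizes all stay
within the top 10% of probes, mirroring a 1% high set drawn from a full
array (at a few thousand probes total, sizes 3,000–4,000 would be
dominated by near-zero-5hmC background and no longer represent the
analysis being emulated); survival coverage with n = 200 over 100–200
replicates.

## Known limitations

- The beta/intensity-precision likelihood is a modelling choice; the
  estimator is near-unbiased for the arm means regardless, but the
  per-entry log-likelihood scale (and hence the diagnostics) depends
  on `c`.
- No empirical-Bayes shrinkage across CpGs and no confidence intervals
  on the per-entry proportions.
- The recursive partitioner intentionally simplifies the classical
  fuzzy-weighted recursion to hard BIC-gated binary splits.
- Proportional hazards are assumed, not tested, beyond lifelines'
  surfaced warnings.
- Fisher tests report the sample odds ratio, not the conditional MLE;
  output metadata says so.
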