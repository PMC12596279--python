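# Methods

`islesar` implements the statistical pipeline for species–area analysis of
microbial communities on discrete habitat islands — the motivating system
being bromeliad phytotelmata, whose water column, detritus and invertebrate
hosts form three nested "compartments" sampled by amplicon sequencing.
This note records the models, the synthetic data the package is validated
against, the numerical choices, and the limits of what the tests show.

## The species–area model

Richness is modelled as the power law `S = c·A^z`, fitted as
`log S = log c + z·log A` by ordinary least squares.  Natural logarithms are
used throughout; the exponent z is base-invariant, intercepts are on the
natural-log scale.  Island size A is detritus mass (mg) for detrital
communities and standing water volume (ml) for aquatic and host-associated
communities.  Zero-richness islands are rejected rather than offset: a
silent `+1` changes z, and the caller should decide whether to drop or
offset.

Uncertainty in z comes from a case bootstrap: (S, A) pairs are resampled
jointly with replacement to the original n, and the log–log fit repeated B
times (default B = 1000).  Resampling pairs jointly — rather than pairing
richness and area independently — keeps the bootstrap distribution centred
on the observed slope, which is what makes downstream slope *comparisons*
meaningful; independent pairing would destroy the very association being
compared.  Slope distributions are compared with Welch's t-test
(Welch–Satterthwaite degrees of freedom computed explicitly) and the
comparison family is Benjamini–Hochberg corrected.  The BH family for the
fits themselves is all SARs fitted in one run; comparisons are corrected
within their own family.

Degenerate bootstrap resamples (zero size variance) are redrawn and
counted; with n = 32 this is vanishingly rare.

## Diversity and evenness

Observed ASV richness is the alpha metric.  Extrapolating estimators
(Chao, ACE) are deliberately excluded: the package targets surveys whose
accumulation curves saturate, and the rarefaction module exists to verify
that premise, not to correct for its failure.  Rarefaction uses the
analytic hypergeometric interpolation
`E[S(m)] = S_obs − Σ_i C(N−N_i, m)/C(N, m)`, evaluated with log-gamma;
no extrapolation beyond the observed depth is offered.

Evenness is the Hill number of order one, `exp(−Σ p_i ln p_i)`, an
effective species number in `[1, S]`.  Regressing q = 1 on log island size
diagnoses "disproportionate effects" — evenness rather than richness
responding to area.  Replicate samples are pooled by count summation before
any per-island statistic.

## Environmental models

Stepwise multiple regression minimises `AIC = n·ln(RSS/n) + 2k` with k
counting the intercept and the Gaussian constant dropped consistently —
the convention of standard linear-model stepwise selection, chosen so
selections are comparable across implementations.  The default direction
(`both`) starts from the full model.  Candidate panels: physical island
descriptors (diameter, height, leaf complexity, invertebrate number, log
invertebrate weight) plus detritus chemistry (%C, %N) or water chemistry
(dissolved oxygen, pH, temperature, nitrate) depending on the island-size
panel.  Incomplete cases are dropped with a logged count; missing
covariates are never imputed, so per-model degrees of freedom may differ.

Relative importance uses the LMG decomposition: a predictor's share is its
incremental R² averaged over all orderings, computed through the subset
formulation with weights `|S|!·(k−|S|−1)!/k!` and a cached R² per subset.
Shares sum to the full-model R² exactly; k ≤ 10 is enforced because the
enumeration is exponential.

## Turnover and dispersion

Bray–Curtis dissimilarities are computed on raw counts.  The Mantel test
correlates upper triangles by Spearman rank correlation with a one-sided
(greater) permutation p — the directional hypothesis being that
compositional difference grows with size difference.  Size distances
default to `|log A_i − log A_j|` for consistency with the log-space SAR; a
raw-scale option is retained.

The composition-vs-size regression bootstraps **islands**, not pairwise
entries: entries sharing an island are dependent, and resampling islands
and rebuilding both triangles propagates that dependence into the slope
distribution (pair-level resampling is demonstrably overconfident; a test
pins the ordering of the two standard errors).  Resampled self-pairs are
excluded as degenerate (0, 0) points.

Beta dispersion embeds the dissimilarity matrix by principal coordinates
(Gower double-centring, full eigendecomposition).  Distance to the group
centroid uses the standard negative-eigenvalue correction: squared
distances along negative-eigenvalue axes are subtracted and the result
clamped at zero before the square root.  Bray–Curtis matrices are
routinely non-Euclidean, so the eigenvalue diagnostics (count and smallest
eigenvalue) are reported.

## Null models

**RC-Bray.**  For each sample pair, 999 null pairs (configurable) are
assembled: each null sample receives its observed richness of species,
drawn without replacement with probability proportional to occurrence
frequency across the metacommunity, then its observed read total, as one
read per drawn species plus a multinomial over metacommunity relative
abundances.  The observed Bray–Curtis is ranked within the null
(ties counted half) and rescaled to [−1, 1].  Values above +0.95 indicate
deterministic divergence, below −0.95 homogenisation, the middle band
drift.  The metacommunity is the full table passed in; callers scope the
table (by locus/compartment) before the call.

**NODF.**  For every row pair and column pair with strictly decreasing
fill, the paired term is `100·overlap/fill_smaller`; equal fills contribute
zero; the statistic averages over all pairs.  Identical row or column
patterns contribute identically, so the implementation groups patterns and
weights by multiplicity — exact, and O(P²) in distinct patterns rather
than O(C²) in columns.  It matches both a brute-force pairwise
implementation and `vegan::nestednodf` (sorted convention) in the tests.

**Margin-preserving randomization.**  For general matrices, a null matrix
is built from a Patefield random contingency table with the target
margins, reduced to binarity with 2×2 moves that lower the excess
`Σ max(0, m−1)`, then mixed by checkerboard swaps (a symmetric-proposal
random walk whose stationary law is uniform on the margin class).  For
matrices with three rows — the compartment × ASV case — the margin class
factorises over column types, and the package draws **exactly uniformly**:
the distribution of the two free type counts is a product of multinomial
coefficients, enumerated once, after which each draw is a categorical
sample plus a column permutation.  Uniformity is verified against
exhaustive enumeration on a 3×3 class.  A curveball variant is provided
for cross-checking.

Significance is oecosimu-style: `z = (obs − mean_null)/sd_null` and a
two-sided permutation p with add-one counts, capped at 1.

## The synthetic generator

The generator produces the study conditions the pipeline is validated
under: 32 islands whose detrital size spans exactly a 250-fold range and
water a 90-fold range (log-uniform with pinned extremes, so log A is
uniform and SAR leverage balanced); a lognormal regional pool of 4000 ASVs
(meanlog 0, sdlog 1.5); per-island replicate samples (2 detritus, 2 water,
1 invertebrate); compartment-specific SAR exponents z = 0.12 (detritus),
0.10 (water), 0 (hosts) with intercepts 3.95/3.25/2.96 on the natural-log
scale; lognormal richness noise σ = 0.5, which puts the median fitted R²
near 0.12 — the weak-signal regime the method must operate in.

Richness, not read depth, carries the SAR: the target
`S* = round(exp(log c + z log A + ε))` is realised exactly by giving every
community member one read and distributing the remaining depth
(gamma-Poisson around 10⁴) multinomially.  This emulates saturated
sampling — accumulation curves plateau by construction — and makes
"observed richness equals community richness" an exact invariant rather
than an approximation.

Two structural features matter for the null-model analyses:

* **Island affinities.**  Each island modulates pool abundances by a
  lognormal affinity (sd 2.0) shared across its compartments, so islands
  share common taxa but differ strongly in composition — the
  high-turnover regime in which RC-Bray values approach +1 between
  islands.
* **Host-in-environment nestedness.**  Invertebrate hosts acquire 95% of
  their community from their own island's detrital community intersected
  with the admissible host fraction of the pool (`host_filter_strength`,
  default 0.3 of the pool, uniformly chosen); the 5% remainder
  (host specialists) comes from the admissible fraction at large — kept
  small because at synthetic community sizes a large specialist share
  drowns the nestedness signal that real, much larger tables retain.  This
  is what produces a compartment matrix whose NODF exceeds
  margin-preserving nulls (z ≈ 3–6 at strength 0.2).  Restricting hosts
  to a pool subset *without* local-environment sourcing does not produce
  a detectable nestedness signal — with both margins fixed, nearly all of
  a 3-row matrix's NODF is frozen, and the only informative degrees of
  freedom are the host presences outside columns occupied by all three
  compartments.  Consequently, nestedness strength is governed by the
  local-sourcing mechanism and is *not* monotone in the admissible
  fraction itself; the tests pin the containment contract and the
  standardized nestedness rather than raw-NODF monotonicity.

Reagent contamination is modelled with dedicated contaminant ASVs
(disjoint from the ecological pool): each is planted in ≥ 75% of the
negative controls with ~50 reads and sprinkled into 30% of true samples
at ~5 reads — strong prevalence contrast, the signature the screening
method relies on.

All randomness flows from a single `numpy` generator seeded by
`SyntheticConfig.seed`; there is no global state.

What the generator does **not** emulate: taxonomy, sequence errors and
chimeras, compositional (relative-abundance) artefacts of library size,
batch effects across extraction runs, cross-talk between samples, and
environmental covariates that jointly drive richness and composition
(only pH is coupled to island size, with slope −0.15 per log ml).
Passing tests therefore show the *statistical machinery* is correct and
calibrated under the stated model, not that any particular field result
is reproduced.

## QC conventions

Decontamination scores each ASV with the one-sided p of a 2×2
presence/absence test ("more prevalent in negatives"): chi-square without
continuity correction, replaced by Fisher's exact test whenever an
expected cell is below 5.  The p-value form makes the score exactly
testable against a hypergeometric enumeration oracle.  Threshold 0.5
(flag when score < 0.5) is the method's conventional default and is
exposed in config.  Decontamination precedes culling.

Culling drops samples at or below the read threshold, then ASVs, and
iterates that ordered pass to a fixed point.  A single pass is not
idempotent — removing low-read ASVs can push a surviving sample below the
sample threshold — and a fixed point makes both post-conditions
simultaneously true.  Defaults follow the fungal thresholds (300 reads per
sample, 3 per ASV); the bacterial pair (2901, 4) is a config change.
Thresholds are always explicit; `suggest_break_threshold` only *suggests*
a cut at the largest gap in log-transformed totals within the lower half
of the distribution (geometric midpoint of the gap; ties break toward the
smallest threshold; a gap must exceed twice the median gap to be reported
with confidence).

## Pipeline determinism and problem sizes

A master seed spawns per-stage child generators keyed by CRC-32 of the
stage name, so disabling one stage never shifts another's stream; reruns
are byte-identical (no timestamps are written, floats are formatted with
`%.10g`).  Default analysis sizes: B = 1000 bootstrap replicates, 9999
Mantel permutations (999 in the pipeline default config), 999 RC-Bray
reps per pair (RC-Bray is quadratic in samples, so the pipeline caps the
islands entering the RC stage, configurable), 1000 nestedness nulls.
Validation simulations use scaled-down pools (400–1000 ASVs) and depths
(~2000 reads) where the quantity under test does not depend on them;
richness-based quantities are unaffected by pool size in the
deep-sampling regime.

## Known limitations

* The prevalence score assumes negatives and true samples are exchangeable
  batches; batch-aware or frequency-based (DNA concentration)
  decontamination is out of scope.
* RC-Bray's null fixes per-sample read totals at their observed values;
  normalising to a common depth is a different null and is not offered.
* Stepwise AIC is greedy; it matches exhaustive best-AIC search on ~90% of
  random instances (spot-checked), and disagreements are logged, not
  treated as errors.
* The exact-uniform null sampler applies only to 3-row (or 3-column)
  matrices; other shapes use the MCMC path, whose uniformity is checked
  empirically on a small enumerable class.
* Beta dispersion compares group spreads without the permutation test of
  group-dispersion homogeneity; the package regresses dispersion on island
  size instead, which is the quantity of interest here.
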