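# Methods

This note documents the statistical machinery, the generative model behind
the synthetic data, the numerical choices, and the limits of what the
passing tests demonstrate.

## Diversity statistics

**Hill numbers.** For a frequency vector with relative abundances `p_i`,
the order-q Hill number is `(Σ p_i^q)^(1/(1−q))`; the q = 1 case is
computed through an explicit `exp(−Σ p_i ln p_i)` branch (zero counts
contribute nothing). The statistic is the effective number of equally
common categories: it is invariant to relabelling, zero-padding and count
replication, and non-increasing in q. q = 1 is the default order; any
nonnegative order is accepted (q = 0 richness, q = 2 inverse Simpson). The
Gini coefficient — population (1/n²) normalisation, computed over the
vector as supplied, so explicitly passed zero categories count as empty
share-holders — is available as an alternative concentration measure.

**Equal-depth BID bootstrap.** An area's between-individual diversity is
the mean Hill number over bootstrap replicates that each draw `n_draw`
events (default 1000) *without replacement* from the area's pooled
streams; CIs are 2.5/97.5 percentiles of the replicate values. Drawing
without replacement within a replicate reflects the protocol of drawing a
fixed number of unique streams rather than resampling; replicates differ
only through the seeded RNG. Areas with fewer than `n_draw` events raise
an explicit under-depth error rather than silently rarefying — equal depth
is the contract that makes areas comparable. The category sequence is
canonicalised (sorted) before drawing, so the estimate is invariant to
stream-row order at fixed seed. Whether the draw should additionally
enforce song uniqueness is ambiguous; events are drawn as-is, and because
the upstream sampler already reduces each user to distinct songs, the
pooled area table contains one event per (user, song) anyway.

**Song embedding.** Songs are embedded from within-user co-listening: a
binary user×song incidence matrix gives a symmetric co-occurrence count
matrix (diagonal zeroed), which is transformed by positive pointwise
mutual information and factorised by truncated SVD of rank d; rows are
scaled by the square root of the singular values. PPMI before SVD is the
standard treatment for count co-occurrence — raw counts would let the
popularity margins dominate the factorisation. Component signs are fixed
deterministically (largest-magnitude loading positive) and the iterative
solver is seeded; songs with no co-occurrence receive zero vectors and a
`disconnected` flag. All downstream scores are invariant to global
orthogonal rotations of the embedding, so the specific basis (and whether
a production system scales rows by singular values) is immaterial; tests
verify this invariance directly.

**GS-score and WID.** The user centroid μ⃗ is by default the *unweighted*
mean over the distinct songs a user listened to, while the score itself
weights each song's cosine against μ⃗ by its play count; a flag switches
to a play-weighted centroid. Both readings of "average of all songs
listened" are coherent; the unweighted centroid makes μ⃗ a property of the
user's repertoire rather than of their play volume. WID is fixed as
`100·clip(1 − GS, 0, 1)`: linear, endpoint-exact (GS = 1 ⟹ WID = 0), and
independent of the dataset, unlike a min–max normalisation that would
break comparability across runs. WID is computed from organic
(user-chosen) streams only; algorithmically recommended events are
excluded. Users whose songs average to a zero centroid, or with no
embedded song, raise an explicit undefined-score error.

**Dispersion.** Per replicate, `n_pairs` distinct user pairs are sampled
uniformly among all unordered pairs, and the *population* variance (1/N)
of their cosine similarities is returned; the estimate is the bootstrap
mean with percentile CI. Note the statistic is not monotone in
heterogeneity: a single tight cluster and a population spread evenly over
many clusters both give low variance (all-similar and all-dissimilar
pairs respectively); it peaks when users split into a few distinct camps.
In the synthetic data, large areas sit in the many-cluster regime, so
dispersion can fall with size even when both diversity layers rise; the
controlled fixture tests (variance grows with cluster separation) pin
down the behaviour the statistic is meant to capture.

## Inclusion filters

Events shorter than 30 s are dropped (and mobile-network events, when
flagged). Users need at least 100 events and at most 10 distinct
locations; bounds are inclusive exactly as worded ("less than 100", "more
than 10"). The home area is the area of the user's modal event location,
ties broken by lexicographically smallest area id (a deterministic rule;
the convention is otherwise unspecified). Areas keep at least 200 unique
users. Finally 100 random *unique songs* are drawn per user — "unique
streams" is read as unique songs, since BID's frequency logic pools song
identities; an `unique="events"` mode implements the other reading. Users
with fewer than the requested distinct songs keep everything, with the
shortfall recorded in the filter report. The documented pipeline order is
streams → users → home → areas → sampling.

## The synthetic generator

The generator emulates the data structure the analysis assumes, not the
music industry. Defaults were calibrated once, at design time, so that the
latent dials act cleanly on the measured statistics; they are held fixed
across the test suite.

- **Areas.** `n_areas` sizes log-spaced over `area_size_range`. All
  structural size effects act per decade of log₁₀ population, measured
  from the centre of the range.
- **Catalog.** Genre means are unit vectors drawn isotropically; song
  vectors scatter around their genre mean with displacement norm
  `song_cluster_sd` (0.8), and user centroids with `user_centroid_sd`
  (0.6). Scatter magnitudes are expressed as displacement norms (the
  per-coordinate deviation is scaled by 1/√d) so geometry does not depend
  on the embedding dimension. Global popularity is Zipf with exponent 1.
- **Choice model.** A user streams a negative-binomial number of events
  (mean 150, shape 50 — the distribution of per-user volumes is not
  otherwise constrained); each event picks a song by softmax over the
  utility `cos(centroid, song) + 0.05·ln(popularity)` at temperature equal
  to the user's latent breadth. Tempering the popularity term together
  with the taste term is deliberate: if popularity entered untempered,
  high-breadth populations would collapse onto the global hits and the
  breadth dial would *reduce* pooled diversity. As breadth → 0 the user
  plays only the argmax-utility song; as breadth grows the choice tends to
  uniform. A small fraction of events carries sub-30 s durations or
  off-home locations, and ~1% of users are heavy travellers, purely to
  exercise the filters.
- **Breadth (WID side).** `breadth = breadth_base + (breadth_size_slope +
  direct_effect_wid)·z + amplitude·exp(−(age−peak)²/2σ²) + gender term +
  Σ (covariate → wid coefficients)·z-scored covariates + noise`, clipped
  positive. The age bump (peak 28, width 10) produces the inverted-U
  trajectory; `breadth_size_slope` and `direct_effect_wid` enter
  identically — the former is the descriptive-scaling dial, the latter the
  labelled dial for causal recovery runs.
- **Genre mixtures (BID side).** Each area's genre mixture is Dirichlet
  with log concentration `taste_concentration_by_size(z) +
  direct_effect_bid·z + Σ (covariate → bid coefficients)·z-scores +
  noise`; higher concentration = more even mixture = higher pooled
  diversity, so a positive slope is the BID–size dial. An area's mixture
  is the average of four Dirichlet draws, reflecting that an analysis area
  pools several commune-scale communities; this tempers draw noise
  without changing how evenness scales with concentration.
- **Demographics and confounding.** Area-level income, education,
  immigration, venues, international social connectedness (built from a
  synthetic gravity model of friendship counts and summed/normalised/
  log-transformed exactly as the SCI index prescribes) and algorithmic
  share are log-linear or logit-linear in z with Gaussian shocks sized so
  that unweighted group SMDs land in the 0.3–0.7 range typical of real
  urban–rural contrasts. Income, education, immigration and algorithmic
  share are then re-drawn per *user* around the area aggregate
  (commune-like granularity — the real covariates are far finer than the
  analysis areas); venues and social connectedness stay area-level. Each
  user's algorithmic share drives their own stream flags. Every DAG arrow
  strength lives in `confounding_coefficients`; zeroing them severs the
  corresponding path exactly.
- **Determinism.** All draws flow from named, order-independent
  substreams of the root seed (catalog, genre means, areas, SCI, users,
  streams), so generating one table never perturbs another. Identical
  config + seed reproduces every table bit-identically.

What the generator does **not** emulate: popularity dynamics over time,
within-window temporal structure, mobility beyond location noise,
platform-specific biases, or real geographic boundaries. Passing
parameter-recovery tests therefore show that the estimators recover known
structure of this generative family — not that the real data satisfy the
model's assumptions.

## Scaling statistics

Correlations are two-tailed Pearson (or Spearman) with Fisher-z 95% CIs
by default (a bootstrap CI is available; which CI the original analyses
used is not specified) and Holm adjustment applied jointly across a named
family of tests. Smooth trends are penalised cubic B-splines (df 8) with
the penalty weight selected by generalised cross-validation; with too few
points, or a degenerate (noise-free) response, the fit falls back to a
straight line with a warning. Group contrasts use classical one-way
ANOVA, Tukey-HSD-adjusted pairwise p-values, and pooled-SD Cohen's d. Age
trajectories bootstrap the mean WID of 100 distinct users per 5-year bin;
thin bins are dropped with a warning. Population terciles are formed by
ranking areas, remainder areas going to the lower groups; per tercile,
each outcome is regressed by OLS on all demographic covariates and the
adjusted R² reported.

## Causal stage

The assumed DAG has population size as exposure, a diversity outcome, and
the demographic covariates in between: size → each area-composition
covariate → outcome, gender → outcome, and age/gender → algorithmic
share. Its testable content is the pairwise basis {u ⟂ v | parents(v)}
over non-adjacent pairs in topological order, tested by linear partial
correlations with Holm adjustment.

Adjustment sets target the **direct** effect as drawn, via the
single-door criterion: Z is valid when it contains no descendant of the
outcome and d-separates exposure and outcome in the graph with the direct
edge removed; minimal sets are found by subset enumeration (the graphs are
small). For the default DAG this yields the full eight-covariate set —
adjusting algorithmic share opens the collider paths through it, which is
why age and gender are also required.

Treatment is the area-size tercile. Generalised propensity scores come
from an unpenalised multinomial logit on a quadratic polynomial expansion
of the standardised adjustment covariates; the expansion matters because
the treatment is a discretised continuous exposure, making the
group-membership posterior curved — a linear logit leaves substantial
residual imbalance. Weights are the generalised overlap (matching-weight)
family `w_i ∝ [Σ_k 1/e_k(x_i)]⁻¹ / e_{Z_i}(x_i)`, normalised to mean one
within group; in the binary case this reduces exactly to the familiar
overlap weights (1−e for treated, e for controls), which is tested
algebraically. The precise multi-treatment generalisation used by any
particular software stack is not standardised; this one is documented and
tested. Propensities under 1e−8 are truncated with a warning. Balance is
reported as pairwise SMDs with unweighted pooled-SD denominators (so
before/after values share a scale) against the |SMD| < 0.1 convention.

Effects: the outcome is Z-scored on the pooled sample *before* weighting
(the alternative ordering is unspecified; pooled standardisation keeps the
scale interpretable), then weighted (adjusted) and unweighted (unadjusted)
least-squares models on treatment indicators give medium−small and
large−small contrasts, re-expressed from the small group's fitted mean as
the shared intercept. Uncertainty comes from bootstrapping the entire
procedure — resampling units, refitting propensities, recomputing
contrasts — with percentile CIs. For the BID outcome, which is constant
within an area, replicates resample whole areas (cluster bootstrap) so the
CI reflects area-level noise; for the user-level WID outcome, users are
resampled. The causal stage restricts to ages 18–65 and binary gender and
is complete-case, mirroring the upstream exclusions.

**Recovery target for an injected direct effect.** The generator's direct
effect is linear in log₁₀ population, while the estimator contrasts
discretised groups; the recovery test therefore compares the adjusted
contrast with `δ × (overlap-weighted mean log₁₀-population gap between
the groups)` — the direct effect the structural equation implies on the
contrast scale. Recovery is checked on the latent breadth outcome, where
the structural equation is linear; the stream→embedding→WID map is
deliberately nonlinear, so a tight percentage bound is only meaningful on
the structural scale (the measured-WID route is exercised by the
confounded-null and shape-recovery runs instead).

## Problem sizes and numerical choices

The confounded-null recovery run uses 96 areas sized 130–800 (~31k
users, ~5M generated events), matching the real analysis's area count —
three terciles of 32 areas — which is what makes overlap weighting and
balance attainable; the shape-recovery run uses 24 areas sized 250–1600
(~17k users) through the learned embedding. Bootstrap replicate counts in
tests (typically 200–500) are scaled-down but stable versions of the
1000-replicate default. The d-separation equivalence sweep is exhaustive
over every labelled DAG on up to 4 nodes (all non-adjacent pairs, all
conditioning subsets) plus 300 seeded random 5-node DAGs with all triples.
Tolerances: analytic identities at 1e−9 relative; stochastic recoveries at
bounds derived from ~3 standard errors of the quantity at the simulated
size. Tie-breaks and degenerate inputs (empty tables, single-category
areas, zero-norm centroids, under-depth areas, thin age bins) each have a
documented deterministic behaviour and a test.

## Known limitations

- Dispersion's non-monotonicity in heterogeneity (above) means its sign
  against population size is regime-dependent in synthetic data.
- The generalised overlap weights balance only approximately for three or
  more groups; balance is therefore *checked*, not assumed.
- Area-level covariates (venues, social connectedness) can never be
  balanced better than the number of areas allows; with few areas the
  balance criterion will fail for structural reasons.
- The linear partial-correlation independence tests detect only linear
  violations of the DAG.
- Plotting/rendering (maps, UMAP projections, density plots) is out of
  scope; all outputs are tabular.
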