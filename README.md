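# listendiv

Dual-layer measurement of cultural diversity in geolocated music-listening
data, with a fully parameterised synthetic generator standing in for
protected streaming records.

Large cities consume more diverse culture. Is that because they aggregate
people from varied backgrounds (demographic mixing), or because urban life
broadens each individual's taste (cultural breadth)? Answering requires
measuring diversity at two levels at once, from individual listening
events:

- **Between-individual diversity (BID).** Pool an area's streams, draw an
  equal number of events per area, and compute the Hill number

  `qD = (Σᵢ pᵢ^q)^(1/(1−q))`, with the q→1 limit `¹D = exp(−Σᵢ pᵢ ln pᵢ)`,

  the *effective number of equally common songs*. A BID of 900 means the
  area's listening is as diverse as 900 equally played songs. Estimates are
  bootstrap means over equal-depth draws (default 1000 events, 1000
  replicates) with 2.5/97.5-percentile CIs, so differently sized areas are
  compared fairly. A Gini coefficient is provided as an alternative
  concentration metric.

- **Within-individual diversity (WID).** Songs are embedded by truncated
  SVD of a positive-PMI co-listening matrix. Each user's
  Generalist–Specialist score is the play-count-weighted mean cosine
  similarity between their listened songs and their centroid μ⃗:

  `GS(μ) = (1/Σ wₛ) Σₛ wₛ · cos(s⃗, μ⃗)`,   `WID = 100·clip(1 − GS, 0, 1)`.

  Specialists score near WID 0, maximal explorers near 100. Area-level
  *dispersion* — the population variance of cosine similarities between
  bootstrapped pairs of user vectors — captures how heterogeneous local
  tastes are.

Around these two statistics the package implements the full analysis
pipeline: the inclusion filters (≥30 s plays, ≥100 streams and ≤10
locations per user, modal-location home assignment, ≥200 users per area,
100 unique songs sampled per user), diversity–population-size correlations
with Holm correction and penalised-spline trend fits, country contrasts
(ANOVA, Tukey HSD, Cohen's d), bootstrapped 5-year-bin age trajectories,
per-size-quantile demographic regressions, and a causal stage: a DAG over
population size, demographics and diversity with implied-conditional-
independence testing, minimal adjustment sets, generalised overlap (ATO)
propensity weights across three population-size groups, standardised-mean-
difference balance checks, and bootstrapped intercept-matched effect
contrasts.

Because raw streaming data are protected, a synthetic generator produces
listening events with the structure the analysis assumes — log-spaced area
sizes, genre mixtures whose evenness grows with size, Zipf-skewed song
popularity, latent per-user taste centroids and breadth with an inverted-U
age profile, and demographics confounded with area size along the assumed
DAG. Every effect is a config dial, so each estimator has a
parameter-recovery test.

## Worked example

```python
import numpy as np
from listendiv import (
    SimulationConfig, LogLinear,
    generate_catalog, generate_population, generate_streams,
    run_filter_pipeline, bid_bootstrap, build_song_embedding, wid_scores,
)
from listendiv.scaling import correlation_family

config = SimulationConfig(
    seed=1, n_areas=24, area_size_range=(250, 1600),
    n_songs=2000, n_genres=12, embed_dim=32,
    breadth_size_slope=0.08,                          # size -> breadth effect
    taste_concentration_by_size=LogLinear(1.8, 2.0),  # size -> mixture evenness
)
catalog = generate_catalog(config)
population = generate_population(config)
streams = generate_streams(population, catalog, config)
sampled, home, report = run_filter_pipeline(streams, population.locations, seed=0)

rng = np.random.default_rng(0)
bid = {area: bid_bootstrap(sub, n_draw=1000, n_reps=500, seed=rng)
       for area, sub in sampled.groupby("home_area")}
embedding = build_song_embedding(sampled, d=32, seed=0)
wid = wid_scores(sampled, embedding)
```

This generates 2.65 M events for ~17 k retained users across 24 areas
(about two minutes on one CPU) and prints, per area,

```
A000: population=  250  BID= 679.0 [652.8, 702.8]  mean WID=36.4
A001: population=  271  BID= 662.7 [635.1, 690.4]  mean WID=40.1
A002: population=  294  BID= 716.5 [691.1, 744.5]  mean WID=51.2
```

i.e. the smallest area's pooled listening is as diverse as ~679 equally
common songs, with the bootstrap 95% CI in brackets. Correlating area
diversity with log₁₀ population (Holm-corrected across the family):

```
                 name     r  ci_low  ci_high  p_adjusted
bid~log10(population) 0.527   0.157    0.767       0.016
wid~log10(population) 0.466   0.077    0.732       0.022
```

Both layers of diversity rise significantly with population size — the
pattern the generator was dialled to produce, recovered end-to-end through
filtering, embedding and equal-depth bootstrapping.

The same stages are available as a CLI
(`listendiv generate|filter|embed|bid|wid|dispersion|scaling|causal|run`),
with stage outputs handed over as CSV/Parquet files plus a JSON manifest,
so any stage can be re-run in isolation:

```bash
listendiv run --out runs/demo --config examples/demo.yaml
```

## Layout

```
src/listendiv/
  config.py     simulation config, named RNG substreams
  synthetic.py  generator: catalog, areas/users/demographics, streams, SCI
  filtering.py  inclusion rules and equal-depth sampling
  diversity.py  Hill numbers, Gini, equal-depth BID bootstrap
  embedding.py  PPMI-SVD song embedding, GS/WID, dispersion
  scaling.py    correlations, GAM trends, ANOVA/Tukey/Cohen's d, age bins
  causal.py     DAG tests, adjustment sets, ATO weights, SMD, effects
  pipeline.py   staged orchestration with manifest
  cli.py        click command-line interface
docs/methods.md   model and design notes
```
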