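# claderich

Clade-based species-richness analysis on time-calibrated phylogenies.

Why do some clades contain millions of species and others a handful? Two
classic explanations compete: old clades have had more **time** to
accumulate species (the clade-age hypothesis), or fast clades accumulate
species more **quickly** (the diversification-rate hypothesis).
`claderich` implements a sampling-based test of these hypotheses that
avoids the bias of named taxonomic ranks: sample clades *at random* from an
ultrametric tree, measure each clade's age, richness and net
diversification rate, and ask which variable explains richness across
clades — with regressions that respect the phylogenetic non-independence
of the sampled clades.

It is aimed at macroevolutionary biologists who have a time-calibrated
species-level tree (e.g. a published supertree) and want a reproducible,
scriptable version of this analysis, plus a synthetic data generator so
the whole pipeline can be exercised and validated without any external
data.

## The statistics at the core

**Net diversification** r = λ − μ (species/Myr) is estimated from a
clade's richness *n* and age *t* by the method-of-moments estimators under
an assumed relative extinction fraction ε = μ/λ ∈ {0, 0.5, 0.9}:

- stem basis: r̂ = ln(n(1−ε) + ε) / t_stem, reducing to ln(n)/t at ε = 0;
- crown basis:
  r̂ = (1/t)·{ ln[ ½n(1−ε²) + 2ε + ½(1−ε)·√(n(nε² − 8ε + 2nε + n)) ] − ln 2 },
  reducing to ln(n/2)/t at ε = 0 and exactly 0 at n = 2 for every ε.

**Regression** uses log₁₀(richness) as the response and untransformed age
(Myr) and rate (species/Myr) as predictors. PGLS assumes Brownian-motion
errors: Cov(i,j) = shared root-to-tip path length of the clade
representatives, shrunk by Pagel's λ (a multiplier on the off-diagonals,
profiled by maximum likelihood over [0, 1]; δ = κ = 1). Four models are
fitted per clade set: richness~age, richness~rate, rate~age and
richness~age+rate. The design is replicated (default: 50 clades × 10
replicates) and summarized by mean r², mean p and the percentage of
replicates with p < 0.05.

Exclusion filters mirror common supertree artifacts: clades with estimated
rates > 1 species/Myr, clades in polytomies, clades with zero crown age
(zero-length branches), and the younger clade of every nested pair.

## Worked example

Simulate a 50-clade "age-driven" forest (shared speciation rates, widely
varying clade ages) and run the replicated analysis:

```bash
claderich simulate --preset age_driven --seed 4 --out scratch/forest.nwk
# wrote scratch/forest.nwk (2066 tips, 50 clades)

claderich run --tree scratch/forest.nwk --m 40 --reps 3 --seed 2 --out scratch/run1
```

which prints

```
     relationship  mean_r2       mean_p  pct_significant  n_clades_total  n_replicates  mean_lambda
     richness~age 0.701103 6.069747e-10       100.000000             114             3     0.000000
    richness~rate 0.246758 1.882341e-02       100.000000             114             3     0.467617
         rate~age 0.062411 4.207644e-01        33.333333             114             3     0.000000
richness~age+rate 0.817931 1.140435e-12       100.000000             114             3     0.391211
```

Read this as: clade age alone explains ~70% of the variance in
log-richness (significant in 3/3 replicates), diversification rate alone
~25%, and age is not a predictor of rate — exactly the signature expected
when rates are shared and ages vary, i.e. a time-driven richness pattern.
`n_clades_total` counts retained clades summed over replicates (clades
lost to nesting or filters are not replaced, so totals vary).
`mean_lambda` is the average ML Pagel's λ. Under the `rate_driven` preset
the ranking reverses (see `scenario_contrast`).

The same pipeline runs on any ultrametric Newick tree with branch lengths
in Myr. The library API mirrors the CLI:

```python
import claderich as cr

tree = cr.parse_newick(open("my_tree.nwk").read())
cfg = cr.RunConfig(m_clades=50, n_replicates=10, epsilon=0.5, seed=1)
per_replicate, summaries = cr.run_replicates(tree, cfg)
```

Other entry points: `claderich subsample` re-runs the analysis on a
randomly thinned tree (incomplete-sampling robustness check) and
`claderich merge-richness` substitutes described species counts for
in-tree tip counts with genus→family→order rank escalation.

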