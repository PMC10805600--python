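# Methods

## The analysis pipeline

The unit of analysis is a *clade set*: `m` internal nodes (default 50)
drawn uniformly without replacement from the candidate list of a rooted
ultrametric tree. Candidates are all internal, non-root nodes with at
least two descendant tips — tips are excluded because a one-species clade
has no crown age, and the root because sampling the entire tree is
degenerate. Sampling can be stratified by subtree (e.g. a fixed number of
clades per domain of life) with exact per-stratum counts.

Each replicate then proceeds:

1. **Nesting resolution.** If one sampled clade contains another, the
   clade with the smaller crown age is excluded, transitively, until the
   ancestor relation restricted to retained clades is empty. Ties are
   broken by excluding the larger node id (any deterministic rule works;
   determinism keeps runs reproducible). Excluded clades are *not*
   replaced, so replicate sizes vary.
2. **Measurement.** Crown age = node depth (max path length to a
   descendant tip); stem age = crown age of the parent; richness = number
   of descendant tips in the tree.
3. **Rate estimation.** The crown (default) or stem method-of-moments
   estimator at a fixed relative extinction ε (default 0.5). ε is an
   assumption, never estimated.
4. **Filters.** Drop clades with r̂ > 1 species/Myr, clades in
   polytomies, and clades with zero crown age. One reason is logged per
   exclusion, first match in the order zero-crown → polytomy → rate.
   All filters can be disabled for sensitivity runs.
5. **Regression.** Four models — log₁₀(richness)~age, log₁₀(richness)~rate,
   rate~age, log₁₀(richness)~age+rate — by PGLS (default) or OLS on the
   reduced one-tip-per-clade tree.

Summaries over replicates report mean r² (adjusted r² for the multiple
model), mean p (slope p for simple models, model-F p for the multiple
model), and the percentage of replicates with p < 0.05.

## Estimators

Stem: r̂ = ln(n(1−ε)+ε)/t. Crown:
r̂ = (1/t)[ln(½n(1−ε²) + 2ε + ½(1−ε)√(n(nε²−8ε+2nε+n))) − ln 2].
The discriminant is grouped exactly as written; the n² and nε² terms grow
together so no catastrophic cancellation occurs even at n = 10⁹ (tested).
Natural logs throughout the estimators; log₁₀ appears only in the
regression response. A post-processing helper converts a mean
branch-specific speciation rate and clade-wide turnover ε from a
branch-heterogeneous speciation model into a net diversification rate,
(1−ε)·λ̄ᵢ; the Bayesian inference that produces those summaries is out of
scope — users supply them.

## PGLS details

The covariance entry for representatives i, j is their shared root-to-tip
path length; the representative of each clade is its lexicographically
smallest tip label (on an ultrametric tree every choice yields the same
pairwise path lengths; the tests assert this). Pagel's λ multiplies the
off-diagonal entries and is profiled by maximum likelihood with bounded
scalar search on [0, 1] (tolerance 1e-6), with both endpoints also
evaluated; δ and κ are fixed at 1. Fits use Cholesky whitening; slope
p-values are two-sided t with n−p−1 df.

**r² definition.** The coefficient of determination is computed on the
whitened scale against the GLS-fitted intercept-only null under the same
covariance — the conventional GLS r². Published comparative analyses are
not always explicit about this choice, so every fit also records an
OLS-style r² on the raw residuals (`r_squared_ols_scale`); if reproducing
an external table at tight tolerance fails, compare both.

PGLS requires ≥4 retained clades; replicates below that are skipped with
a warning and excluded from summary means.

## Synthetic clade forests

The generator emulates the statistical structure the analysis assumes:
many monophyletic clades of varying age with clade-specific rates inside
one ultrametric tree.

- Per clade: stem age ~ U(stem_age_range); crown age = stem age × U(0.6,
  0.95); speciation rate λ lognormal (`lambda_median`, `lambda_sdlog`);
  extinction μ = ε_true·λ. Each clade is grown forward in time from its
  two crown lineages and conditioned, by rejection, on both lineages
  surviving — the cheapest unbiased scheme at these sizes, and the one
  that makes tree depth equal the nominal crown age. A count-only variant
  of the same process supports recovery experiments with very large
  clades.
- Clades hang from a ladder backbone whose joins sit at fixed 10-Myr
  intervals above the deepest stem age; each clade's stem age is realized
  exactly by pairing it with a pendant sister tip. Backbone shape is
  irrelevant to the analyses (only path structure among representatives
  enters PGLS), so the simplest deterministic shape is used.
- The global seed expands to per-clade generators through spawn-keyed seed
  sequences, so clade simulations are order-independent and reproducible.
- Presets: `age_driven` (stem ages 5–100 Myr, λ median 0.05/Myr, sdlog
  0.05 — richness differences driven by time) and `rate_driven` (stem
  ages 20–30 Myr, λ median 0.06/Myr, sdlog 0.5 — driven by rate). Rates
  are lognormal because clade rates are strictly positive and dispersed
  multiplicatively.

Artifact injection conserves total tree depth: selected internal nodes are
collapsed into their parents (polytomies), selected cherries have their
pendant edges zeroed with the removed length donated to the cherry's stem
(zero crown ages), and a sampling fraction < 1 prunes tips uniformly at
random.

**What the generator does not emulate:** heritable within-clade rate
shifts, time-varying rates, fossil taxa, the strongly right-skewed age
distribution of candidate nodes in real supertrees (clade ages here are
uniform within a range), or taxonomically biased (non-random) missing
taxa. Passing tests therefore validate the pipeline's statistical
machinery and its behaviour under the stated generating conditions, not
the empirical claims one would make from any particular real tree.

## Recovery experiments and their design

- *Estimator error*: 200 Yule clades at λ = 0.2/Myr with crown ages
  U(5, 50) Myr; the crown estimator at ε = 0 recovers the rate with
  median relative error under 15%.
- *True-vs-estimated correlation*: a correlation is only defined when true
  rates vary, so this leg draws λ lognormal (median 0.2, sdlog 0.4) with
  ages U(10, 25) Myr — dispersion typical of across-clade comparisons,
  with ages bounded so clades stay at desk scale (λ·t ≤ ~8). Pearson
  r between true and estimated rates exceeds 0.8.
- *Pagel's λ recovery* uses 50-clade forests: with 50 representatives the
  likelihood is informative enough that Brownian-motion responses give
  median λ̂ > 0.8 and iid responses give median λ̂ < 0.1. This matches the
  50-clade replicate design; with many fewer representatives λ is weakly
  identified on a ladder-dominated covariance and its estimate is noisy —
  a property of λ estimation generally, not of this implementation.
- *Scenario contrast* simulates 10 independent forests per preset and
  regresses over each forest's marked clades: under `age_driven`,
  r²(richness~age) > r²(richness~rate) in ≥8/10 sets; under
  `rate_driven` the inequality reverses in ≥8/10.

## Numerical and interface choices

- Ultrametricity tolerance 1e-6 Myr (supertrees carry rounding noise);
  the error names the worst-offending tip pair. Zero-branch tolerance
  1e-9 Myr.
- Newick output uses 12 significant digits: on trees hundreds of Myr deep,
  9 digits would let root-to-tip sums drift past the ultrametricity
  tolerance after a write/parse round trip.
- Node ids are assigned by deterministic post-order traversal at parse
  time, so a given Newick string always yields the same ids and seeded
  clade sampling is reproducible.
- The polytomy flag covers any multifurcation inside the clade's subtree
  by default ("a clade in a polytomy" is ambiguous between its crown node
  and any internal node); `polytomy_scope="crown"` restricts it to the
  crown node.
- Paired r² comparisons fall back to p = 1 with a `degenerate` flag when
  the differences have (numerically) zero variance, where the t statistic
  is undefined.
- No multiple-testing correction is applied across replicates: the design
  reports raw per-replicate p-values against a fixed 0.05 threshold.

## Known limitations

- The method-of-moments estimators assume the assumed ε; systematic error
  from a wrong ε shifts rate levels (though rankings are fairly robust —
  hence the standard ε grid {0, 0.5, 0.9}).
- Richness in the tree understates true richness under incomplete
  sampling; the subsampling experiment and described-richness merge probe
  robustness but do not correct the estimates.
- PGLS assumes Brownian-motion errors on the reduced tree; other error
  structures (OU, measurement error) are not implemented.
- The candidate list treats every internal node as a potential clade;
  taxonomy-aware (named-rank) selection is deliberately unsupported except
  by passing an explicit node-id list.
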