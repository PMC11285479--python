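# Methods

`skewnet` estimates how concentrated social control is within female social
groups and relates it to reproductive skew.  This note records the models
and procedures, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Units and eligibility

The unit of analysis is the social group-year.  Only adult females enter
any computation: only adults reproduce, and female–female control is the
question.  Individuals trapped five or fewer times in a year are treated as
transients and excluded everywhere (`trap_threshold = 5`, read strictly as
"more than five"; the threshold is configurable).  Network and skew metrics
require N ≥ 3 females — reaching centrality degenerates on a dyad — and the
skew computation additionally needs at least one weaned offspring in the
group.  Observation records are restricted to the active season (Apr 15 –
Sep 7 by default, configurable (month, day) bounds).

## Group detection

Association between two females is the simple-ratio index over calendar-day
sampling periods: SRI = x / (x + y_A + y_B + y_AB), with "together" meaning
at least one shared location on the same day.  A dyad with no observation
days is *undefined* (NaN), distinct from an observed 0.

Groups are found by minimising the two-level map equation on the annual SRI
matrix, separately within each colony (colonies act as containers of
groups).  Codelength uses strength-proportional visit rates — the exact
stationary distribution of an undirected weighted walk, also valid
per-component on disconnected graphs.  The optimiser is deterministic given
a seed: node-move sweeps in seeded random order (ties to the lowest module
index), alternating with whole-module merges, until no move lowers the
codelength; a final guard compares against the single-module partition so
the reported codelength never exceeds it.  Zero-strength individuals become
singleton groups.  Only the flat two-level code is implemented — the groups
of interest have no sub-structure worth a hierarchical code — and no
teleportation is used.  Exhaustive partition search at small N (tested up
to 6 nodes, where all set partitions are enumerable) agrees with the greedy
optimum on planted-block matrices; greedy suboptimality on adversarial
graphs remains possible in principle.  Because any map-equation
implementation involves such optimiser choices, group assignments can
differ from those produced by other Infomap implementations on the same
data; all downstream metrics are conditional on the detected partition.

## Hierarchy metrics

The agonistic network counts directed acts i → j between group members
within the season.  Reachability is computed on the **binarised** graph:
any observed aggression creates a directed edge.  This is the default
because reach centrality is defined in terms of which individuals can be
reached at all, not how often; a weighted variant (widest-path bottleneck
capacity on max-normalised weights) exists behind a flag for sensitivity
analyses but is never used by the pipeline.  GRC = Σ(C_R^max − C_R(i))/(N−1).
An all-zero network yields GRC 0 — egalitarian by absence of evidence — and
is logged as low-information rather than dropped.

Dyadic dominance is decided by strict majority of directed acts (no Elo or
David's scores).  Landau's h applies only to complete tournaments; h′
averages h over random completions (unknown dyads: uniform direction; tied
dyads: fair coin), 10 000 replicates by default, giving a Monte-Carlo
standard error below 0.005 for typical group sizes.  One seeded generator
per call fills free dyads in fixed row-major order, so h′ is
bit-reproducible.  Simple random fill is used rather than an
improved-randomisation scheme; with no ties/unknowns h′ collapses to h
exactly.

## Skew

M = N·Σ(s_i/S − p_i)² − N·(1 − Σp_i²)/S with p_i the exposure shares.  The
correction term is the exact multinomial expectation (from
Var(s_i/S) = p_i(1−p_i)/S under random allocation of S offspring); the test
suite validates it against a 10⁵-draw Monte-Carlo oracle at several (N, S)
configurations with a 3-standard-error gate.  Exposure defaults to equal
(1.0 per female-year) — no finer exposure measure is assumed by default —
and is configurable via the `exposure` column.  Zero-offspring females are
included: non-breeders are the phenomenon, not missing data.

## Inference

Response and predictors are log-transformed (predictors) and standardised
(all) over the analysis set.  Zero GRC values would break the log, so when
zeros are present an offset of half the smallest positive value of that
column is added inside the log (applied column-wide for consistency;
configurable).  Constant columns raise an error rather than silently
producing NaNs.

The model ladder mirrors the scientific comparison of interest: full
(GRC + h′ + size), GRC + size, h′ + size, size only, all with **crossed**
colony and year random intercepts (implemented as variance components over
level indicators inside a single all-encompassing group).  REML fits supply
the reported coefficients with Wald z tests; parallel ML refits supply the
likelihood for AICc = AIC + 2k(k+1)/(n−k−1), where k counts fixed effects,
variance components and the residual.  REML-for-estimates /
ML-for-comparison is standard practice; Satterthwaite degrees of freedom
are not implemented — at the target sample sizes (dozens of group-years)
Wald z is anticonservative by a modest, known amount, which the
operating-characteristic tests quantify directly.  A variance component
estimated below 1% of the residual variance triggers a singular-fit warning
but not an error.

Marginal R² = var(Xβ̂)/(var(Xβ̂) + Σσ²_random + σ²_resid); conditional R²
adds the random variances to the numerator.  Semi-partial (part) R² of a
predictor is marginal R²(full) − marginal R²(reduced); its 95% CI comes
from a parametric bootstrap (default 100 iterations: simulate the response
from the fitted full model including random-effect draws, refit everything,
recompute), with failed refits skipped, counted and warned about past 10%.
VIFs come from the fixed-effects design matrix; exact collinearity is
reported capped at 10⁶ rather than infinite.

## Synthetic data

The generator emulates the *structure* of colony field data: an
individual-year registry with transients, males and yearlings (filter
fodder), daily co-presence placing group members at a shared home location
(within-group SRI ≫ between-group), directed agonistic acts, and
pedigree-style offspring counts.  Per group, females hold latent ranks
1..N and a despotism parameter δ ≥ 0 shapes aggression twice over:
initiation propensity exp(−δ·(rank−1)) and a logistic direction bias
σ(δ·(rank_j − rank_i)).  At δ = 0 both directions of every dyad are equally
likely — cyclic, egalitarian structure; at large δ only the top female
initiates and all acts run down-hierarchy, approaching an out-star.  The
logistic direction bias (rather than a hard down-hierarchy indicator with
additive noise) is what makes δ = 0 genuinely egalitarian; a hard indicator
would produce transitive, hierarchical networks at *every* δ.  Dyad counts
are Poisson at a rate calibrated to rare aggression (~1.5 acts per dyad per
season), which naturally yields the tied and unknown relationships that h′
exists to handle.

Reproduction is Dirichlet-multinomial: concentration weights
∝ exp(−κ·δ·(rank−1)), total concentration N·exp(α₀ + u_colony + u_year)
with Gaussian colony/year intercepts on the log-concentration scale.  κ
couples skew to despotism (κ = 0 is the null world for type-I-error
checks).  Group sizes come from a negative binomial truncated to the
observed 3–11 range, matched to a mean near 4.7; truncation caps the
spread near 1.9, slightly tighter than the field spread.  Litter size
defaults to 1.5 weaned pups per female, folding non-breeders into the mean.

What the generator does **not** emulate: individual persistence across
years, survival/dispersal demography, male behaviour, kin structure within
groups, spatial burrow geometry, or observation-effort heterogeneity.
Passing tests therefore certify the statistical machinery — filters,
metrics, the skew correction, detection of planted effects at realistic
noise — not robustness to those field complications.

Two important consequences of the realistic sparsity: (i) even δ = 0 groups
show mean GRC around 0.2, not 0, because unobserved dyads create reach
asymmetries in small sparse digraphs — the despotism ladder test asserts
monotone separation (≈0.2 → >0.6), not absolute anchors; (ii) a latent
coupling κ has no closed-form mapping to a standardised regression
coefficient, so power and CI-coverage studies of the inference stage use a
separate row-level simulator that plants coefficients directly on the
standardised scale (GRC effect 0.6, crossed random s.d. 0.4/0.4, residual
s.d. 0.6, field-like predictor correlations 0.625 GRC–size and 0.202
h′–size).

## Problem sizes

Defaults were chosen so every routine check is quick on one core: the
despotism ladder uses 200 groups per δ level; the M-index null oracle 10⁵
multinomial draws; operating characteristics of the mixed model 100
replicates of 100 group-years each (power and size); CI coverage 100
replicates at 200 group-years; the end-to-end acceptance run is a 60
group-year world with 100 bootstrap iterations.

## Known limitations

* Greedy map-equation optimisation can in principle return a suboptimal
  partition; the guard only guarantees it beats the one-module code.
* Wald z p-values are slightly anticonservative at very small n; a
  Satterthwaite option was considered and deliberately left out.
* The weighted reach variant enumerates simple paths and is exponential in
  the worst case; it is meant for the small groups (N ≤ 11) this package
  targets.
* Equal exposure is an assumption, not a measurement; with real
  residency data the `exposure` column should carry time-in-group.
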