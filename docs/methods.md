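# Methods

## The question and the statistic

For a clade known only from fossils, a decline in speciation rate
before its extinction should leave a signature in its phylogeny: the
number of splitting events accumulated along any root-to-tip lineage
(the *node count*, `y_i`) should grow sub-linearly in the lineage's
duration (*time elapsed*, `t_i`, the root-to-tip distance in Myr).
`dinodiv` formalises this as a comparison of three nested regressions of
node count on time, fitted as Bayesian Poisson generalized linear mixed
models and compared by DIC.

Node-count convention: the root is counted and the tip is not, so the
minimum node count is 1 — a tree's root is itself one cladogenetic
event, which keeps the intercept treatments coherent at `t = 0` (an
`include_tip` flag provides the both-endpoints alternative).
Multifurcating nodes count once each: node count measures cladogenetic
events passed, regardless of how well resolved they are.

## The model

For tips i = 1..n of one dated tree:

    y_i | l_i  ~  Poisson(exp(l_i))
    l_i        =  x_i' beta + o_i + u_i + e_i
    u          ~  N(0, sigma2_a * A)
    e_i        ~  N(0, sigma2_e)

`A` is the phylogenetic variance–covariance matrix:
`A[i,j]` = the path length shared by the two tips' root-to-tip paths
(root-to-MRCA distance), `A[i,i]` = the tip's root-to-tip distance.  It
is symmetric PSD by construction.  The default is raw Myr units with an
optional unit-depth scaling (`scale=True` divides by the maximum
root-to-tip depth); for *fitting* the choice is immaterial because a
scalar rescaling of `A` is absorbed exactly into the `sigma2_a`
posterior, but reported `sigma2_a` values change meaning accordingly.

Fixed-effect forms (the three speciation hypotheses):

- null: `x_i = (1, t_i)` — constant rate;
- asymptote: `x_i = (1, sqrt(t_i))` — slowdown levelling off;
- downturn: `x_i = (1, t_i, t_i^2)` — continual decline.

Intercept treatments: *estimated* (free `beta0`), or fixed on the
latent (log-link) scale as an offset `o_i` of 0 or 1.  Fixing on the
latent scale means `E[y] = 1` (`e^0`) or `e` (`e^1`) at `t = 0`; the
response-scale alternative ("expected count exactly 1") corresponds to
`fixed_zero` and is what that mode should be read as.  Since the model
is log-link Poisson, "the intercept" only exists on the latent scale,
which is why the offsets live there.

## Priors

- Fixed effects: independent `N(0, 1e10)` — effectively flat.
- Phylogenetic variance: parameter-expanded. The effect is written
  `u = alpha * eta` with `eta ~ N(0, sigma2_eta * A)`,
  `alpha ~ N(0, 25^2)` and an inverse-gamma base
  `sigma2_eta ~ IG(nu/2, nu V/2)` with `V = 1, nu = 1`; the reported
  variance is `sigma2_a = alpha^2 * sigma2_eta`.  With `nu = 1` this
  induces a heavy-tailed half-Cauchy-type prior on the phylogenetic SD
  (scale 25) — weakly informative, and much better behaved near 0 than
  a bare inverse-gamma.
- Residual ("units") variance: `IG(nu/2, nu V/2)` with
  `V = 1, nu = 0.002` — the conventional near-flat default for
  overdispersion variances in this model family.

All prior constants are exposed through `PriorSpec`.

## The sampler

A Metropolis-within-Gibbs scheme over (latents `l`, fixed effects
`beta`, base effect `eta`, expansion scalar `alpha`, variances):

1. **Latents** `l_i`: single-site random-walk Metropolis, fully
   vectorised (given `beta, u, sigma2`, the sites are conditionally
   independent).  Per-site step sizes adapt toward 0.44 acceptance in
   batches of 50 during burn-in only and are frozen afterwards, so the
   retained phase is a fixed Markov kernel satisfying detailed balance.
2. **(beta, eta)** jointly: exact Gaussian Gibbs.  `A = Q L Q'` is
   eigendecomposed once per fit; in the eigenbasis the random-effect
   precision block is diagonal, so the joint draw reduces to a p×p
   Schur-complement solve (p ≤ 3) plus an O(n) diagonal draw — O(n^2)
   per iteration instead of the O(n^3) of a naive joint update.
   Eigenvalues below 1e-8 (relative) are floored there: consensus trees
   with zero-length shared branches can make `A` numerically singular.
   A smallest eigenvalue below -1e-8 (relative) is an error naming the
   eigenvalue.
3. **alpha**: scalar Gaussian Gibbs (it is a regression coefficient of
   `eta` in the latent residual).
4. **Variances**: conjugate inverse-gamma Gibbs draws.

Chain schedule defaults follow the published operating point: 5×10^5
iterations, thinning 10^3, burn-in 5×10^4, retaining 450 samples.  At
that schedule a ~100-tip downturn-model fit reaches mean ESS well above
the 200 quality bar (the pipeline logs a warning whenever a fit's mean
ESS falls below 200).  Replicated experiments (parameter recovery,
selection power) use a reduced schedule — 50 000 iterations, thinning
25, burn-in 5 000 — retaining 1 800 samples, four times more than the
full schedule, because DIC is a posterior mean whose differences are
judged against a 4-unit rule and its Monte-Carlo error at 450 retained
samples is of that same order.  The problem sizes and replicate counts
used by the validation experiments are recorded in
`dinodiv/validation.py`.

Divergence (a non-finite latent) aborts the fit with a diagnostic.
Seeds: every fit takes one integer seed; the pipeline derives per-fit
seeds (< 2^31) by hashing the tree identifier, model form and intercept
mode with the base seed, so partial re-runs reproduce original chains.

## DIC

The deviance is conditional on the latent predictors:
`D(l) = -2 sum_i log Poisson(y_i | exp(l_i))`, with
`pD = Dbar - Dhat` (posterior-mean deviance minus deviance at the
posterior-mean latents) and `DIC = Dbar + pD`.  DIC variants differ in
their "focus" level; the latent-conditional choice is the standard one
for non-Gaussian mixed models where the marginal likelihood is
intractable.  Absolute DIC values under other conventions differ, but
ΔDIC comparisons between the three forms — the only use made of DIC
here — remain meaningful.  Exact ties resolve toward the simpler model
(null < asymptote < downturn).

The selection rule: best model = smallest DIC; models within 4 units of
the best are indistinguishable.  If exactly one candidate remains, it
is unambiguous; if the candidates are {downturn, asymptote}, the
combined slowdown category is reported; and if the *null* is within 4
units of the best — even when not itself best — no model is favoured,
on the parsimony argument that a simplest model statistically tied with
the best leaves nothing demonstrated.  Both the 4-unit threshold and
the null-blocking rule are configurable.

## ESS

Effective sample size uses `N / (1 + 2 sum rho_k)` with the
autocorrelation sum taken over Geyer's initial positive sequence
(consecutive pairs `rho_{2m} + rho_{2m+1}` retained while positive),
clipped to [0, N].  A constant chain reports 0 with a warning.  On
AR(1) chains the estimator tracks the closed form
`N (1-rho)/(1+rho)` within tens of percent, and it agrees with
`arviz.ess` on stationary chains.

## Time-scaling

The dating protocol is deliberately the simple stochastic one used with
fossil cladograms: draw each taxon age uniformly in its stratigraphic
interval; place each internal node at its oldest descendant tip's age;
then raise ancestral nodes (postorder, children before parents, tips
never moved) until every branch lasts at least `mbl` (default 1 Myr).
The pass only increases node ages, preserves topology exactly, and is
idempotent on compliant trees.  Because the raises propagate, the root
can end up older than any taxon's maximum possible age;
`root_age_diagnostic` reports `root age - oldest max_age` with a
configurable flag threshold (default 10 Myr — roughly the scale of a
geological stage, beyond which the inflation deserves attention).
Repeating the draw (default 100 replicates, seeds `base + r`)
propagates age uncertainty into every downstream statistic.

Taxon ages are drawn independently per taxon; nothing links the draws
of ancestors and descendants.

## The synthetic-data generator

`simulate_bd_tree` grows a tree forward in time by a thinned Gillespie
algorithm: per-lineage speciation rate `lambda(t) = lambda0 e^{-k t}`
(`t` = time since the clade origin — the downturn hypothesis is a
clade-wide temporal decline, not a per-lineage ageing effect),
constant extinction rate `mu`.  Because `lambda` declines, the rate at
the last event time upper-bounds the true rate and thinning is exact.
Extinct lineages are kept as fossil tips at their extinction ages —
pruning to extant-only would change the node-count structure that the
method regresses on.  Total extinction before the end (or blowing
through the tip cap) returns a failure status the caller can retry.
Surviving lineages become tips at `end_age` (default 66 Ma, placing
trees in a Mesozoic-like window).

`generate_age_ranges` wraps each true tip age in an interval of
exponentially distributed width (independent across taxa, true age
uniform within the interval, younger bound floored at 0 Ma) — a simple
stand-in for ragged stratigraphic precision.

`simulate_glmm_counts` draws counts from exactly the model the sampler
assumes.  The phylogenetic effect is drawn on the *unit-depth-scaled*
covariance, so its `sigma2_a` parameter means "phylogenetic variance at
the deepest tip" — the scale on which values like 0.05–0.1 are
conventional.  On the raw Myr-scaled covariance the same numbers would
imply latent SDs of ~2 at the tips and swamp any fixed-effect signal.

What the generator does *not* emulate: stratigraphic sampling of fossil
occurrences (no fossilized-birth-death process), trait- or
clade-dependent rates, correlated age-range errors between related
taxa, and topological error in the input cladogram.  Passing tests
therefore show that the machinery recovers what it assumes, on trees
whose shape and size match the intended regime — not that the
biological conclusions from any particular fossil dataset are robust to
those unmodelled features.

## Validation experiments and problem sizes

`dinodiv.validation` fixes the study conditions used for
self-validation: a ~100-tip tree (speciation 0.11/Myr, extinction
0.02/Myr, 50 Myr) for recovery and ESS; ~120–200-tip trees (70 Myr)
with a downturn signature `beta = (0, 0.2, -0.002)` — a speciation peak
at 50 Myr — or a null signature `beta = (0, 0.1)`, with
`sigma2_a = sigma2_e = 0.05`, for selection power; 20 recovery
replicates and 10 replicates per selection regime at the reduced chain
schedule.  `scripts/acceptance.py` re-runs all of these from a single
seed and writes the measured quantities as JSON.

## Known limitations

- The sampler is single-chain; between-chain diagnostics (R-hat) are
  not computed.  ESS and the quality-bar warning are the mixing guards.
- DIC is a relative measure with a latent-conditional focus; its
  absolute values are not comparable across deviance conventions.
- The node-placement rule (oldest descendant) systematically
  underestimates divergence times; the mbl correction is a floor, not
  an estimate.  More sophisticated dating (cal3, tip-dating) is out of
  scope.
- Discrimination between the three forms degrades as phylogenetic
  variance grows: a Brownian-like effect on a non-ultrametric tree can
  partially mimic smooth temporal trends, which is precisely why
  ensembles of trees and the conservative 4-unit rule are used rather
  than single-fit verdicts.
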