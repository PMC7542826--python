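# Methods

## The model

Haploid chromosome number `n` evolves along a rooted, time-calibrated
phylogeny as a continuous-time Markov chain on a bounded integer state
space `n_min..n_max`. Three event types act:

| event      | move            | rate symbol | meaning                          |
|------------|-----------------|-------------|----------------------------------|
| fission    | `n -> n+1`      | λ_fis       | centromeric split / gain of one  |
| fusion     | `n -> n-1`      | λ_fus       | Robertsonian-type join / loss    |
| polyploidy | `n -> 2n`       | λ_pol       | whole-genome duplication         |
| demiploidy | `n -> ⌈1.5 n⌉`  | λ_dem       | unreduced-gamete route (default 0) |

"Fission" and "fusion" are shorthand for any ±1 change in haploid
number. A transition whose target would exceed `n_max` is simply
dropped (no probability mass is remapped to the boundary — mapping a
doubling to `n_max` would fabricate a near-doubling event). The
*simple* model sets λ_pol = 0; the *complex* model frees it, so the two
are nested and differ by one degree of freedom.

An optional trait-linked variant doubles the state space with a binary
character (e.g. sexual vs asexual reproduction): each trait state
carries its own (λ_fis, λ_fus, λ_pol) triple and the trait itself flips
at rates q01/q10. This is the construction used to ask whether
chromosome rates differ between reproductive modes.

**State-space bounds.** `n_min = 1` and `n_max = 2·(largest observed
count) + 1`, so a single polyploidy step from the largest observed
state stays inside the space while matrices stay small. Both bounds
are overridable.

**Likelihood.** Felsenstein pruning with per-node rescaling (log-scale
accumulation), uniform root prior by default (an observed-tip-frequency
prior is a switch). Tip observations may be a single count, a candidate
set (uniform probability over the candidates), or missing (all-ones).
Zero-length branches get the identity propagator exactly.

**Identifiability and units.** Multiplying all rates by `c` while
dividing all branch lengths by `c` leaves the likelihood unchanged, so
rates are estimated on trees rescaled to unit root depth and divided by
the root age in MY afterwards; all reported rates are per million
years. These are rate parameters of exponential waiting times, i.e.
expected events per lineage per MY.

## Branch propagators

`transition_probabilities` (the exported operator) computes
`P(t) = exp(Qt)` by scipy's scaling-and-squaring Padé `expm`; row sums
are accurate to better than 1e-10.

The iterative fitters evaluate the likelihood thousands of times, so
they use a reusable `Propagator` that spectrally decomposes `Q` once
and propagates each branch with two matrix-vector products, batched
across each tree level. `Q` is non-normal, and when fission and fusion
rates are strongly unequal its eigenbasis becomes catastrophically
ill-conditioned (condition numbers beyond 1e15 occur at a fission:fusion
ratio of ~3 with ~100 states). The decomposition is therefore accepted
only after three checks (eigenbasis condition estimate, reconstruction
error of `Q`, and row-sum error of `exp(Q)`), and otherwise the
propagator switches to a dyadic scheme: `exp(Q·2^-j)` is built once per
power — a 4-term Taylor series from precomputed `Q^2..Q^4` at tiny
norms, repeated squaring above — and a branch length acts through its
binary expansion truncated at `2^-32` (a relative branch-length error
of ~2e-10; all powers of one `Q` commute, so the order of application
is irrelevant). Sampling paths (ML and MCMC) use relaxed acceptance
thresholds (~1e-5 absolute propagator error) since posterior
exploration does not need the strict likelihood contract.

## Estimation protocol

Mirroring an analysis over a Bayesian posterior tree sample:

1. Each tree is rescaled to unit depth (scale factor = root age, MY).
2. Chromosome-count ambiguity is resolved by one uniform draw per
   (seed, tree) before the chain starts, so different trees explore
   different resolutions and reruns are reproducible.
3. Per tree, a Metropolis–Hastings chain runs over the unit-tree rates
   (default 1000 generations). Moves cycle through one sliding-window
   update per parameter (reflected at zero) and one joint multiplicative
   rescaling of all rates — the posterior is ridged along the total-rate
   direction, and the scale move (with its Jacobian-corrected Hastings
   ratio; exact zeros are fixed points) traverses that ridge directly.
   One move runs per generation, each window tuned toward 25–45%
   acceptance during burnin. The chain starts at the
   maximum-likelihood fit, which is why short chains suffice: burnin
   only has to forget the tuning transient, not find the mode.
4. The first 25% of each chain is discarded; 100 states are subsampled
   uniformly without replacement (seeded); each draw is divided by the
   tree's root age; the per-tree samples are pooled (100 trees × 100
   draws = 10 000 in the full protocol).

**Priors.** Independent exponentials on the unit-tree rates, mean 100
per rate (configurable per rate). On a unit-depth tree the plausible
rate range spans roughly 0.3–500 (per-MY rates of 0.003–0.5 across root
ages of 100–1000 MY), and an exponential with mean 100 is close to flat
across all of it while remaining proper. A much tighter prior would
visibly shrink high-rate clades — a unit-tree rate of ~120 is a normal
operating point, not a tail event.

**Model choice.** Simple vs complex is a 1-df likelihood-ratio test,
`Λ = 2(llC − llS)` clipped at zero, p from χ²₁. Since the null places
λ_pol on the boundary of its parameter space, the asymptotic null
distribution is the mixture ½δ₀ + ½χ²₁, so the χ²₁ p-value is
conservative (asymptotic size α/2, and smaller still in finite samples
where information about λ_pol is low); the package follows the
standard χ²₁ convention, which errs toward the simpler model.

**Rate comparisons.** Two clades are called significantly different in
a rate when their 95% highest-posterior-density intervals (shortest
interval containing ⌈0.95·N⌉ sorted draws) are disjoint. No
multiple-testing correction is applied — the operational rule is the
interval overlap itself.

## Ancestral states and stochastic mapping

Marginal reconstruction combines the postorder (pruning) conditionals
with a preorder "outside" pass; node vectors are normalized and the
most-probable state breaks ties toward the smaller state. For
chromosome numbers the rates are fixed at each tree's posterior means,
and clade root vectors are averaged across the tree set (the pie-chart
semantics of posterior-averaged reconstructions).

Sex chromosome systems are collapsed to two states (multi-XY counted as
XY; tips with unknown SCS, and optionally parthenogens, dropped) and
fitted with the all-rates-different two-state model by maximum
likelihood per tree — the likelihood is the same pruning code on a 2×2
generator, which is cross-checked in the tests against the chromosome
model restricted to two states.

Stochastic maps draw node states from the exact joint conditional
(root from its marginal, each child given its sampled parent), then
fill in each branch conditional on its endpoints by rejection sampling
(forward simulation, accept on the matching endpoint, 100 attempts)
with an exact uniformization-bridge fallback — never silent truncation.
Transition counts are classified by move type (±1, doubling); an
ambiguous `1 -> 2` move counts as a fission. Fusion-vs-fission excess
is tested with a paired t-test on per-tree mean counts; a zero-variance
non-zero difference is flagged degenerate rather than reported as a
statistic.

## Tip rates and regressions

A tip rate is `(tip count − most probable immediate-ancestor count) /
terminal branch length`, averaged over the tree set; the absolute
variant averages magnitudes. Zero-length terminal branches are skipped
with a log note. Regressions of chromosome number (or tip rate) on
genome size are ordinary least squares and, phylogenetically corrected,
generalized least squares under a fixed Brownian-motion covariance (the
shared root-to-MRCA branch-length matrix, normalized to unit mean
diagonal — estimates are invariant to that normalization and to global
branch rescaling). No Pagel's λ estimation: the corrected model the
analysis calls for is the plain Brownian PGLS, and λ would not be well
constrained at n ≈ 20–50. Genome sizes enter untransformed (Mbp);
species with several estimates contribute their mean.

## Synthetic data

The generators emulate the real inputs' structure, not any particular
dataset:

* **Trees** — forward birth–death simulation (default birth 0.03,
  death 0.01 per MY) run until exactly `n_tips` lineages are extant,
  extinct lineages pruned, tips extended into the open interval after
  the last event so terminal branches are strictly positive, then the
  whole tree rescaled to a fixed root age (default 300 MY, the
  time-calibration convention). Tip labels are shared across the set
  and shuffled per tree, like a posterior sample.
* **Chromosome numbers** — exact Gillespie simulation down each branch
  under the CTMC, returning tip states *and* the typed event history
  (replaying the history must reproduce the tips — a tested
  invariant). Default true rates are the high-rate end of the regimes
  the package targets: fusion 0.420, fission 0.385, polyploidy 0.004
  per MY, root state 12.
* **Binary traits** — two-state simulation used for SCS (default
  0.002 per MY each way, XO root) and reproductive mode (asexual kept
  a minority: 0.001 in, 0.005 out).
* **Karyotype tables** — tips assigned to order/genus blocks; optional
  count ambiguity (±1 candidate sets) and per-column missingness;
  genome sizes lognormal with median ≈ 6 000 Mbp and log-sd 0.55,
  spanning roughly 2 000–18 000 Mbp as in large insect genomes, plus an
  optional additive per-chromosome component.

What the generator does *not* emulate: correlated topologies within a
posterior sample (trees are independent draws, so each tree carries its
own simulated data in recovery tests), taxonomy-linked rate
heterogeneity, karyotype measurement error beyond the ±1 ambiguity
model, and non-ultrametric trees. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model, not
robustness to model violation in real karyotype compilations.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problem sizes chosen
as the smallest that still exercise each claim: likelihood oracles
enumerate ≤4-tip, ≤6-state cases; null LRT calibration uses 200
replicates of 50 tips; recovery at the study regime uses 10 trees × 100
tips; power/size checks for HPD-overlap detection use 20 replicate
pairs of 100-tip clades. The full-scale protocol (100 trees, 1000
generations, 10 000 pooled draws) is the library default and runs
unchanged — only the counts above are reduced.

Other numerical conventions: HPD on fewer than two draws is degenerate;
ML fits run L-BFGS-B with box bounds at zero (so boundary MLEs are
exact zeros) and non-finite likelihoods mapped to a large penalty;
optimizer non-convergence is returned flagged, never hidden; the MCMC
seed stream is `SeedSequence([seed, tree_id])`, making every per-tree
chain, ambiguity draw and subsample independent and reproducible.

## Known limitations

* No speciation/extinction-linked (SSE) rate models and no
  chromosome-arm (fundamental number) evolution.
* The LRT's χ²₁ convention is conservative for the boundary null (see
  above).
* Stochastic-map event attribution is by move signature; when one rate
  regime makes two event types produce the same move (`1 -> 2`), the
  count is attributed to fission.
* PGLS assumes the Brownian covariance exactly; no measurement-error
  or λ/OU extensions.
* The joint trait-linked model is provided and tested at the matrix
  level but the headline pipeline estimates chromosome rates and SCS
  rates separately, as the main analysis design does.
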