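# Methods

This note records the models implemented in `phylocomp`, the conventions
chosen where several were defensible, the synthetic study conditions, and
the limits of what the test suite demonstrates.

## Trees and geometry

Trees are rooted, strictly binary, ultrametric, with branch lengths in My
and node ages stored as time before present.  Ultrametricity is enforced at
read time with a relative tolerance of 1e-6 × root age (BEAST-style Newick
exports carry harmless rounding error), after which tip ages are snapped to
exactly 0.  Polytomies are a hard error — no silent resolution.  Node
numbering is canonical (tips sorted by label, internals in postorder with
children ordered by smallest descendant tip), so event tables and
serialized results are stable across runs and round trips.

## Interaction timelines

A lineage is an edge, identified by its child node.  Region and guild
histories are piecewise-constant segment lists that must tile each edge
exactly.  The interaction matrix is binary: two lineages interact on an
interval when their region sets intersect (any shared region counts — the
matrix carries no overlap-fraction weighting) and both carry the focal
guild state.  Non-focal lineages have all-zero rows and evolve as if in
allopatry.  Breakpoints are the union of branching events and history
change-points, so every interval has a constant generator.

Mk models use the all-rates-different parameterization with a flat root
prior, fit by L-BFGS-B on log rates over the pruning-algorithm likelihood.
Stochastic maps draw node states from exact conditional distributions and
branch paths by Nielsen-style rejection (1,000-attempt cap per branch) with
a uniformization bridge as fallback.

## Likelihood core

All five trait models are Gaussian on the tips, and under the
parameterization used here the tip mean is the root state z₀ for every
family:

- the MC drift matrix G (G_ii = −S for interacting lineages,
  G_ij = S/(n_i−1) for A_ij = 1) has zero row sums, so the expectation
  never moves;
- OU is fit with the optimum at the root state (θ = z₀), the convention of
  standard single-optimum fitters, because θ and z₀ are not separately
  identifiable on an ultrametric tree.  `ou_vcv` retains the general
  (z₀, θ) form for completeness.

The covariance is exactly linear in the overall rate (σ² for BM/MC/OU, σ₀²
for DD), so z₀ and the rate are profiled analytically and each fit reduces
to a bounded 1-D search over the structural parameter (α, S, r, or the
rate-ratio b/σ₀² for DD_lin), started from several points (S from
{−0.01, −0.1, −1}, slopes from small negative/zero/positive values) with
the restart table kept in the fit diagnostics.  S is optimized as −e^u to
respect the S ≤ 0 constraint smoothly; search bounds scale with the tree
(|S| ≤ 30/T, |r| ≤ 20/n_max) to keep exponentials finite.

**MC covariance propagation.**  Within an interval the moment ODE
dV/dt = GV + VGᵀ + σ²I has constant G = S·G₀ with G₀ parameter-free, so the
eigendecomposition of G₀ is cached once per interval and the propagation is
exact (matrix-exponential form, with the noise integral evaluated in the
eigenbasis).  When sympatric counts are equal within interacting components
G₀ is symmetric and the real `eigh` path is used; otherwise a complex
eigendecomposition with inversion.  At each branching the parent's row and
column are duplicated into both daughters (between-daughter covariance =
parent variance).  This replaces fixed-step RK4 integration: it is both
faster (the decomposition is reused across all optimizer evaluations) and
exact for piecewise-constant generators.  An independent fine-step Euler
integration and a 10⁵-path Euler–Maruyama simulation verify it in the
tests.

**DD covariance.**  The pairwise covariance integrates the ancestral
lineage's rate along the shared root-to-MRCA path.  Per timeline a tensor
T[n] (time each tip pair's ancestor spent at sympatric count n) is
precomputed, making each evaluation a weighted sum over counts.  n_i(t)
counts the focal lineage itself (minimum 1), so isolated lineages evolve at
σ₀² + b (linear) or σ₀²·e^r (exponential); the alternative neighbor-only
convention changes the meaning of the parameters, which is why the count
convention is stated here and in the API docs.

**Subgroup trimming.**  Covariances are computed on the full tree (so
non-focal lineages contribute to the history) and then restricted to focal
tips with data for the likelihood; for a multivariate normal, restriction
equals marginalization.  Every family is fit to the *same* focal-tip data
so the AICc comparison is coherent.  Parameter counts include z₀ (BM 2,
OU 3, MC 3, DD 3); AICc = −2lnL + 2k + 2k(k+1)/(n−k−1).  Best-model ties
break toward the simpler family.

The MC mean μ_i excludes the focal lineage itself; including it only
rescales S, and the including-self convention is available as an
`include_self` switch for cross-checks against other implementations.

## Simulation, DTT, MDI

Forward simulation is Euler–Maruyama with step ≤ T/1000 by default
(halving the step moves tip moments by less than one Monte-Carlo SE in the
convergence test); branching copies the parent state.  Disparity is the
mean pairwise squared Euclidean distance.  The DTT curve evaluates, at each
internal-node age, the mean over lineages crossing that age of subclade
disparity relative to the whole clade (the root point is 1).  MDI is the
trapezoid-rule signed area between the observed curve and the *pointwise
median* of the null curves (median chosen because the relative-disparity
statistic is right-skewed; the choice is recorded in output metadata).  A
consequence worth knowing: the mean MDI of Brownian data against a Brownian
null is not exactly zero but carries a small positive mean-vs-median
offset (≈ +0.01–0.03 on 40-tip trees), which the calibration tests bound.

Sympatric/allopatric disparity trajectories classify pairs by the A matrix
of the interval containing each grid age (100 equally spaced ages by
default); present-day classification is available separately.  Ages with no
pairs in a class are missing, never zero.

## Tempo and regressions

σ̂² is the analytic ML estimate (GLS mean, divide by n).  Felsens average
(x_i − x_j)²/(2·t_MRCA) over extant cherries only — no reconstructed
ancestors.  BM-with-ME maximizes the likelihood with covariance
σ²C + diag(SE²), replacing missing SEs by one shared free parameter.
Trait-class comparisons are ordinary one-way ANOVAs with Tukey HSD, run per
tree with per-tree and mean summaries (both 4-class and pooled groupings
supported).  The support regressions are plain OLS / logistic fits; the
logistic outcome dichotomizes at RS > 0.5, and separation falls back to an
L2-penalized fit, flagged.

Mass-type measurement error from summary statistics uses the squared
standard error of the species mean, imputing the SD from range/4 when only
a range is reported and from the across-species mean SD when only n and
mean exist.  This is an explicit approximation, labeled as such in the
output column name (`mass_me_se2_approx`).

## Convergence test

Dissimilarity is the square root of the Euclidean distance over a pPC set;
sympatry indicators threshold the Szymkiewicz–Simpson coefficient at 5, 20,
50, 80 %.  The observed OLS t for sympatry is compared to t's from trait
sets simulated on the tree under BM and OU at their per-axis MLEs; the
two-tailed p is 2·min(lower, upper rank tail) with +1 correction, flagged
at α = 0.0125 (0.05/4 thresholds).  Pairwise rows are dependent; no
analytic correction is applied because the simulation null inherits the
same dependence — the size checks show the test is, if anything,
conservative at the Bonferroni threshold.

## Diversification

Three models in the Kendall/Nee reconstructed-process framework with
speciation parameterized in age, λ(age) = λ₀e^{β·age} (β > 0 = faster
speciation toward the root, i.e., a slowdown): constant pure birth,
exponential pure birth, and exponential birth–death with constant μ.
Conditioning is on survival of both crown lineages (stem conditioning by
flag).  Pure-birth cases are closed-form with λ₀ profiled; the birth–death
case integrates the survival auxiliaries on a 2,000-point age grid.  Under
this conditioning the analytic constant-rate MLE is λ̂ = (n−2)/total tree
length, which the tests verify against a numeric optimum.

## Synthetic study conditions

Defaults emulate a continental songbird radiation: crown age 25 My;
birth–death trees (λ = 0.25, μ = 0.05); up to 10 regions with per-region
gain rate d = 0.12/My, loss rate e = 0.04/My, budding probability 0.25
(the last region is never lost); guild schemes diet (4 states), habitat
(3), year-round territoriality (2) under symmetric Mk at 0.05/My;
replicate counts per class drawn around 5.35 ± 7.69 (resource use),
4.27 ± 1.17 (male plumage), 3.84 ± 1.32 (female plumage), 8.53 ± 7.24
(song).  Profiles: tiny (16 tips, 2 regions, 3 maps), standard (64 tips,
4 regions, 5 maps), paper-scale (323 tips, 10 regions, 50 maps).  The
map bank holds guild maps *conditioned on the present-day states* of the
true history (map 0), as an empirical stochastic-map bank would be; region
maps are independent draws of the range process, whose rates put pairwise
sympatry agreement near the present in the 0.75–0.9 band.  A consequence:
deep-time congruence in the synthetic bank is higher than an inference
bank would show, because all maps share the generating process rather than
the data.

Traits: 27 in four classes.  Competition-generated traits evolve among
sympatric members of the modal (largest) diet class — on a 64-tip tree
that subgroup has ~20–30 members — at effect sizes chosen for
detectability there: |S|·T ≈ 4–8 for MC and |r|·n ≈ 3–6 for DD_exp,
mostly negative DD.  Positive diversity dependence concentrates variance
near the present exactly as OU does, and at this subgroup size the two are
largely confounded; the plan therefore carries only one positive-DD trait
per run and the recovery harness does not promise to re-identify it.  Song
traits are fast (σ² ≈ 4–6 z-units²/My equivalent) and competition-neutral,
plumage intermediate, echoing the empirical rate ordering.  Measurement
replicates are drawn on a shifted positive "measurement scale"
(offset ≈ 10 + 3·SD) so relative ME stays defined for traits that cross
zero; this is a toy measurement model and its ME values are not comparable
across trait scales.

What passing tests on these fixtures do **not** show: performance under
real inference uncertainty in ancestral ranges (synthetic region maps are
draws from the truth, not posterior reconstructions), under model
misspecification of the guild process, or with the missing-data patterns
and phylogenetic error of real datasets.

## Problem sizes in tests and the acceptance script

Recovery experiments run at 100–150 tips with 10–50 replicates; the
model-selection calibration uses 100 Brownian datasets; the
convergence-size experiment uses 500 outer replicates at 500 simulations
each on a 40-tip tree; MDI calibration uses 1,000 nulls; diversification
type-I uses 200 replicates of 200-tip trees.  These sizes make the suite
run in minutes while keeping Monte-Carlo error small relative to each
criterion's tolerance; each test states the binomial/MC error bound it
uses.

## Known limitations

- A(t) is binary; partial range overlap does not down-weight interactions.
- The MC/DD likelihoods assume univariate traits; co-evolving multivariate
  competition is out of scope.
- Only single-optimum OU is offered — no multi-optimum or time-shift
  models.
- Diversity-dependent *diversification* (lineage-count speciation rates)
  is not implemented; the birth–death module exists to check that
  reconstructed lineage counts are adequate inputs for the DD trait
  models.
- The uniformization fallback in stochastic mapping can be slow for very
  stiff Q matrices with long branches.
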