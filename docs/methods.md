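# Methods

## Model

Strains compete for `R` substitutable resources supplied at rates `K_i`.
Strain `mu` is a point in phenotype space `(X_mu, alpha_mu)`: the log total
uptake budget `X = log(sum_i r_i)` and the normalized consumption strategy
`alpha = r / sum_i r_i` on the resource simplex.  After coarse-graining the
underlying chemostat over time, the relative abundances `f_mu` obey

    df_mu/dt = f_mu [ sum_i r_{mu,i} h_i(f) - 1 ],
    h_i(f)   = kappa_i / (sum_nu r_{nu,i} f_nu),        kappa_i = K_i / sum_j K_j,

where `h_i` is the availability of resource `i` (supply share divided by
total consumption).  Time is measured in generations; absolute biomass and
explicit chemostat dynamics are intentionally outside this package's scope,
as is cross-feeding.  A resource consumed by no community member has
undefined availability and is dropped from the dynamics (supply shares are
renormalized over the consumed set, with a warning).

The two derived availability summaries used throughout are `h_bar`, the
mean availability over consumed resources, and the excess availability
`g_i = h_i / h_bar - 1`, which is the quantity a strategy mutation "sees".

## Equilibria as a concave program

The dynamics admit the strictly concave potential

    Phi(f) = sum_i kappa_i log( sum_mu r_{mu,i} f_mu ) - sum_mu f_mu ,

whose gradient is exactly the vector of per-capita growth rates.  The
unique maximizer of `Phi` over `f >= 0` is the uninvadable state:
survivors have zero growth, every excluded strain has non-positive
invasion growth, at most as many survivors as consumed resources, and
`sum f = 1` automatically.  We locate it in three phases:

1. a multiplicative warm phase `f <- f * (growth + 1)` (an EM-type update
   that increases `Phi` and decays losers geometrically), run in chunks
   until the candidate set falls near the competitive-exclusion bound;
2. an active-set damped Newton solve of `growth = 0` on the candidate
   support, dropping members that collapse to the boundary and re-admitting
   excluded strains whose invasion growth at the restricted optimum exceeds
   `1e-10`;
3. when the working support exceeds the number of consumed resources (a
   degenerate face, routine in fully saturated communities), a pivot LP
   re-expresses the current consumption vector as the minimum-total-
   abundance nonnegative combination; its basic solution has at most `R`
   positive entries and cannot decrease `Phi`, which rules out cycling.

The returned state carries KKT residuals (required `<= 1e-8`, typically
`~1e-14`), exact zeros for excluded strains, and a `degenerate` flag when
some excluded strain sits within `1e-9` of neutrality.  The extinction
threshold separating "numerical dust" from survivors is `1e-10` in
relative abundance.

An independent LSODA integration of the replicator form is kept as a
cross-validation oracle; on random small instances the two agree to
`1e-6` in every abundance, and `Phi` is verified to be non-decreasing
along trajectories.

A caution that matters near full saturation: with zero budget spread
(`std_X = 0`) every strain in the binary ensemble is exactly neutral at
the uniform-availability point, the equilibrium face is massively
degenerate, and the fitness landscape collapses to a point mass at zero.
Full saturation is therefore approached with small positive `std_X`, never
reached with exactly zero spread.

## Random ensembles and calibration

The default ensemble is binary usage: each resource used independently
with probability `R0/R` (empty repertoires resampled), effort uniform over
the used set, and `X ~ N(0, std_X^2)`.  Only the spread of `X` matters
because the dynamics are invariant under a common budget shift; the mean
is pinned to zero.  A symmetric-Dirichlet alternative with concentration
matched so that `E[sum alpha^2] = 1/R0` is registered under the same
interface, and user schemes can be plugged in.

Experiments are parameterized by niche saturation `S*/R` and sampling
permissivity `S*/S` rather than by `(S, std_X)` directly.  The pool size
follows from the definitions (`S = S*_target / permissivity`); the budget
spread that produces the target survivor count is obtained by inverting a
precomputed Monte-Carlo surrogate: for each tabulated ensemble `(R, R0)`
we store the mean survivor count and the availability noise over a grid of
`(S, std_X)` points (50 independent assemblies per point; log-spaced
`std_X` because `S*` is steeply sensitive near zero spread).  The table
ships as package data and is regenerated by
`scripts/build_calibration_table.py`.  Queries interpolate monotonically
(PCHIP in log spread, linear across pool sizes); saturation targets that
exceed the spread-free ceiling return the closest achievable point with an
explicit flag.  Ensembles outside the table fall back to bisection on
pilot assemblies; the calibration result records which path was taken.

The O(1) factor `C` in the availability-noise law (below) is estimated
from the same table by inverting the predicted `Std(g)` at each grid point
and smoothing against sampling depth `S/S*` (Gaussian kernel in log
depth); it lands near 1.3 for the depths used here.

## Mutations and invasion fitness

A mutation moves a parent `(X, alpha)` to `(X + dX, alpha + d_alpha)` with
`sum_i d_alpha_i = 0`.  Knock-outs zero one used entry and renormalize;
knock-ins grant an unused resource the mean share of the current
repertoire before renormalizing (chosen so a uniform parent stays uniform
and the effect size is `||d_alpha|| ~ 1/R0`); general multi-resource
shifts are accepted if they stay on the simplex.  Knock-ins targeting a
resource no community member consumes are rejected: the coarse-grained
model assigns such a resource no availability.

Invasion fitness is computed two ways.  The exact value,
`s = e^(X+dX) sum_i alpha'_i h_i - 1`, is the initial per-capita growth
rate of a rare mutant at the unperturbed equilibrium and drives every
simulated fate.  The linearized community form `s ~ dX + sum_i d_alpha_i g_i`
is reported alongside because the analytic results are phrased in it; at
dense consumption (`R0/R >= 0.2`, uniform supply) the two agree to a few
percent.  Monoculture fitness uses the same linearized form with the
parent equilibrated alone (availabilities defined only on its own
repertoire).  Under exactly uniform supply every monoculture knockout has
the same fitness, so the community-vs-monoculture correlation is reported
as 0 with a degeneracy flag rather than NaN.

## Theory

For the binary ensemble at depth `S/S*` the mean-field analysis predicts
Gaussian excess availabilities

    g_i ~ (1 - S*/R) [ K_i/Kbar - 1 + Z_i C (S*/R)^(-1/2) sqrt((1-R0/R)/R0) ],

valid when supply is near-uniform and each resource feeds many survivors
(`R0 S* >> R`); outputs carry validity flags instead of silently
extrapolating.  Downstream quantities implemented in `crevo.theory`:

- DFE width `sigma_inv = C ||d_alpha|| (1-S*/R) (S*/R)^(-1/2)
  sqrt((1-R0/R)/R0)`, with the DFE Gaussian of mean `dX`;
- coexistence threshold `s_coex(f_P) = sigma_inv (f_P S*) (S*/R)^(-1/2)
  sqrt(2) ||d_alpha|| / ||d_alpha_comm||`, where
  `||d_alpha_comm||^2 = 2(1-R0/R)/R0` is the strategy spread between
  random community members, and `s_bar_coex` its value on a typical
  background `f_P = 1/S*` (used exactly, not up to a constant);
- coexistence probability as the establishment-weighted survival integral
  `P = int_0^inf s rho(s) e^(-s/s_bar) ds / int_0^inf s rho(s) ds`
  (adaptive quadrature), its closed form at `dX = 0`,
  `P ~ (R/S*) 2||d_alpha||^2 / ||d_alpha_comm||^2`, and the three
  direct-cost/benefit regimes of the ratio `P(dX)/P(0)` with regime tags;
- the community-vs-monoculture fitness correlation
  `r = sqrt(y/(1+y))`, `y = [Var(K)/Kbar^2 R0/(1-R0/R)] (S*/R) / C^2`,
  obtained by splitting the availability law into its supply-driven and
  community-noise parts.

## First-step experiments

An establishing mutation is drawn by factorizing supply and establishment:
parent with probability proportional to abundance (a uniform-parent switch
exists for sensitivity), target uniform among that parent's eligible
moves, acceptance proportional to `max(s, 0)`.  Only relative
establishment weights matter for every reported statistic, so the linear
weighting stands in for `2s` or `1 - e^(-2s)`.

Fates are classified at the re-equilibrated state: `COEXISTS` (mutant and
parent both survive), `REPLACES_PARENT`, `MUTANT_DIES` (impossible under
the sequential policy, where the uninvadable state must contain a
positive-growth invader; possible when rescued species compete), and
`NOT_BENEFICIAL`.  The default *sequential* policy re-equilibrates the
pre-invasion survivors plus the mutant; *reinvasion* and *simultaneous*
re-admit the full original pool.  Because the equilibrium of a candidate
set is unique, those two policies coincide in their final states; both
names are kept so protocols read naturally.  Coexistence probabilities
condition on successful invasion and exclude the rare `MUTANT_DIES`
events from both numerator and denominator.

Extinction statistics exclude the parent, and include the zero-matched
Poisson reference (`lambda = -log P(0)`), the mutant-vs-displaced shared
resource distribution against the all-residents background, the
extinction probability binned by pre-invasion abundance (log-abundance
bins by default, matching how microbial abundance distributions are
displayed; quantile bins optional), and the fold change in target-resource
use among displaced species.

## Multi-step evolution

Strictly mutation-limited: one establishing mutation at a time, sequential
re-equilibration between events, time counted in successful mutations.
Knockouts only by default; a child's mutation counter is its parent's plus
one, and the run stops when any surviving strain reaches 10 accumulated
mutations (or beneficial mutations are exhausted).  Each coexistence event
founds a tagged branch pair; descendants inherit all ancestral tags, and a
pair's coexistence duration is the number of community-wide steps until
one side loses its last living member (community-wide counting is a
deliberate choice; per-lineage clocks would read slower).  Pairs intact at
the end are right-censored: they enter the Kaplan-Meier maintenance curve
(via lifelines) but not the mean duration.  "Related" strains are
survivors sharing their founding ancestor with at least one other
survivor, which in this protocol can only arise through an in-situ
diversification somewhere in their ancestry.  DFE snapshots are stored
every `snapshot_every` events (plus first and last); excess kurtosis is
the summary used to monitor the drift from the initial Gaussian shape
toward a two-tailed exponential.

## Problem sizes and replication

Default experiment sizes were chosen so the full validation suite and the
headline statistics re-run comfortably on a single CPU: 50 communities per
niche-saturation point for the DFE-width law; 250-400 successful
invasions per coexistence estimate; 8 communities and 1000 invasions for
the extinction ensembles at near-complete saturation; 9 replicate
evolution runs at `R=100, R0=20, S*/R=0.9, S*/S=0.1` for the multi-step
statistics.  The calibration table is the one expensive artifact and is
precomputed (50 assemblies per grid point).

## What the generator does and does not emulate

Communities here are statistically exchangeable random draws: no
phylogenetic correlation between strains, no regulation, sequestration,
antagonism, cross-feeding, spatial structure, or demographic noise, and
establishment is a weight rather than a birth-death process.  Passing
tests therefore demonstrate internal consistency of the simulator with
its mean-field theory under the stated random ensembles, not fidelity to
any particular real community.  Known limitations worth flagging: near
full saturation results are sensitive to the small calibrated budget
spread (the exactly-degenerate `std_X = 0` point is excluded by
construction); multi-step statistics beyond the first events leave the
regime the replica-style theory describes, and the package treats the
simulation itself as the source of truth there; and the `C` factor is a
smoothed Monte-Carlo estimate, so theory-vs-simulation comparisons carry
its few-percent uncertainty.
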