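# Methods

## The model

Gene expression dynamics are described by an S-System, a power-law
differential-equation formalism in which gene *i*'s rate of change is the
difference of a production and a degradation term:

    dX_i/dt = alpha_i * prod_j X_j^g_ij  -  beta_i * prod_j X_j^h_ij

`alpha_i, beta_i > 0` are rate constants; the kinetic orders `g_ij` and
`h_ij` quantify regulator *j*'s effect on gene *i*'s production and
degradation (sign = activation/repression, zero = no regulation).  To
represent regulatory latency every regulator value is read a
regulation-specific lag ago, `X_j(t - tau_ij)`, giving a delay differential
equation (DDE) with two `N x N` delay matrices (`tau^g`, `tau^h`), each
entry in `[0, tau_max]` on a 0.1-time-stamp (TS) grid.  A TS is the
interval between consecutive samples of the expression time course.

Inference is *decoupled*: gene *i*'s 4N+2 parameters
`{alpha_i, beta_i, g_i., h_i., tau^g_i., tau^h_i.}` are estimated
independently, with all other genes replaced by piecewise-linear
interpolants of the observed data.  The first `tau_max` of every series is
treated as known history for the DDE and excluded from the fit.

## Numerical integration

Both the coupled generator (`integrate_full`) and the decoupled evaluator
(`integrate_decoupled`) use classic RK4 with delayed arguments evaluated on
the integrator's half-step grid; delayed values of the solution itself are
midpoint-interpolated from the stored trajectory.  The default internal
step is one twentieth of the sampling interval, which (a) resolves the
0.1-TS delay grid exactly and (b) keeps `h·|lambda| <~ 1` for the stiffest
benchmark modes (rate constants of order 10).  A trajectory that loses
positivity or exceeds `1e6` is flagged as failed and receives a sentinel
worst-case fitness (`1e9`) rather than raising, so the evolutionary search
continues.  Out-of-domain spline queries clamp to the nearest endpoint,
which keeps positive expression positive.  Kinetic orders that are exactly
zero contribute a factor 1 without evaluating the power.

The decoupled evaluator is compiled with numba; it is cross-checked in the
test suite against a closed-form exponential decay, a fourth-order
Richardson step-halving check, and a brute-force Euler DDE integration at
`h = 1e-4`.

## Fit criterion

Model quality is the squared relative error (SRE)
`sum_t ((X_cal - X_exp)/X_exp)^2` summed over all series, evaluated only on
samples after the history window.  The adaptive criterion adds a
scale-free sparsity penalty:

    ASRE = SRE + B_i * C_i * 2N / (2N - r_i)

`r_i` counts *distinct* regulator genes (a gene acting in both phases
counts once, keeping `r_i <= N`); `C_i` is 1 inside the open in-degree band
`(J, I)` and `1 + d^2` at violation distance `d` outside it; the band is
re-set every `l` generations to the population's min/max in-degree.  The
balancing factor `B_i` is zero during warm-up and is then re-computed on
the same schedule as the band.  We set it to the *resolvable accuracy
scale* of the population — the spread of SRE across the better half
(median minus best), floored at 5% of the best SRE.  Two properties
motivated this choice over a single early reset: (1) a B frozen at the
warm-up error scale dwarfs converged errors by orders of magnitude and
either strips true regulations or never prunes, depending on where it
lands; (2) under heavy measurement noise every model shares a large
irreducible SRE, and a floor-scale B prunes genuine regulations — the
spread tracks what the data can actually distinguish.

## Search engine

Parameters are evolved with trigonometric differential evolution
(population 100, `F_o = 0.5`, `F_t = 0.05`, `CF = 0.8` by default): the
DE/rand/1 mutant `r1 + F_o (r2 - r3)`, replaced with probability `F_t` by
the fitness-weighted three-parent trigonometric mutant, followed by
binomial crossover with one forced component and greedy one-to-one
replacement.  Out-of-bounds components are reflected back into
`alpha, beta in (0, 20]`, kinetic orders in `[-3, 3]`, delays in
`[0, tau_max]`.

Because structure (the zero pattern) is discrete, the continuous operators
alone converge to dense local optima in which spurious regulators absorb
interpolation error.  Four structure-aware devices fix this; each was
added after measuring a specific failure mode on noise-free benchmark
data:

1. **Skeletalising.**  Kinetic orders below `zero_tol = 0.1` in magnitude
   decode to exact zeros.  (A threshold near machine precision makes exact
   zeros unreachable for a continuous search, so the in-degree machinery
   never sees a gradient.)  The threshold sits well below the weakest
   kinetic order of either benchmark (0.3).
2. **Structure inheritance.**  The mutant's kinetic slots are masked by the
   base parent's zero pattern; crossover then recombines two structures
   instead of taking the union of three, so sparse lineages breed true.
3. **Structural moves.**  40% of trials get one explicit edit: drop the
   regulator with the weakest combined kinetic weight, drop the single
   weakest slot, or enable an absent regulator with a moderate random
   kinetic order and its delay seeded from the lagged-correlation estimate.
4. **Slope-matching rate repair.**  Every candidate's `alpha, beta` are
   overwritten by the weighted least-squares solution of
   `alpha P(t) - beta D(t) = dX/dt`, where `P` and `D` are the candidate's
   power-law terms evaluated on the observed profiles and the derivatives
   come from a cubic-spline fit of the samples (weights `1/X^2`, matching
   the relative-error criterion).  This classic decoupled device removes
   the two global scale dimensions from the search; fitness is still the
   fully integrated SRE.  Central-difference slopes proved too crude — the
   alpha/beta error they induce can exceed the SRE contrast between
   competing structures on fast transients.

The initial population enumerates regulator subsets from the empty set
upward (all subsets for 5 genes; up to singletons for 20 genes within an
~0.8-population budget), smallest first, with production signs taken from
the lagged correlations and a positive self-degradation order; the
remainder is random sparse structures.  Initial in-degree is capped at N
for networks of up to 10 genes and at 5 beyond (scale-free prior).  Half
of every random batch takes the cross-correlation lag estimates as exact
delay seeds, the other half uniform random delays.

**Phases.**  Warm-up runs with `B_i = 0` until `n_e = 50` generations or
until the best SRE halves the best initial criterion value; then `B_i` is
set and the worse half of the population is replaced by fresh random
structures.  The main phase runs `phase1_generations` with the periodic
adaptation.  Finally two multistage-refinement (MRA) stages prune, in the
best individual, every kinetic order with `0 < |k| < psi = 0.25` (zeroing
the pruned edges' delays), freeze those slots across the population, and
re-optimise for `mra_generations` with structural moves disabled; a stage
is rolled back (and refinement ends) if the best SRE degrades by more than
5%.  Pruned slots stay exactly zero through refinement.

**Lag seeding.**  For every ordered pair the target profile is shifted
forward over the 0.1-TS candidate grid (profiles linearly interpolated to
that resolution) and the lag maximising the absolute Pearson correlation
is kept, ties toward the smallest lag; per-lag |correlation| profiles are
averaged across replicate series.  Absolute correlation makes repressors
detectable; the correlation's sign at the chosen lag doubles as an
activation/repression hint for initialisation.  One lag per ordered pair
seeds both the production and degradation delay.

**Best of several runs.**  The decoupled objective is per-gene, so the
best of `k` independent runs is assembled per sub-problem: candidates are
compared by `SRE + B_cmp * 2N/(2N - r)` with `B_cmp` the geometric mean of
the candidates' final error scales.  Entire runs remain reproducible
functions of `(data, config)`; per-gene RNG streams are spawned from the
config seed, so results do not depend on execution order.

## Synthetic benchmarks

Two networks standard in this benchmark literature are bundled: a
5-gene cascade (13 regulations; delay configurations conf1 = none,
conf2 = five 1.0-TS delays, conf3 = six mixed delays up to 2.1 TS) and a
20-gene network (26 production regulations, unit self-degradation;
conf4 = none, conf5 = eight delays).  `tau_max = 3` TS for all of them.

The generator draws initial states uniformly from `[0.1, 1.0]`, holds them
constant over the history window, integrates the coupled DDE and samples
15 points per series at 1-TS spacing.  One TS corresponds to 0.05…0.01
model time units; the default is **0.01**.  The benchmark rate constants
are of order 10, so relaxation times are ~0.05 time units: sampled at one
model time unit per TS the system is indistinguishable from its steady
state inside the fitted window (measured relative range 0.0) and no method
could recover structure; at 0.01 the transient spans many TS and survives
the `tau_max`-long history cut-off.  Noise is multiplicative Gaussian
(`X * (1 + eps)`, `eps ~ N(0, level)`), floored at `1e-3` to keep power
laws defined — the conventional reading of "5% noise" in this literature.

What the generator does *not* emulate: technical artefacts (dye bias,
missing values), biological replicates with batch structure, or
non-uniform sampling.  Passing the synthetic campaigns therefore
demonstrates correct recovery under the model's own assumptions, not
robustness to real microarray pathologies.

## Evaluation

Networks are scored over all `2 N^2` kinetic-order slots (production and
degradation separately, self-edges included): a slot is present when its
kinetic order is nonzero; sensitivity, specificity, precision and F-score
follow from the confusion counts, with 0/0 reported as undefined rather
than coerced.  A recovered delay is correct within ±0.1 TS (one resolution
step); an interaction inferred with a delay of at most 0.1 TS counts as
instantaneous.

## Campaign scale and measured behaviour

The standard evaluation recipe in this package (used by the test suite and
`scripts/acceptance.py`) is deliberately desk-scale: four replicate series
(one seed each), population 60, 400 main-phase + 2x150 refinement
generations, best of five runs.  At this scale, single runs recover
roughly half of the per-gene structures exactly; the per-gene best-of-five
assembly recovers most genes, with F-scores in the 0.85–0.95 range on the
noise-free 5-gene configurations and recovered delays accurate to one
resolution step.  Exhaustive recovery of every regulation at this reduced
budget is not guaranteed — the full-scale protocol for these benchmarks
(ten series, population 100, 1000 + 2x250 generations; the package
defaults) multiplies both the data constraints and the search budget
severalfold.

## Known limitations

* The decoupled approximation injects linear-interpolation error of the
  regulator profiles into every fit; with sparse sampling this error, not
  the integrator, bounds the achievable SRE.
* Regulations can be structurally unidentifiable at small sample sizes.
  In the four-series 5-gene campaigns, gene 3 relaxes to the fixed point
  X3 = 1 where its dependence on gene 2 cancels to second order; the two
  corresponding kinetic-order slots then sit below the decoupling-error
  floor, and structure-frozen fits show the criterion genuinely preferring
  a model without them (removing those edges does not worsen — and a rival
  self-only structure slightly betters — the achievable fit error).  This
  caps noise-free sensitivity at 11/13 in those campaigns regardless of
  search effort; the fractional-delay configuration, where the same edge
  carries a 1.3-TS delay, restores identifiability.
* The slope-matching repair assumes the observed samples support a
  reasonable derivative estimate; heavily noisy or very sparse series
  degrade it to a rough initialiser (fitness remains the integrated SRE,
  so correctness is unaffected).
* Only uniformly sampled series are accepted by the decoupled evaluator;
  resample non-uniform data first (`resample_series`).
* The coupled 2N(N+1)-parameter (non-decoupled) estimation problem and
  stiff/adaptive integration are out of scope.
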