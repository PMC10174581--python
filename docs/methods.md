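# Methods

## Model and assumptions

The package treats a quantitative food web as a static, flux-weighted
directed graph.  Species survival depends only on the fraction of
original energy inflow retained; there is no population dynamics, no
prey switching, and no rewiring — when a prey species dies, its
consumers simply lose that flux.  These are the standard assumptions of
topological (structural) robustness analysis; they make large webs
tractable at the price of ignoring compensatory feeding behaviour, so
results should be read as structural vulnerability, not demographic
prediction.

A virtual environment node closes the system: it sends each species its
import flux and receives exports + respiration.  Import edges never
disappear, so a species drawing a fraction ≥ (1 − t) of its baseline
inflow from imports can never go secondarily extinct — deliberate, since
the environment is not a removable node.  The species→environment
weights (exports + respiration, merged into one edge) are retained for
energy accounting and for out-degree scores, but play no role in
extinction, which is driven by inflows only.

## Cascade semantics

* Extinction rule: P(i) ≤ t, with the boundary case counted as extinct.
  A `strict_less` switch flips the rule to P(i) < t for sensitivity
  checks; all shipped defaults use ≤.
* Propagation is synchronous (all species failing the rule in a round
  die together) and runs to a fixed point.  The cascade operator is
  monotone — more deaths can only lower inflows — so the fixed point is
  unique and independent of update order; the test-suite cross-checks
  synchronous against randomised one-at-a-time propagation on 100
  seeded webs.
* A secondarily extinct species loses its outgoing edges exactly like a
  primarily removed one.
* Species with zero baseline inflow are accepted but logged at load
  time; their survival fraction is defined as 0 and they die the first
  time they are evaluated.
* At t = 1 every species with any inflow dependence dies (P ≤ 1
  always); at t = 0 only species whose inflow drops to exactly zero die.
  Both extremes are exercised as closed-form tests.

## Centrality baselines

Degrees are flux-weighted and computed on the current surviving web.
By default they include the environment edges (imports in-side,
exports + respiration out-side), because those edges are part of the
augmented graph; `--exclude-env-centrality` drops them.  The default
protocol mode is *dynamic* (scores recomputed after every removal and
cascade); *static* mode (rank once on the intact web) is kept as an
option because a one-shot ranking is also a defensible reading of
"decreasing order" protocols.  Ties break to the lowest species index,
with an optional seeded random tie-break.

Eigenvector centrality is the dominant eigenvector of the transpose of
the alive inter-species flow matrix, found by power iteration
(tolerance 1e-10 on the L1 change, at most 10⁴ iterations), L1-normalised
and non-negative: a species scores highly when it receives much energy
from high-scoring species.  Two degenerate cases need conventions: an
all-zero surviving flow matrix yields uniform scores, and on acyclic
webs (dominant eigenvalue 0, nilpotent matrix) the last non-zero
iterate is returned, concentrating mass on terminal consumers.  Both
conventions are isolated in one function and verified against dense
eigendecomposition on strongly connected webs.

## Tabu search

A solution removes exactly n species; moves swap one removed with one
kept species.  Per iteration, up to `n_can` candidate neighbours are
drawn whose swaps are neither in this iteration's swap list nor in the
tabu list; the best candidate becomes current.  If it improves the
historical best, the best is updated and the tabu list cleared
(aspiration); otherwise its swap enters a FIFO tabu list of capacity
`L`.  Ties among candidates go to the first one drawn, keeping runs
reproducible for a fixed seed.

Defaults `T_max = 100`, `n_can = 20`, `L = 7`, `retry_cap = 200` are
conventional mid-range settings for webs of tens to low hundreds of
species; all are exposed on the CLI and in `TabuConfig`.  Two
pathologies are handled explicitly: when the retry cap is hit with at
least one candidate in hand the iteration settles for what it has, and
when it is hit with none (every swap forbidden) the oldest tabu entry
is evicted, so candidate generation can never loop forever.

The removal-curve protocol optimises each budget p = 1..N independently
(seed derived as `seed XOR p`, kept below 2³¹), then pads the series
with N after the first total collapse.  Because independent stochastic
runs could occasionally produce a dip, each budget also evaluates the
previous budget's best set plus one extra species as a fallback
incumbent — removing more species never lowers F, so the reported curve
is non-decreasing by construction.  Validity is certified against
exhaustive enumeration: on 30 seeded webs with N = 8–10 and n = 2–3
(T_max = 200, n_can = 10, L = 3) the search must reach the brute-force
optimum in at least 95% of runs and may never exceed it.

## Metrics

SEA is computed literally as (Σₚ Nₚ)/N² − 0.5.  Immediate total
collapse gives exactly 0.5; the no-secondary-extinction curve Nₚ = p
gives 1/(2N), the discrete area of the diagonal, which is the value the
idealised "no secondary extinction → 0" reading approaches as N grows.
R₅₀ is (min p with Nₚ ≥ N/2)/N; a tie at exactly half counts as having
reached 50%.  The threshold sweep uses the 19-point grid 0.05..0.95 in
steps of 0.05.

## Comparison statistics

The harness produces one row per (web, method, replicate); replicate
averages per web feed the statistics, so ANOVA and Dunnett contrasts
operate on web-level values (one value per web per method) — with six
methods and twelve webs that is a (5, 66) degrees-of-freedom design,
which matches the scale of the published critical values this package's
regression fixtures embed.  Dispersion is reported both as SD and SEM,
since "mean ± SEM" labels in the literature sometimes turn out to be
SDs on recomputation.  The classical F statistic and the Dunnett
max-|t| adjustment come from scipy (`f_oneway`, `dunnett`); hand-computed
two-group oracles and the balanced-design equal-CI-width property guard
them in the tests.

## Synthetic webs

The generator draws a niche-model topology (species on a niche axis,
each consumer eating a contiguous niche interval) and resamples until
the realised binary connectance is within ±0.03 of the target, then
assigns lognormal(0, σ=1) flux weights.  Basal species always import
from the environment; a configurable fraction (default 0.1) of
consumers do too, mimicking webs where mid-trophic compartments receive
allochthonous input.  Exports and respiration are small positive
lognormals.  Defaults (S = 30, C = 0.15) sit inside the empirical
envelope of the carbon-flux webs this package targets (S ≈ 20–130,
C ≈ 0.08–0.37).

What the generator does *not* emulate: mass balance (inflows need not
equal outflows), allometric scaling of fluxes, empirical degree
correlations, or the block structure of detrital compartments.  Passing
tests on synthetic webs therefore certify the algorithms' correctness
and invariants, not ecological realism of any particular prediction.

Weighted connectance C_w is reported for description only: per-species
inflow and outflow flux distributions are reduced to effective link
counts exp(H) (Shannon-entropy perplexity), averaged and divided by S².
This is one member of the family of entropy-based effective-connectance
definitions; with equal weights it reduces exactly to the binary
connectance, which the tests pin down.

## Problem sizes and determinism

The shipped test-suite runs webs of 8–40 species (plus two generator
size checks at 130), 100-web cascade cross-checks, and the 30-web
optimizer certification — a few tens of seconds end to end.  Every
stochastic path takes a numpy `default_rng` seed derived from a single
base seed (replicates add their index, budgets XOR theirs), so every
result in this documentation is reproducible verbatim.

## Known limitations

* The replication harness for the original twelve carbon-flux webs
  needs those webs as canonical JSON under `data/s1/` (the
  `--s1-map` adapter converts supplementary-style key names); the webs
  are not redistributed here, so that integration test reports failure
  until the data is supplied.
* Dunnett p-values below scipy's integration resolution are reported as
  a "<0.01" band rather than a raw number of dubious precision.
* The optimizer certifies near-optimality only at oracle-checkable
  sizes; on large webs the usual metaheuristic caveat applies — the
  result is a lower bound on the true maximum disintegration.
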