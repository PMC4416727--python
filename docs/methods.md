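# Methods

## The model

`osotua` simulates a population of livestock herders who insure each other
through need-based transfers — the Maasai *Osotua* institution — while
repeated disasters strike the population with spatial and/or temporal
correlation.  The package has three moving parts: a correlated disaster
generator, a spatially embedded support network, and the yearly herd
dynamics that couple them.  A fourth component analyzes the directed
"cattle-flow" networks that the disasters activate.

### Disaster fields

Disasters live on a lattice of 100 ring locations x 50 years.  A field is
built from M = 40 cluster modes placed uniformly on the lattice.  Each
cluster contributes a number of events drawn from Normal(N/M, 1) — with the
defaults N = 500, M = 40 that is Normal(12.5, 1) — rounded to the nearest
non-negative integer.  Events are distinct lattice cells sampled by
discretizing continuous draws from an axis-aligned bivariate normal with
standard deviations sigma_x (locations) and sigma_t (years) centered on the
mode.  The location axis wraps around the ring; draws whose year falls
outside [1, 50] are rejected and redrawn, which preserves the Gaussian
profile inside the window.

Correlation scenarios narrow these widths geometrically.  At strength level
p the correlated axis uses sigma = 2^-(p-1) times its base value (64 for
space, 32 for time); the other axis stays at base.  Level p = 1 with base
widths is indistinguishable from uniform scattering (the "none" scenario);
p = 7 brings sigma_x down to one lattice spacing, the natural end of the
grid, so the default level range is 1..7.  Four scenarios: `none`,
`spatial`, `temporal`, `spatiotemporal` (both axes narrowed).

Numerical choices worth knowing:

- *Distinctness is per cluster.*  Cells struck by two different clusters
  collapse into a single occupied cell of the binary occupancy matrix.
  Consequently the realized event count at the weakest correlation averages
  about 476, not the nominal 500: with near-uniform sampling the expected
  number of occupied cells is 5000·(1 − (1 − 12.5/5000)^40) ≈ 476.  The
  collapse is intrinsic to a binary occupancy representation; an optional
  global-mixture mode (`mixture=True`) samples the full M-modal landscape
  without replacement instead.
- *Exhaustion policy.*  Under very narrow widths a cluster may not have
  enough reachable cells to honor its distinct-sample quota within the
  10^4-draw budget.  The default (`exhaustion="truncate"`) returns the
  cells found, so that in the sigma -> 0 limit each cluster collapses onto
  its mode alone and a field carries at most M events, matching the
  delta-distribution limit of the sampler.  `exhaustion="spill"` instead
  tops up deterministically with the nearest unused cells.
- Continuous draws map to cells by rounding each coordinate to the nearest
  integer.  Locations are 0-based (0..99), years 1-based (1..50).

### Support networks

The support network starts as a ring lattice of n = 100 nodes with k = 4
(each node linked to two neighbors per side); a node's pre-rewiring index
is its *physical position*, which is what disasters see.  A fraction beta
of edges is then rewired: each edge independently selected with
probability beta keeps one randomly chosen endpoint and reattaches the
other to a uniform node (self-loops and duplicates rejected), conserving
the edge count and mean degree exactly.  beta = 0.2 gives a spatially
almost homogeneous network, beta = 0.8 a strongly heterogeneous one whose
links often reach far outside a disaster's correlation length.  We also
provide a configuration-model generator with a truncated power-law degree
sequence (exponent 2.5 by default, scaled to a target mean degree, ring
positions assigned by a random permutation) for degree-heterogeneity
comparisons.

### Herd dynamics

Every node starts with 70 cattle; the minimum sustainable herd is 64.
Each year, in order:

1. **Growth** — every living herd is multiplied by 1 + g,
   g ~ Normal(3%, 3%) truncated below at −100%.  Only the mean is a
   published quantity; the spread is configurable (`growth_sd`).
2. **Loss** — every living node whose lattice cell is occupied this year
   loses a fraction l ~ Normal(30%, 10%) of its herd, clipped to [0, 1].
   A disaster striking a living node counts as an *effective* disaster;
   hits on dead nodes are wasted (the *masking* effect).
3. **Requests** — every living node below 64 asks one uniformly chosen
   *living* partner for exactly 64 − herd.  The partner gives the full
   amount iff that leaves it at or above 64, else nothing.  Needy nodes
   are processed in a fresh random order each year (outcomes can depend on
   order when givers are near the threshold); a node may serve several
   askers in one year.  Refusals are final by default (`retries` asks
   further distinct partners).  The step conserves total cattle.
4. **Survival check** — a node below 64 at this point extends its
   below-threshold streak, otherwise the streak resets; two consecutive
   below years eliminate the node.  Dead nodes are frozen: they never
   grow, lose, give, or receive.

Herds are real-valued; growth and losses are multiplicative percentages,
so nothing is gained by integer rounding.  The survival check runs after
the gift round by default — a gift that restores a herd to exactly 64
prevents that year from counting, which is the point of the institution —
with `check_pre_gift=True` available for sensitivity analysis.  The
growth and loss percentages of a run are pre-drawn before any gift-round
randomness, so runs started from the same seed see identical fields and
shocks whether or not a network is present; paired isolated-vs-networked
comparisons rely on this.

### Flow networks

All gift events of a run collapse into a directed graph with one edge per
(giver, receiver) pair, weighted by event count.  Metrics: mean shortest
path over connected ordered pairs of non-isolated nodes (undirected
projection), mean total degree over non-isolated nodes, mean local
clustering of the undirected projection, and cycle counts.  "Number of
cycles" is ambiguous; both candidate definitions are implemented — the
default counts elementary directed circuits (Johnson's algorithm via
networkx, capped at 10^5 with an overflow flag), `cyclomatic` returns
|E| − |V| + #components of the projection.  The circuit-count magnitudes
reported for randomized temporal-correlation networks (thousands) indicate
the enumeration-style definition.  Edges of nodes that later died are
retained: activation is a property of the whole 50-year history, and
dropping dead nodes fits the published per-scenario values no better
overall.  Null baselines shuffle the directed edge set by double edge
swaps (in- and out-degree sequences conserved exactly), 10 swaps per edge,
ensemble means over at least 100 randomizations.

### Experiments and reproducibility

`run_sweep` crosses scenarios x levels x network treatments; each cell
draws `n_networks` independent networks and `n_reps` repetitions per
network, regenerating the disaster field each repetition by default
(`regenerate_field=False` fixes one field per network).  All randomness
derives from one master seed through `numpy.random.SeedSequence` spawning,
so cells, networks and repetitions have independent streams and every
result is bit-reproducible.  Two replicate presets exist: `paper`
(100 networks x 1000 reps, the published protocol) and `ci`
(20 x 100) for fast runs.  The acceptance script uses 100 networks x
200 repetitions per cell for herd-size summaries, 400 replicate runs for
flow clustering, 200 fields for generator calibration, and 150 paired
replicates for the networked-vs-isolated survival gain; the test suite
uses smaller ensembles (their standard errors are quoted in the
assertions).

Mean surviving herd sizes pool all surviving nodes across the ensemble
(total surviving cattle / total survivors); averaging per-run means first
differs by under 1%.

## What the generator does and does not emulate

The synthetic disaster fields reproduce the *correlation structure* of
recurring disasters — droughts (spatio-temporal), earthquake zones
(spatial), economy-wide downturns (temporal) — not any empirical hazard
process.  Losses are independent percentage draws; real disasters have
severity correlated with the event, herds have demography rather than
percentage growth, and real support networks are not degree-regular rings.
Passing tests therefore validate the mechanism (masking, need-based
pooling, activated-network structure), not quantitative predictions for
any real pastoralist economy.

## Known limitations and open choices

- The asking rule is read as: any below-threshold living node asks once
  per year, whether or not it was struck that year.  The alternative
  (requests only in the year of a loss) produces markedly sparser
  activated networks whose clustering does not match the published
  flow-network values, and was rejected on that basis.
- Under this reading the simulated mean herd sizes per surviving node run
  some 15–20% below the published 122/130 (uncorrelated) and the
  published beta-contrast at strong spatial correlation (195 vs 165) does
  not emerge: the two network heterogeneities differ by at most a few
  percent in mean surviving herd in every variant we examined, and the
  ordering is weakly inverted.  The survival-rate patterns — the >50%
  networked survival gain, the scenario orderings, and the masking
  signatures — all reproduce.  A pre-gift survival check closes most of
  the herd-size gap but caps the networked survival gain at ~35%,
  contradicting the better-attested survival claim; we keep the post-gift
  check.
- Cross-cluster collapse (above) places the realized event count ~5%
  below the nominal N at weak correlation; results treat the generator's
  own realized behaviour as the ground truth.
- Request processing order, partner choice among living partners only,
  and real-valued herds are modeling choices the sources leave open; each
  is a flag or documented default.
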