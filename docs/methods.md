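# Methods

## Model structure

The simulation couples three entities. The **meadow** is a continuous 2-D
torus (side `size_map`, default 50): distances use the minimum-image
convention, so there are no edges and the flower field is statistically
homogeneous. **Flowers** are immobile point resources with a unit nectar
capacity. **Pollinators** are mobile agents in one of three behavioural
modes (searching, assessing, handling), identical within a run, that differ
only in whether they read scent marks.

Time is discrete; one step is one pollinator action. Each step the engine
activates every pollinator once in a fresh uniform-random permutation, then
updates every flower. Flower claims are resolved sequentially within the
step — the first claimant in the permutation wins — which enforces the
one-occupant-per-flower rule without a separate conflict-resolution phase
and, because the permutation is redrawn each step, gives no pollinator a
systematic priority.

## Nectar, scent, and their shared clock

Nectar refills linearly at `refill_coef` of capacity per step, capped at 1;
the scent mark fades at the same rate, floored at 0. Both are functions of
one state variable, the time since last harvest, so mark concentration is
by construction a reliable cue for standing nectar: `nectar + scent = 1`
until saturation. A harvest resets the clock (nectar 0, mark 1).
Never-visited flowers are represented by a sentinel (no clock), preserving
the initial condition — full, unmarked — exactly.

Two modelling choices here were genuinely open:

* **Occupancy pauses the clock.** No nectar is secreted (and no mark
  fades) while a pollinator sits on a flower. The alternative — refilling
  under the visitor — makes total nectar production nearly independent of
  foraging strategy at high competition (every flower is then a
  near-permanent drip at the same rate), which suppresses all
  strategy-level differences in collected nectar; with the pause, heavy
  revisitation carries a real community-level cost, and the strategy
  contrasts at high competition emerge. Per flower-visit the difference is
  ≤ `cost × refill_coef` ≈ 1% of capacity, but the aggregate effect at two
  pollinators per flower is large because flowers are then occupied most of
  the time.
* **Scent has no independent decay rate.** The mark is defined as the
  complement of normalized nectar. A decoupled fade rate would let the cue
  be wrong in either direction; that regime is out of scope.

## Pollinator behaviour

A searching pollinator perceives unoccupied flowers within the detection
radius (1 length unit). It ignores flowers in its **novelty memory** — the
last `novelty_memory` (default 4) flowers it left or rejected. Depth 1
(remembering only the very last flower) lets a forager shuttle endlessly
between two mutually in-range flowers, harvesting only the trickle of
refill between bounces; this trap dominates low-competition dynamics and
inverts the handling-cost effect. Any depth ≥ 2 breaks pairwise cycles;
4 also covers small clusters and behaves indistinguishably from 8 in our
measurements.

Landing consumes the step (the pollinator is placed exactly on the flower
regardless of the within-radius distance — one step is one action).
Assessment consumes the next step: a scent user accepts with probability
`1 − scent`. The literal alternative (accept with probability equal to the
mark concentration) would make just-emptied flowers maximally attractive —
the opposite of a repellent cue — but is exposed as
`scent_semantics="literal"` for anyone who wants to examine that reading.
A rejected flower is released immediately and only remembered as
non-novel; rejection does not reset the flower's clock or count as a
visit. An accepted visit then costs `cost` handling steps, so a full visit
cycle is 1 (landing) + 1 (assessment) + `cost` steps and accepted visits
per pollinator are bounded by `n_steps / (cost + 1)`.

Movement is a correlated random walk: the turning angle is Normal(0, σ²)
with σ = 2π · `inertia` radians and the step length is 1 unit (equal to the
detection radius, keeping perception and motion commensurate). `inertia`
0.01 is near-ballistic; 0.4 approaches uniform re-orientation. The default
0.1 (σ ≈ 0.63 rad) gives moderately persistent paths.

## Randomness and replay

One `numpy` Generator seeded from `SimulationConfig.seed` drives placement,
activation order, turning angles, Bernoulli trials and candidate
tie-breaks, so a run is bit-reproducible from (config, seed). Candidate
lists from the periodic KD-tree are sorted before the uniform tie-break to
keep the draw platform-independent. Experiment and sensitivity seeds are
derived per (cell, replicate) through `numpy.random.SeedSequence`, keeping
replicates independent and the whole table reproducible from one base
seed.

## Metrics

Coefficients of variation use the sample (n−1) standard deviation over the
mean and are reported as missing (NaN) rather than raised when fewer than
two values exist or the mean is zero. Pollen carryover counts, for each
accepted visit, the *distinct* downstream flowers (excluding the focal one)
the visitor reaches by the end of the run — distinct recipients, because
the quantity proxies how many flowers can receive the focal flower's
pollen; counting total subsequent visits is the noted alternative. Flowers
never visited contribute no carryover observations. A `carryover_window`
parameter (default unlimited, i.e. the run horizon) restricts the
downstream horizon in steps for sensitivity checks.

Nectar is conserved exactly: collected + standing = initial stock +
delivered refill, checked per run to floating tolerance.

## Experiment harness and problem sizes

The competition experiment crosses pollinator abundance
{0.1, 0.3, 0.5, 1, 2} per flower with refill {0.001, 0.0025, 0.005} and
both strategies; the cost experiment varies handling cost 1–10 at abundance
0.1. The default 10 replicates per cell (distinct derived seeds) give
cell-mean standard errors small enough for the qualitative contrasts; the
test suite runs the full competition design at this replication
(300 simulations, a few minutes).

Sensitivity analysis samples parameters i.i.d. uniform from their variation
intervals (Latin-hypercube sampling is deliberately not the default), runs
one simulation per draw, and fits a random-forest regression (2,000 trees,
3 variables per split) of mean nectar collected on the parameters;
reported importance is permutation importance and variance explained is the
out-of-bag R². The tested contract is the importance *ranking* only. The
desk-scale design (`reduced_sensitivity_design`) uses 300 samples with
every parameter confined to a narrow neighborhood of its default
(map 45–55, steps 900–1100, density 0.08–0.12, abundance 0.2–0.4, cost
3–7, inertia 0.05–0.15) while the refill coefficient keeps its full range,
since its dominance is the property being probed.

## What the generator does and does not emulate

Flowers are homogeneous in capacity, refill rate and handling cost;
pollinators are homogeneous in strategy and perception; the arena is
unbounded (toroidal) and floristically uniform. Passing tests therefore
speak to the information-use mechanism itself, not to landscapes with
floral patchiness, species mixtures, central-place foraging, energetic
costs of flight, or communities mixing strategies — all out of scope.

## Numerical and degenerate-input choices

Coordinates are folded into [0, `size_map`) with an explicit guard against
floating-point folding onto the boundary. `n_steps = 0` and
`pollinator_ratio = 0` are valid degenerate runs (no events, flowers
full). Realized counts round half away from chance: `round(density·area)`
flowers and `round(ratio·flowers)` pollinators, reproducing the canonical
250-flower / 500-pollinator setup exactly. Configs are validated eagerly;
a config that realizes zero flowers is rejected.

## Known limitations

* The low-competition disadvantage of scent use is a small effect
  (collected-nectar ratio ≈ 0.96 at abundance 0.1 on the slowest-refill
  landscape) and fades as refill accelerates; with fast refill the two
  strategies are near-parity at low abundance.
* The CV of remaining nectar for scent users is flat across competition but
  not small in absolute terms (≈ 0.8); only the contrast with non-users
  (≈ 1.0 → 1.7) is a robust signature.
* Sequential claim resolution means within-step outcomes depend on the
  activation permutation; statistically this is washed out by redrawing the
  permutation each step, but single-step trajectories are not
  permutation-invariant.
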