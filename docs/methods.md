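# Methods

This note records the algorithmic conventions `spool` uses, why they were
chosen where the published description leaves room, what the synthetic data
emulate, and the known limitations.

## Model and update cycle

One compute step processes a binary input **z** as: overlap → inhibition →
(if learning) Hebbian update → duty-cycle update → boost update →
(periodically) inhibition-radius update.  With learning disabled the step is
a pure function of the state; nothing is mutated, and boost factors are not
applied (see below).

**Potential pools.**  The potential radius γ is interpreted as a *radius*:
column *i*'s pool is the hypercube spanning 2γ+1 lattice sites per dimension
around its centre, clipped at the input borders (no wraparound), each site
kept with probability *p*.  This is the reading under which the documented
initial identity between the inhibition radius and γ holds exactly (a full
pool has connected span ≈ 2γ+1, and the radius formula below returns
(2γ+1−1)/2 = γ), and it is the reading that reproduces the published
untrained statistics.  Pools are fixed after construction.  An empty pool
(possible with *p* < 1 near borders) is resampled once, then raises.

**Inhibition.**  Neighborhoods are Euclidean balls of the current radius ϕ
on the column grid, excluding the column itself and any dead columns;
global inhibition treats every other living column as a neighbor.  The
winner rule is configurable:

* `topk` (default): under global inhibition, exactly `round(s·N)` columns
  with the highest overlaps activate, ties broken toward lower column
  index; under local inhibition it behaves as `count`.
* `count`: column *i* activates when fewer than `round(s·(|N_i|+1))`
  neighbors have strictly greater overlap — ties keep all tied columns, so
  density can transiently exceed the target.
* `percentile`: the literal nearest-rank percentile test
  `o_i ≥ Z(V_i, 100−s)`.

`topk` is the default because deterministic tie-breaking is what produces
the documented behaviour of the *untrained* pooler: before learning,
overlaps are small integers with massive ties, and index tie-breaking
concentrates activity on a subset of columns (≈28 % of columns never fire
over a 100-pattern set, entropy ≈0.122 bits/column).  Tie-admitting rules
spread untrained activity much more evenly and do not show this regime.  A
column must also reach the stimulus threshold θ_stim, compared against the
same overlap value used in the competition.

**Boosting is a learning-time mechanism.**  Boost factors multiply the
overlaps only while learning is enabled; frozen evaluation ranks columns by
raw connected overlaps.  Homeostatic gain exists to rotate opportunity
among columns during plasticity; applying it during read-out makes
evaluation hostage to the instantaneous boost state — marginal, strongly
boosted columns with one or two connected active synapses flip under any
perturbation, and measured stability drops from ≈0.99 to ≈0.87.  Duty
cycles follow the fixed-period exponential average with T = 1000 from the
first step (an initial-period ramp was evaluated and rejected as a
deviation from the stated update).

**Dynamic inhibition radius.**  ϕ = max(1, (mean connected span ×
columns-per-input − 1)/2), where a column's span is the per-dimension
extent (max − min + 1) of its connected inputs, averaged over dimensions
and over columns with at least one connected synapse.  Recomputed every 50
learning steps (the cadence is unspecified in the literature; 50 bounds the
cost of rebuilding neighborhoods).  If no column has a connected synapse
the radius is left unchanged.

**Lesions.**  Dead columns never activate, never learn, and are excluded
from inhibition neighborhoods, duty-cycle means, and all metric
denominators.  Lesioned input bits read as zero forever; synapses onto them
are retained and decay only through subsequent learning, which is what
produces the documented "no immediate change, then rewiring" signature.

## Initialization

Permanences are i.i.d. U(0,1) on the pool (exactly 0 elsewhere), so ≈50 %
of potential synapses start connected at θ_c = 0.5.  Duty cycles start at
0 and boosts at 1.  All randomness flows from a single seed through
separate child streams (pool, permanences, run-time shuffles), so a seed
fully determines the trajectory and serialization round-trips are
bit-exact, including the RNG state.

## Evaluation protocol

Metrics are measured at epoch boundaries with learning frozen, on the full
current dataset (entropy, sparseness, utilization) and on a fixed
50-pattern subset for the stability index.  The noise sweep corrupts each
pattern independently at each level k ∈ {0, 0.05, …, 1}: `round(k·n_active)`
active bits are turned off and the same number of inactive bits turned on
(popcount exactly preserved, round half up); the robustness index is the
trapezoidal integral of the mean retained-output fraction over k ∈ [0,1].
Patterns that drive no output column are excluded with a warning.

## Study configurations

Two standard layouts follow the published parameter table: a dimensionless
pooler (1024 columns, global inhibition, γ = ∞) and a topological one
(32×32 columns over 32×32 inputs, local inhibition, γ = 5).  The
quantitative baseline (sparseness, entropy, noise robustness, utilization)
uses the dimensionless pooler: with global pools, trained winners connect
to essentially all of a preferred pattern's bits, giving the large
winner-versus-runner-up margins that the published trained noise-robustness
values (index ≈0.65, output nearly unchanged at 40 % noise) require.  A
topological pooler's 121-bit windows see at most ~12 % of a sparse
pattern's bits; its trained robustness saturates near 0.47 regardless of
the winner rule, so those endpoints cannot arise from the topological
configuration.  The fault-tolerance experiments use the topological pooler,
whose local structure the lesions probe.

## Synthetic data

The generators emulate the study's stimulus families exactly: 32×32 random
binary images with per-image density uniform in [2 %, 20 %]; 10×10 images
with one horizontal and one vertical 5-pixel bar at independent uniform
positions; 10×10 crosses (two 5-pixel bars sharing their centre, placed
fully inside); 32×32 unions of six 7-pixel bars, each independently
horizontal or vertical, fully inside the image.  Bars are one pixel thick.
Each epoch presents the dataset once in a fresh seeded random order; the
fault-tolerance stream draws a fresh 100-image bar-set epoch each time.
These stimuli are statistically stationary, noise-free and uncorrelated
across presentations — passing tests on them demonstrates the coding and
homeostatic properties, not performance on natural, drifting, or temporally
correlated data.

## Experiment schedules and problem sizes

* Baseline: 100 patterns × 40 epochs × 10 seeds (the published training
  length), noise sweeps before and after training.
* Dataset switch: 50 epochs on one random-sparse set, 70 on a disjoint one;
  noise sweeps at epochs 50, 51 and 120; synapse formation/removal counted
  per epoch from the connected-matrix diff.
* Lesions: 18 000 pre-lesion and 42 000 post-lesion inputs in 100-input
  epochs — the full published schedule.  A shortened 3 000/6 000 schedule
  was evaluated and rejected: the pre-lesion coverage trace is still in its
  initial pruning transient at 3 000 inputs, which masks the stroke
  recovery and inverts the plateau-speed comparison.  Stroke kills the
  central 11×11 block of *columns*; the input lesion silences the central
  11×11 block of *inputs*; the comparison region is the equally sized block
  immediately to the right of the centre.  Recovery plateaus are detected
  as the trace staying within 5 % of its final value.

## Numerical choices

Overlaps and permanences are float64; the connected matrix is boolean with
a float mirror for the mat-vec.  Nearest-rank percentiles use no
interpolation.  `round(x)` on counts is floor(x + 0.5).  The winner quota
is never below one; a column with an empty neighborhood self-activates if
it meets θ_stim.  Permanences are clipped to [0,1] after every update, and
the connected matrix is recomputed only for rows that learned.

## Known limitations

* Trained ownership converges almost perfectly under U(0,1) permanence
  initialization: trained entropy reaches ≈99 % of its sparsity-bound
  maximum and the trained robustness index lands ≈4–5 % above the published
  value, which reflects a less perfectly equalized reference state.
* With exact-k inhibition, patterns owned by more than `round(s·N)` fully
  connected columns tie at the activation cut; input noise reorders the
  tied owners, so the mean retained-output fraction sits at ≈0.98–0.99
  rather than exactly 1.0 from the first nonzero noise level.  "Unchanged
  output under noise" is therefore approximate at the ~1 % level.
* Receptive-field structure on bars/crosses/MNIST is qualitative; the
  mixed-input overlap probe reports ordering (merged inputs overlap their
  constituents far more than random pairs) rather than absolute values.
* No temporal pooling: the model has no memory across steps beyond its
  synapses and duty cycles.
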