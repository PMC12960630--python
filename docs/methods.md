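# Methods

## Model overview

The simulator models a hard-wired spiking circuit that performs tabular
Q-learning with the learning arithmetic executed locally at each synapse.
States and actions are one-hot mapped to neurons; the p×q synapse grid is
the Q-table, each synapse a saturating n-bit up/down counter with levels
1..2^n.  All value-carrying signals are deterministic periodic spike
trains on a shared digital clock; a scalar v is represented by a firing
frequency f(v) such that the number of spikes inside the learning window
τ_α is exactly ⌊f·τ_α⌋.  One environment transition triggers:

1. reward/penalty encoding — the R neuron fires at f_R (one spike per
   window) on any in-bounds transition, the P neuron at f_P (2^n spikes)
   on failure;
2. the γ population — action-neuron replicas under exploitation-only
   lateral inhibition whose winner fires at γ·f(max_a Q(S′,a)); the
   population's OR is broadcast to all synapses;
3. delay alignment — each action neuron's train is delayed by τ_d, so the
   spikes representing Q(S,A) are still arriving during the first τ_d of
   the next state;
4. local selection — delayed state and delayed action spikes coincide
   (within τ_s) only at the (S,A) synapse and retrigger an
   eligibility-trace pulse of width τ_etw there;
5. gated counting — LTP = (R OR γ) AND α AND ET and
   LTD = (P OR A_dm) AND α AND ET drive the counter one step per spike,
   clamped to [1, 2^n] at every step.

With α-pulse width equal to τ_d (learning rate 1) the counts realize
Q ← R + γ·max_a Q(S′,a) in integer arithmetic.

## Simulation modes

*Spike mode* materializes every train on the clock grid and runs the
gating pipeline.  *Functional mode* generates the same spike ticks in
closed form and steps the counter through the identical interleaved
event sequence, including eligibility-trace coverage.  The two modes are
exactly equivalent — property-tested on random transitions and verified
exhaustively over every (level, next-max, outcome, sojourn) combination
of all four bit-widths during development.  Saturation makes the counter
path-dependent: an increment arriving while the counter sits at its
maximum is lost even if decrements follow, which is why a converged
synapse under reward wobbles by about one level per visit.  Coincident
LTP/LTD ticks cancel (simultaneous up/down pulses leave the counter
unchanged); this convention is applied identically in both modes.

Spike placement uses a phase accumulator: spike i of an f-Hz train sits
at tick ⌊i/(f·dt)⌋.  This guarantees ⌊f·τ⌋ spikes per window for
non-integer f·τ, which rounding the period to the nearest tick does not
(a 1005 Hz train in a 2 ms window would lose its second spike).

The delayed action train's phase at the update window is inherited from
the previous sojourn: the action neuron has been firing for as long as
the (state, action) pair persisted, so k control intervals of history set
the phase (k·20 ms mod 1/f).  This matters: the order in which
potentiation and depression spikes arrive decides what survives at the
clamp bounds, and the sojourn-varying phase keeps those path effects
diverse.  Freezing the phase at a fixed one-interval history makes 3-bit
learning collapse (0/10 runs reach ceiling); with sojourn-dependent phase
it reaches 10/10.

## Parameters

Reference parameterizations per counter width (frequencies in Hz, times
in ms):

| width | f_S | τ_d | τ_α | f_R | f_P | τ_etw |
|------:|----:|----:|----:|----:|----:|------:|
| 2-bit | 10k | 2 | 2 | 505 | 2200 | 17 |
| 3-bit | 10k | 5 | 5 | 205 | 1700 | 14 |
| 4-bit | 20k | 8 | 8 | 127 | 2050 | 11 |
| 5-bit | 40k | 10 | 10 | 105 | 3250 | 9 |

Discount γ = 0.99, learning rate 1 (τ_α = τ_d), ε-greedy exploration
starting at 1 and decaying by 0.7 per episode.  Clock resolution dt is
10 µs, halved to 5 µs when state neurons fire at 20 kHz or faster.  The
coincidence window defaults to τ_s = 1.5/f_S, which makes every delayed
action spike during joint activity a qualifying coincidence.

The level→frequency map is published only for 3-bit (201–1610 Hz,
linear).  The other maps were chosen for stable operation under the
governing calibration ⌊f(k)·τ_α⌋ = k: 2-bit counts c(k) = 1.005k and
4-bit c(k) = 1.005 + 1.003(k−1) follow the 3-bit structure (the largest
slopes that keep the discounted counts ⌊γ·c(k)⌋ at k−1); the 5-bit map
uses c(k) = k + 0.2 because its trace width τ_etw = 9 ms bridges the
slowest interspike gap only if f(1) ≥ ≈111 Hz — the cost is that
⌊γ·c(k)⌋ = k rather than k−1 for k ≤ 19.  Where τ_etw is shorter than an
interspike gap (a 5-bit synapse at level 1), spikes falling into the
uncovered gap are lost — in both simulation modes alike.

## Cart-pole environment

Classic constants: gravity 9.8 m/s², cart 1.0 kg, pole 0.1 kg,
half-length 0.5 m, ±10 N force, 20 ms control interval.  Integration is
explicit Euler with ten 2 ms substeps per control step; with a single
20 ms step the distorted dynamics prevent even conventional real-valued
Q-learning from reaching the ceiling reliably, while at 2 ms results are
insensitive to further refinement (Richardson-style check in the tests).
Episodes start at the origin with a uniform ±0.05 rad pole-angle
perturbation — the standard toolbox reset.  This jitter, the ε-greedy
draws, and winner-take-all tie resolution are the only randomness; from
an exactly-zero start the whole system is deterministic and a greedy
policy can lock permanently into a failing loop once exploration decays.

The quantizer maps θ (degrees) to six right-closed bins with edges
(−12, −0.1, −0.01, 0, 0.01, 0.1, 12) and θ̇ (rad/s) to three bins with
edges ±0.87; x and ẋ are not discretized (they matter only through the
failure bounds).  Units are config flags: the published edges carry
none, and the degree/rad-per-s reading makes the outer θ edge coincide
with the ±12° failure bound.  States are ordered θ-outer/θ̇-inner, 1..18,
with index 19 for failure.  Reward is +1 per in-bounds transition and
−2^bits on failure.

## Policy circuits

Exploitation resolves lateral inhibition as an instantaneous argmax on
drive strength.  Ties among equally driven neurons are decided by the
seeded policy draw (uniform over the tied set): a physical WTA race
between equal-rate neurons is decided by noise, and this noise is
functionally important — counter values concentrate on few levels, ties
are common, and deterministic lowest-index resolution deadlocks learning.
The bare `exploitation_winner` contract (no draw supplied) keeps the
deterministic lowest-index convention.  Exploration suppresses all
action neurons except a uniformly drawn X before inhibition acts; the
exploration and tie-break variates are drawn every control step whether
used or not, so the random stream is identical across modes and
branches.  The next action is selected from the post-update grid
(update-then-select); the γ population reads the pre-update grid, which
is only observable for self-transitions since otherwise its row is never
the updated one.

## Experiments and statistics

An episode scores 1 per 20 ms step balanced, ceiling 200 at 4 s.
Learning curves average scores over non-overlapping 20-episode windows
per run, then across 10 seeded runs (run r uses seed base+r).  "Reaches
the ceiling" is assessed with a −5-point tolerance on the cross-run
window mean, since exploration makes individual runs vary.  The
conventional Q-learning baseline shares the environment, quantizer,
rewards and ε schedule, with a real-valued table initialized at 0 and
updated in the convex form (1−α)Q + α·target — exact at α = 1, so
equal-intent values stay exactly tied and tie randomization is
preserved.  The bit-width comparison feeds each run's final-window mean
(10 values per condition) into a one-way ANOVA (direct SS/df/MS
decomposition, p-value from the F distribution, cross-checked against
scipy) and Tukey HSD pairwise comparisons (scipy's studentized-range
implementation, rank-validated against a Monte-Carlo oracle in the
tests).

With these defaults, functional mode, 10 runs × 100 episodes per
condition: the baseline and the 4- and 5-bit configurations first hold a
ceiling-level window at episode 60, the 3-bit configuration reaches the
ceiling within the budget, and the 2-bit configuration's cross-run mean
stays below the ceiling throughout — reproduced end-to-end by
`scripts/acceptance.py` and the test suite.

## Known limitations

* The eligibility-trace generator is behavioural (pulse logic with
  retriggering), not an analog capacitor–MOSFET model; its buffer
  threshold appears only as a parameter of the pulse conversion.
* LIF neurons are provided and validated against the closed-form
  interspike interval, but the network contract is the frequency map
  itself; membrane constants for the architecture's neurons are not
  specified anywhere and rate coding is exact by construction.
* Non-3-bit rate maps, the tie-resolution noise model, the reset-jitter
  width and the integration substeps are simulator design choices (made
  once, documented above); the learning outcomes are insensitive to the
  first within the stated constraints but genuinely depend on the last
  three.
* The environment is the only task studied; nothing in the architecture
  modules assumes cart-pole, but scaling behaviour (wiring delays, large
  state spaces) is out of scope.
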