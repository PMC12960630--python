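# spikeql

A clock-driven simulator of a **non-von Neumann spiking architecture for
tabular Q-learning**, in which the Q-table lives physically inside the
synapses: each state–action pair's value is an n-bit saturating up/down
counter stored at the synapse that connects the one-hot state neuron to
the action neuron, and the learning logic — eligibility-trace selection,
potentiation/depression gating, counting — runs locally at every synapse
with no memory lookup or address decoding.

The package is for researchers in neuromorphic computing and spiking
reinforcement learning who want to study quantized, in-synapse Q-learning
at spike-level fidelity without building hardware: it provides the
spike-signal primitives, the synapse and network circuits, a
cart-pole benchmark with the architecture's 19-state quantizer, and the
experiment/statistics pipeline for comparing counter bit-widths.

## The model

Tabular Q-learning updates

```
Q(S, A) ← Q(S, A) + α · (R + γ · max_a Q(S′, a) − Q(S, A))
```

The architecture realizes every term as spikes:

* **Rate coding.** Deterministic periodic trains carry scalars as firing
  frequencies calibrated so a window of width τ_α contains exactly
  ⌊f·τ_α⌋ spikes: the reward is 1 count, the penalty 2^bits counts, and a
  synapse at level k drives its action neuron at f(k) with ⌊f(k)·τ_α⌋ = k
  (201–1610 Hz for the 3-bit reference set).
* **max and argmax** are winner-take-all lateral inhibition: among action
  neurons for the ε-greedy policy, and among a parallel γ-population whose
  thresholds scale firing by γ to broadcast γ·max_a Q(S′, a).
* **Temporal alignment.** The selected action's spikes are delayed by τ_d
  so the current Q(S, A) coexists with the next state's maximum for τ_d
  after each transition; a learning-rate pulse of width τ_α ≤ τ_d gates
  the update window.
* **Synapse selection.** Delayed state and action spikes coincide only at
  the (S, A) synapse, where they trigger an eligibility-trace pulse; the
  globally broadcast signals update exactly that counter: LTP spikes =
  (R OR γ) AND α AND ET, LTD spikes = (P OR A_dm) AND α AND ET, one count
  per spike.

Two simulation modes produce **bit-identical** results: `spike` runs the
full waveform pipeline on a 5–10 µs clock; `functional` generates the
contributing spike ticks analytically and steps the counter through the
same interleaved sequence (hundreds of times faster).

The benchmark is cart-pole: ±10 N bang-bang force every 20 ms, failure at
|x| > 2.4 or |θ| > 12°, success after 4 s (score 200), state quantized to
18 in-bounds cells (6 θ-bins × 3 θ̇-bins) plus one failure state — 19
states, 38 synapses.

## Worked example

```python
import numpy as np
from spikeql import preset, run_training, learning_curve, first_ceiling_window

cfg = preset(3)          # the published 3-bit parameter set
scores = np.stack([run_training(cfg, n_episodes=100, seed=s).scores
                   for s in range(10)])
curve = learning_curve(scores)
print(curve.window_ends)  # [ 20  40  60  80 100]
print(curve.mean)         # [ 55.2 179.3 200.  200.  197. ]
print(first_ceiling_window(curve))  # 60
```

The five numbers are the cross-run mean score per 20-episode window: the
agent balances ~1 s on average during the exploratory first window and
reaches the 200-point ceiling (4 s of balance in every episode of every
run) from the third window on.  `examples/` contains narrative scripts
for each capability: rate-coding calibration, a single spike-level
transition with waveform export, the 3-bit training run, and the
bit-width sweep with ANOVA/Tukey statistics.  A thin CLI mirrors them
(`spikeql train`, `spikeql sweep`, `spikeql demo-waveforms`,
`spikeql stats`).

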