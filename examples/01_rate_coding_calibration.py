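"""Rate coding and the count calibration behind the learning rule.

Every quantity in the tabular update — reward, penalty, the stored Q level
and the discounted next-state maximum — is carried as the number of spikes
a periodic train delivers inside the learning-rate window τ_α.  This
script encodes the 3-bit reference frequencies and counts the spikes.
"""

from spikeql import PulseSignal, count_spikes, preset, rate_encode

cfg = preset(3)
gate = PulseSignal.pulse(0.0, cfg.tau_alpha)

print(f"3-bit parameterization, tau_alpha = {cfg.tau_alpha * 1e3:.0f} ms")
for name, freq in [("reward R", cfg.f_reward), ("penalty P", cfg.f_penalty)]:
    train = rate_encode(freq, 0.0, cfg.tau_alpha, cfg.dt)
    print(f"  {name:>10} at {freq:7.1f} Hz -> {count_spikes(train, gate)} spikes")
print("  action neuron rates per Q level:")
for k in (1, 4, 8):
    f = cfg.action_rate(k)
    train = rate_encode(f, 0.0, cfg.tau_alpha, cfg.dt)
    print(f"    level {k}: {f:7.1f} Hz -> {count_spikes(train, gate)} spikes")

# The counts are the update's arithmetic: one reward count, 2^bits penalty
# counts (the most negative value a 3-bit counter can absorb), and exactly
# k spikes for a synapse storing level k — so spike counting realizes
# Q <- Q + (R + gamma*max' - Q) with integer steps.
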