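"""Compare counter bit-widths against conventional Q-learning.

Trains the 2/3/4/5-bit configurations and a real-valued tabular
Q-learning baseline (same quantizer, rewards and ε schedule), then runs a
one-way ANOVA and Tukey HSD over each run's final-window score.
About a minute in functional mode.
"""

from spikeql import run_bitwidth_sweep

result = run_bitwidth_sweep(n_runs=10, n_episodes=100, base_seed=0)

print("final-window mean score per condition:")
for label, curve in result.curves.items():
    print(f"  {label:>10}: {curve.mean[-1]:6.1f}  (per-window: "
          + " ".join(f"{m:.0f}" for m in curve.mean) + ")")

a = result.anova
print(f"\nANOVA: F({a.df_between}, {a.df_within}) = {a.f_value:.4f}, p = {a.p_value:.3g}")
print("Tukey HSD vs the Q-learning baseline:")
for t in result.tukey:
    if "q_learning" in (t.group_a, t.group_b):
        print(f"  {t.group_a} - {t.group_b}: diff {t.mean_diff:7.2f}  "
              f"[{t.ci_low:7.2f}, {t.ci_high:7.2f}]  p = {t.p_value:.4f}")

# Expected pattern: 3-, 4- and 5-bit counters reach the 200 ceiling and do
# not differ significantly from the baseline; the 2-bit counter stays
# below the ceiling and differs significantly.
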