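"""Train the 3-bit architecture on cart-pole and print the learning curve.

Ten seeded runs of 100 episodes, scores averaged per 20-episode window and
across runs — the study's headline experiment.  Takes a few seconds in
functional mode.
"""

import numpy as np

from spikeql import first_ceiling_window, learning_curve, preset, run_training

cfg = preset(3)
scores = np.stack(
    [run_training(cfg, n_episodes=100, seed=s).scores for s in range(10)]
)
curve = learning_curve(scores)

print("3-bit counter, 10 runs x 100 episodes")
print("window end :", "  ".join(f"{e:5d}" for e in curve.window_ends))
print("mean score :", "  ".join(f"{m:5.1f}" for m in curve.mean))
print("run-to-run sd:", " ".join(f"{s:5.1f}" for s in curve.sd))
print("first window at ceiling (>=195):", first_ceiling_window(curve))

# A final-window mean of ~200 means every run balances the pole for the
# full 4 s (score 200) in essentially every late episode; the ceiling is
# reached within the 100-episode budget.
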