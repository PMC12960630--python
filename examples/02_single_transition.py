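"""One spiking transition, both routes: full waveforms vs functional.

Simulates the synaptic update of a single environment step through the
complete pipeline (rate encoding, τ_d delay lines, eligibility trace,
LTP/LTD gating, counter stepping) and checks it against the fast
functional route, then exports the waveform bundle as CSV files.
"""

from spikeql import PolicyDraw, QTableGrid, preset, step_transition
from spikeql.spiking import export_waveforms

cfg = preset(3)

# a mid-training scene: the visited synapse stores level 5, the next
# state's best action stores level 7
for mode in ("spike", "functional"):
    grid = QTableGrid.from_config(cfg)
    grid.set_level(9, 1, 5)
    grid.set_level(2, 1, 7)
    grid.set_level(2, 2, 3)
    grid, action, waveforms = step_transition(
        grid, prev_state=9, taken_action=1, new_state=2, is_failure=False,
        draw=PolicyDraw(explore=False, x=1), config=cfg, mode=mode, capture=True,
    )
    print(f"{mode:>10}: Q(s_9, a_1) 5 -> {grid.level(9, 1)}, next action a_{action}")
    if waveforms:
        index = export_waveforms(waveforms, "waveforms_demo")
        print(f"            wrote {len(waveforms)} signal CSVs to {index.parent}/")

# Both modes land on the same level: the update counts one reward spike
# plus floor(0.99 * f(7) * tau_alpha) = 6 potentiation spikes against
# 5 depression spikes from the delayed action train, moving the counter
# from 5 to the next-state maximum 7.
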