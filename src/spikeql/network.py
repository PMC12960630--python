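"""Full-architecture assembly: neurons, wiring, policy, and one transition.

The architecture maps the tabular Q-learning loop onto a hard-wired spiking
circuit: ``p`` one-hot state neurons, ``q`` action neurons under lateral
inhibition (winner-take-all), an exploration-suppression circuit driven by
the ε-greedy random draw, ``q`` γa neurons computing the discounted
next-state maximum, R/P neurons carrying reward and penalty, per-action
delay lines (τ_d) and the α-pulse generator.  The p×q grid of counter
synapses *is* the Q-table; every learning signal reaches a synapse either
by global broadcast or local wiring, so an update needs no memory lookup.

:func:`step_transition` performs one environment step of spiking
computation — update the (previous state, taken action) synapse, then
select the next action from the post-update grid — in either of two modes:

* ``"functional"``: analytic event generation (fast; bit-exact with spike
  mode);
* ``"spike"``: full waveform-level simulation through the gating pipeline,
  optionally returning the signal bundle for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import synapse as syn
from .spiking import (
    DEFAULT_DT,
    PulseSignal,
    SpikeTrain,
    alpha_pulse,
    count_spikes,
    delay_train,
    gate_and,
    gate_or,
    rate_encode,
)

__all__ = [
    "NetworkConfig",
    "QTableGrid",
    "PolicyDraw",
    "preset",
    "load_config",
    "one_hot_encode",
    "action_rate",
    "exploitation_winner",
    "exploration_gate",
    "gamma_population",
    "select_action",
    "draw_policy",
    "step_transition",
    "UpdateTable",
]

def _default_action_rates(bits: int, tau_alpha: float) -> tuple[float, ...]:
    """Level→frequency map satisfying the count calibration floor(f(k)·τ_α)=k.

    The 3-bit architecture uses the reference linear map 201 Hz (level 1)
    to 1610 Hz (level 8), i.e. spike counts per α window of
    c(k) = 1.005 + 1.00643·(k−1).  The maps for the other widths are not
    published and were chosen here, like the reference parameterizations,
    for stable operation of the architecture:

    * 2-bit — c(k) = 1.005·k, the largest uniform slope that keeps the
      discounted counts ⌊γ·c(k)⌋ at k−1 for every level;
    * 4-bit — the 3-bit structure rescaled, c(k) = 1.005 + s·(k−1) with
      the slope s reaching 2^bits + 0.05 at the top level;
    * 5-bit — c(k) = k + 0.2.  The floor is raised because the 5-bit
      eligibility-trace width (9 ms) is shorter than the interspike gap of
      a 100.5 Hz neuron: the trace persists until the next action spike
      only if the slowest level fires above ≈111 Hz, so c(1) ≥ 1.11; the
      price is that ⌊γ·c(k)⌋ equals k rather than k−1 for k ≤ 19.

    All maps satisfy ⌊f(k)·τ_α⌋ = k exactly.
    """
    n = 2**bits
    if bits == 3:
        lo, hi = 201.0, 1610.0
        return tuple(lo + (k - 1) * (hi - lo) / (n - 1) for k in range(1, n + 1))
    if bits == 2:
        return tuple(1.005 * k / tau_alpha for k in range(1, n + 1))
    if bits == 5:
        return tuple((k + 0.2) / tau_alpha for k in range(1, n + 1))
    slope = (n + 0.05 - 1.005) / (n - 1)
    return tuple((1.005 + slope * (k - 1)) / tau_alpha for k in range(1, n + 1))


@dataclass(frozen=True)
class NetworkConfig:
    """All architecture parameters for one bit-width configuration.

    Defaults are the reference 3-bit parameterization; use :func:`preset`
    for the other bit-widths.  Invariants enforced at construction:

    * τ_α ≤ τ_d (update spikes coexist only for τ_d);
    * ⌊f_P·τ_α⌋ = 2^bits and ⌊f_R·τ_α⌋ = 1 (the penalty is the most
      negative value a counter of this width can absorb, the reward is one
      count);
    * ⌊f(k)·τ_α⌋ = k for every level k of the action-rate map.
    """

    bits: int = 3
    p: int = 19
    q: int = 2
    f_state: float = 10_000.0
    tau_d: float = 0.005
    tau_alpha: float = 0.005
    f_reward: float = 205.0
    f_penalty: float = 1_700.0
    tau_etw: float = 0.014
    tau_s: float | None = None
    gamma: float = 0.99
    alpha_lr: float = 1.0
    epsilon_init: float = 1.0
    epsilon_decay: float = 0.7
    hold_time: float = 0.02
    dt: float = 0.0
    action_rates: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau_s is None:
            # state neurons fire far faster than action neurons, so a window
            # of 1.5 state periods guarantees every A_dm spike coincides
            object.__setattr__(self, "tau_s", 1.5 / self.f_state)
        if not self.dt:
            object.__setattr__(self, "dt", 5e-6 if self.f_state >= 20_000.0 else DEFAULT_DT)
        if not self.action_rates:
            object.__setattr__(self, "action_rates", _default_action_rates(self.bits, self.tau_alpha))
        if self.tau_alpha > self.tau_d + 1e-12:
            raise ValueError("tau_alpha must not exceed tau_d")
        if int(self.f_penalty * self.tau_alpha) != 2**self.bits:
            raise ValueError(
                f"penalty calibration failed: floor({self.f_penalty}*{self.tau_alpha}) "
                f"!= 2^{self.bits}"
            )
        if int(self.f_reward * self.tau_alpha) != 1:
            raise ValueError("reward calibration failed: floor(f_R*tau_alpha) != 1")
        if len(self.action_rates) != 2**self.bits:
            raise ValueError("action-rate map must cover every counter level")
        for k, f in enumerate(self.action_rates, start=1):
            if int(f * self.tau_alpha) != k:
                raise ValueError(f"action-rate calibration failed at level {k}: f={f} Hz")

    @property
    def max_level(self) -> int:
        return 2**self.bits

    def action_rate(self, level: int) -> float:
        """Firing frequency (Hz) of an action neuron at a given Q level."""
        if not 1 <= level <= self.max_level:
            raise ValueError(f"level {level} outside [1, {self.max_level}]")
        return self.action_rates[level - 1]

    def trace_params(self) -> syn.TraceGenParams:
        return syn.TraceGenParams(tau_s=self.tau_s, tau_etw=self.tau_etw)

    # -- config file round-trip (Table-style key names) ----------------

    def to_dict(self) -> dict:
        return {
            "bits": self.bits,
            "p": self.p,
            "q": self.q,
            "s_freq_hz": self.f_state,
            "tau_d_ms": self.tau_d * 1e3,
            "tau_alpha_ms": self.tau_alpha * 1e3,
            "reward_freq_hz": self.f_reward,
            "penalty_freq_hz": self.f_penalty,
            "tau_etw_ms": self.tau_etw * 1e3,
            "gamma": self.gamma,
            "alpha": self.alpha_lr,
            "epsilon_init": self.epsilon_init,
            "epsilon_decay": self.epsilon_decay,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        kwargs = dict(
            bits=int(d["bits"]),
            f_state=float(d["s_freq_hz"]),
            tau_d=float(d["tau_d_ms"]) * 1e-3,
            tau_alpha=float(d["tau_alpha_ms"]) * 1e-3,
            f_reward=float(d["reward_freq_hz"]),
            f_penalty=float(d["penalty_freq_hz"]),
            tau_etw=float(d["tau_etw_ms"]) * 1e-3,
        )
        for key in ("p", "q", "gamma", "epsilon_init", "epsilon_decay", "seed"):
            if key in d and d[key] is not None:
                kwargs[key] = d[key]
        if "alpha" in d and d["alpha"] is not None:
            kwargs["alpha_lr"] = float(d["alpha"])
        return cls(**kwargs)


#: Table-style parameterizations per counter bit-width.
_PRESETS: dict[int, dict] = {
    2: dict(bits=2, f_state=10_000.0, tau_d=0.002, tau_alpha=0.002,
            f_reward=505.0, f_penalty=2_200.0, tau_etw=0.017),
    3: dict(bits=3, f_state=10_000.0, tau_d=0.005, tau_alpha=0.005,
            f_reward=205.0, f_penalty=1_700.0, tau_etw=0.014),
    4: dict(bits=4, f_state=20_000.0, tau_d=0.008, tau_alpha=0.008,
            f_reward=127.0, f_penalty=2_050.0, tau_etw=0.011),
    5: dict(bits=5, f_state=40_000.0, tau_d=0.010, tau_alpha=0.010,
            f_reward=105.0, f_penalty=3_250.0, tau_etw=0.009),
}


def preset(bits: int, **overrides) -> NetworkConfig:
    """Reference configuration for a counter bit-width (2, 3, 4 or 5)."""
    if bits not in _PRESETS:
        raise ValueError(f"no preset for bits={bits}; available: {sorted(_PRESETS)}")
    return NetworkConfig(**{**_PRESETS[bits], **overrides})


def load_config(path: str | Path) -> NetworkConfig:
    """Load a configuration from a YAML key-value file (Table-style names)."""
    with open(path) as fh:
        return NetworkConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Q-table grid
# ---------------------------------------------------------------------------


class QTableGrid:
    """The p×q grid of counter synapses (hard-wired topology).

    State and action indices are 1-based throughout, matching the
    s_1..s_p / a_1..a_q labelling of the architecture.  All synapses are
    initialized at the counter maximum.
    """

    def __init__(self, p: int, q: int, bits: int, init_level: int | None = None):
        self.p = int(p)
        self.q = int(q)
        self.bits = int(bits)
        level = 2**bits if init_level is None else int(init_level)
        if not 1 <= level <= 2**bits:
            raise ValueError("initial level outside counter range")
        self.levels = np.full((self.p, self.q), level, dtype=np.int64)

    @classmethod
    def from_config(cls, config: NetworkConfig) -> "QTableGrid":
        return cls(config.p, config.q, config.bits)

    @property
    def n_synapses(self) -> int:
        return self.p * self.q

    def level(self, n: int, m: int) -> int:
        return int(self.levels[n - 1, m - 1])

    def set_level(self, n: int, m: int, level: int) -> None:
        if not 1 <= level <= 2**self.bits:
            raise ValueError("level outside counter range")
        self.levels[n - 1, m - 1] = level

    def row(self, n: int) -> np.ndarray:
        """Q levels of state s_n across all actions (read-only view)."""
        return self.levels[n - 1]

    def synapse(self, n: int, m: int) -> syn.CounterSynapse:
        return syn.CounterSynapse(level=self.level(n, m), bits=self.bits)

    def copy(self) -> "QTableGrid":
        g = QTableGrid(self.p, self.q, self.bits)
        g.levels = self.levels.copy()
        return g

    def to_frame(self):
        """Snapshot as a pandas DataFrame (rows s_1..s_p, columns a_1..a_q)."""
        import pandas as pd

        return pd.DataFrame(
            self.levels,
            index=[f"s_{n}" for n in range(1, self.p + 1)],
            columns=[f"a_{m}" for m in range(1, self.q + 1)],
        )


# ---------------------------------------------------------------------------
# policy circuits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolicyDraw:
    """One realization of the ε-greedy randomness for a single transition.

    ``explore`` is the ε_π draw (1 with probability ε); ``x`` is the
    uniformly drawn action index used when exploring (1-based);
    ``tiebreak`` resolves winner-take-all ties among equally driven action
    neurons (a physical WTA between neurons firing at identical rates is
    decided by noise, so the simulator draws the resolution uniformly).
    """

    explore: bool
    x: int
    tiebreak: int = 0


def draw_policy(rng: np.random.Generator, epsilon: float, q: int) -> PolicyDraw:
    """Draw (ε_π, X, tie-break) for one transition; every component is
    always consumed so the RNG stream is identical in exploitation and
    exploration and across simulation modes."""
    explore = bool(rng.random() < epsilon)
    x = int(rng.integers(1, q + 1))
    tiebreak = int(rng.integers(0, q))
    return PolicyDraw(explore=explore, x=x, tiebreak=tiebreak)


def one_hot_encode(state_index: int, p: int) -> np.ndarray:
    """One-hot binary vector with element ``state_index`` (1-based) HIGH."""
    if not 1 <= state_index <= p:
        raise ValueError(f"state index {state_index} outside 1..{p}")
    v = np.zeros(p, dtype=np.int64)
    v[state_index - 1] = 1
    return v


def action_rate(q_level: int, config: NetworkConfig) -> float:
    """Firing frequency of an action neuron for a stored Q level."""
    return config.action_rate(q_level)


def exploitation_winner(q_levels_row: np.ndarray, tiebreak: int | None = None) -> int:
    """Winner-take-all over a Q row: index (1-based) of the maximum level.

    Lateral inhibition is resolved as an instantaneous argmax on drive
    strength.  With the default ``tiebreak=None`` ties go to the lowest
    index (first argmax); a policy draw's tie-break integer selects
    uniformly among the tied neurons instead, modelling the noise-decided
    outcome of a WTA between equally driven neurons.
    """
    row = np.asarray(q_levels_row)
    if row.size == 0:
        raise ValueError("empty Q row")
    if tiebreak is None:
        return int(np.argmax(row)) + 1
    tied = np.nonzero(row == row.max())[0]
    return int(tied[tiebreak % tied.size]) + 1


def exploration_gate(draw: PolicyDraw, q: int) -> np.ndarray:
    """Suppression mask from the exploration circuit (1 = suppressed).

    With ε_π = 0 the MUX output is 0 and nothing is suppressed
    (exploitation); with ε_π = 1 every action neuron except the uniformly
    drawn X is suppressed before lateral inhibition acts.
    """
    mask = np.zeros(q, dtype=np.int64)
    if draw.explore:
        mask[:] = 1
        mask[draw.x - 1] = 0
    return mask


def gamma_population(
    q_levels_row_next: np.ndarray,
    config: NetworkConfig,
    window_start: float = 0.0,
) -> SpikeTrain:
    """Combined γ(t) train encoding γ · max_a Q(S', a) for the next state.

    The γa neurons mirror the action neurons' synapses but implement only
    the exploitation lateral inhibition, so the winner is always the true
    row maximum regardless of the exploration draw; its firing rate is the
    action rate scaled by γ (threshold adjustment in hardware).  The OR
    over the population is the winner's train itself.
    """
    winner = exploitation_winner(q_levels_row_next)
    level = int(np.asarray(q_levels_row_next)[winner - 1])
    rate = config.gamma * config.action_rate(level)
    return rate_encode(rate, window_start, config.tau_alpha, config.dt)


def select_action(
    action_trains: list[SpikeTrain],
    window: PulseSignal,
    fallback_row: np.ndarray | None = None,
) -> int:
    """Selection module: the action whose train fires most in the window.

    After WTA/suppression exactly one train is normally active; ties break
    to the lowest index.  If every train is empty the exploitation winner
    of the current Q row is returned as a fallback.
    """
    if not action_trains:
        raise ValueError("need at least one action train")
    counts = np.array([count_spikes(t, window) for t in action_trains])
    if counts.sum() == 0 and fallback_row is not None:
        return exploitation_winner(fallback_row)
    return int(np.argmax(counts)) + 1


# ---------------------------------------------------------------------------
# one environment step of spiking computation
# ---------------------------------------------------------------------------


class UpdateTable:
    """Memoized functional-update results for one configuration.

    The counter update of a transition depends on (current level,
    next-state max level, reward-or-penalty, sojourn length); levels are
    small integers and sojourns repeat heavily, so each combination is
    computed once by :func:`spikeql.synapse.functional_update` and reused.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self._cache: dict[tuple[int, int, bool, int], int] = {}

    def new_level(
        self, q_level: int, next_max: int, is_failure: bool, sojourn_steps: int = 1
    ) -> int:
        key = (q_level, next_max, is_failure, sojourn_steps)
        if key not in self._cache:
            self._cache[key] = syn.functional_update(
                q_level,
                reward_count=0 if is_failure else 1,
                penalty_count=self.config.max_level if is_failure else 0,
                next_max_level=next_max,
                config=self.config,
                sojourn_steps=sojourn_steps,
            )
        return self._cache[key]


def _spike_mode_update(
    grid: QTableGrid,
    prev_state: int,
    taken_action: int,
    new_state: int,
    is_failure: bool,
    config: NetworkConfig,
    sojourn_steps: int = 1,
) -> tuple[int, dict]:
    """Waveform-level computation of one synaptic update.

    Works in transition-local time: tick 0 is the state transition.  The
    state and action trains of the *previous sojourn* (``sojourn_steps``
    control intervals) are encoded on [-sojourn, 0) and pushed through the
    τ_d delay lines; γ(t), R/P and the α pulse are generated at the
    transition.
    """
    dt = config.dt
    hold = config.hold_time * sojourn_steps
    q_level = grid.level(prev_state, taken_action)
    s_prev = rate_encode(config.f_state, -hold, hold, dt)
    s_dn = delay_train(s_prev, config.tau_d)
    a_m = rate_encode(config.action_rate(q_level), -hold, hold, dt)
    a_dm = delay_train(a_m, config.tau_d)
    gamma_t = gamma_population(grid.row(new_state), config)
    r = rate_encode(0.0 if is_failure else config.f_reward, 0.0, config.tau_alpha, dt)
    p_train = rate_encode(config.f_penalty if is_failure else 0.0, 0.0, config.tau_alpha, dt)
    alpha = alpha_pulse(0.0, config.tau_alpha, config.tau_d)
    et = syn.eligibility_trace(s_dn, a_dm, config.trace_params())
    ltp, ltd = syn.ltp_ltd_gate(r, gamma_t, p_train, a_dm, alpha, et)
    new_level = syn.step_counter_events(q_level, config.bits, ltp.ticks, ltd.ticks)
    waveforms = {
        f"S_{prev_state}": s_prev,
        f"S_d{prev_state}": s_dn,
        f"A_{taken_action}": a_m,
        f"A_d{taken_action}": a_dm,
        "gamma": gamma_t,
        "R": r,
        "P": p_train,
        "alpha": alpha,
        f"ET_{prev_state}{taken_action}": et,
        f"LTP_{prev_state}{taken_action}": ltp,
        f"LTD_{prev_state}{taken_action}": ltd,
    }
    return new_level, waveforms


def step_transition(
    grid: QTableGrid,
    prev_state: int,
    taken_action: int,
    new_state: int,
    is_failure: bool,
    draw: PolicyDraw,
    config: NetworkConfig,
    mode: str = "functional",
    table: UpdateTable | None = None,
    capture: bool = False,
    sojourn_steps: int = 1,
) -> tuple[QTableGrid, int, dict]:
    """One environment step of spiking computation.

    Updates exactly the (previous state, taken action) synapse from the
    transition's learning signals (reward or penalty per ``is_failure``,
    γ·max over the new state's pre-update row, the synapse's own delayed
    action spikes), then selects the next action from the post-update grid
    via the exploration circuit and winner-take-all.  ``sojourn_steps`` is
    the number of control intervals the (state, action) pair had persisted
    before this transition; it sets the phase of the delayed action train.
    ``grid`` is mutated in place and also returned.

    Spike and functional modes produce bit-identical grids; spike mode can
    additionally return the waveform bundle (``capture=True``).
    """
    for idx, name in ((prev_state, "prev_state"), (new_state, "new_state")):
        if not 1 <= idx <= config.p:
            raise ValueError(f"{name} {idx} outside 1..{config.p}")
    if not 1 <= taken_action <= config.q:
        raise ValueError(f"action {taken_action} outside 1..{config.q}")

    waveforms: dict = {}
    if mode == "functional":
        if table is None:
            table = UpdateTable(config)
        q_level = grid.level(prev_state, taken_action)
        next_max = int(grid.row(new_state).max())
        new_level = table.new_level(q_level, next_max, is_failure, sojourn_steps)
    elif mode == "spike":
        new_level, waveforms = _spike_mode_update(
            grid, prev_state, taken_action, new_state, is_failure, config, sojourn_steps
        )
        if not capture:
            waveforms = {}
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'spike' or 'functional'")
    grid.set_level(prev_state, taken_action, new_level)

    # -- select the next action (update-then-select) -------------------
    row = grid.row(new_state)
    if mode == "functional":
        next_action = draw.x if draw.explore else exploitation_winner(row, draw.tiebreak)
    else:
        mask = exploration_gate(draw, config.q)
        winner = draw.x if draw.explore else exploitation_winner(row, draw.tiebreak)
        trains = []
        for m in range(1, config.q + 1):
            active = mask[m - 1] == 0 and m == winner
            rate = config.action_rate(int(row[m - 1])) if active else 0.0
            trains.append(rate_encode(rate, 0.0, config.tau_d, config.dt))
        next_action = select_action(
            trains, PulseSignal.pulse(0.0, config.tau_d), fallback_row=row
        )
    return grid, next_action, waveforms
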