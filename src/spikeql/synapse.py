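"""Per-synapse local learning: eligibility traces, LTP/LTD gating, counters.

Each synapse of the architecture stores one Q(s_n, a_m) value in a
saturating n-bit up/down counter and updates it entirely from signals that
are either broadcast globally (reward R, penalty P, the discounted
next-state maximum γ(t), the delayed action spikes A_dm, the learning-rate
pulse α) or generated locally (the eligibility trace ET).  The trace is the
selection mechanism: it goes HIGH only at the synapse whose pre-synaptic
state neuron and post-synaptic action neuron were jointly active before the
transition, so the globally broadcast learning signals update exactly one
counter.

Two routes compute the same update:

* the *spike* route runs the full pipeline
  (rate encoding → delay → :func:`eligibility_trace` →
  :func:`ltp_ltd_gate` → counter stepping);
* the *functional* route (:func:`functional_update`) generates the
  contributing spike ticks analytically and steps the counter through the
  identical interleaved event sequence.

The two are exactly equivalent (property-tested), including the
path-dependent behaviour at counter saturation: an LTP spike arriving
while the counter already sits at its maximum is lost, which is why a
converged Q-value under reward wobbles by about one level per visit — the
same one-step deviations visible in the reference experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .spiking import PulseSignal, SpikeTrain, gate_and, gate_or, periodic_ticks

if TYPE_CHECKING:  # pragma: no cover
    from .network import NetworkConfig

__all__ = [
    "CounterSynapse",
    "TraceGenParams",
    "eligibility_trace",
    "ltp_ltd_gate",
    "counter_update",
    "step_counter_events",
    "transition_event_ticks",
    "functional_update",
]


@dataclass(frozen=True)
class CounterSynapse:
    """A saturating n-bit up/down counter holding one Q(s_n, a_m) level.

    Levels are integers in [1, 2^bits]; the lower bound is 1, matching the
    integer-level convention of the architecture (a 3-bit counter spans
    levels 1..8).
    """

    level: int
    bits: int

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("counter width must be at least 1 bit")
        if not 1 <= self.level <= self.max_level:
            raise ValueError(f"level {self.level} outside [1, {self.max_level}]")

    @property
    def max_level(self) -> int:
        return 2**self.bits


@dataclass(frozen=True)
class TraceGenParams:
    """Behavioural parameters of the eligibility-trace generator.

    tau_s is the pre/post coincidence window: an A_dm spike arriving within
    tau_s after an S_dn spike marks the synapse eligible.  Each qualifying
    coincidence (re)triggers an ET pulse of width tau_etw, so the trace
    stays HIGH while both trains remain active.  v_th and leak_tau describe
    the buffer thresholding of the underlying decaying trace; the
    behavioural model only needs them to define the pulse conversion and
    they default to a generic unit threshold.
    """

    tau_s: float
    tau_etw: float
    v_th: float = 0.5
    leak_tau: float = 0.02

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.tau_etw <= 0:
            raise ValueError("tau_s and tau_etw must be positive")


def eligibility_trace(
    s_dn: SpikeTrain,
    a_dm: SpikeTrain,
    params: TraceGenParams,
) -> PulseSignal:
    """Eligibility-trace pulse from delayed state/action spike coincidence.

    An A_dm spike *qualifies* if some S_dn spike occurred within ``tau_s``
    before it (inclusive of exact coincidence).  The trace is the union of
    ``tau_etw``-wide pulses triggered at each qualifying A_dm spike; since
    tau_etw exceeds the longest action interspike interval, the union is in
    practice one contiguous HIGH interval spanning the joint activity.
    """
    if len(a_dm) == 0 or len(s_dn) == 0:
        return PulseSignal.low()
    if not s_dn.same_clock(a_dm):
        raise ValueError("state and action trains must share the clock")
    dt = a_dm.dt
    tau_s_ticks = max(0, round(params.tau_s / dt))
    s_ticks = s_dn.ticks
    # for each action spike, the most recent state spike at or before it
    idx = np.searchsorted(s_ticks, a_dm.ticks, side="right") - 1
    has_prev = idx >= 0
    gap = np.full(len(a_dm), np.iinfo(np.int64).max, dtype=np.int64)
    gap[has_prev] = a_dm.ticks[has_prev] - s_ticks[idx[has_prev]]
    qualifying = a_dm.ticks[gap <= tau_s_ticks]
    if qualifying.size == 0:
        return PulseSignal.low()
    return PulseSignal.union_of((qualifying * dt).tolist(), params.tau_etw)


def ltp_ltd_gate(
    r: SpikeTrain,
    gamma_a: SpikeTrain,
    p: SpikeTrain,
    a_dm: SpikeTrain,
    alpha: PulseSignal,
    et: PulseSignal,
) -> tuple[SpikeTrain, SpikeTrain]:
    """Group the update signals into potentiation and depression spikes.

    LTP = (R OR γ) AND α AND ET — reward and the discounted next-state
    maximum push the counter up; LTD = (P OR A_dm) AND α AND ET — penalty
    and the synapse's own current Q push it down.  Together the spike
    counts realize the tabular update R + γ·max_a Q(S', a) − Q(S, A) at
    learning rate α (encoded by the α-pulse width).
    """
    ltp = gate_and(gate_and(gate_or(r, gamma_a), alpha), et)
    ltd = gate_and(gate_and(gate_or(p, a_dm), alpha), et)
    return ltp, ltd


# ---------------------------------------------------------------------------
# counter stepping
# ---------------------------------------------------------------------------


def step_counter_events(
    level: int,
    bits: int,
    ltp_ticks: np.ndarray,
    ltd_ticks: np.ndarray,
) -> int:
    """Step a saturating counter through time-ordered up/down spike events.

    Events are applied one at a time in tick order with clamping at every
    step, so transient saturation is path-dependent (an increment at the
    upper bound is lost even if decrements follow).  LTP and LTD spikes on
    the same tick cancel — simultaneous up/down pulses leave the counter
    unchanged.
    """
    ltp_ticks = np.asarray(ltp_ticks, dtype=np.int64)
    ltd_ticks = np.asarray(ltd_ticks, dtype=np.int64)
    common = np.intersect1d(ltp_ticks, ltd_ticks)
    if common.size:
        ltp_ticks = np.setdiff1d(ltp_ticks, common)
        ltd_ticks = np.setdiff1d(ltd_ticks, common)
    events = np.concatenate(
        [
            np.stack([ltp_ticks, np.ones_like(ltp_ticks)], axis=1),
            np.stack([ltd_ticks, -np.ones_like(ltd_ticks)], axis=1),
        ]
    )
    events = events[np.argsort(events[:, 0], kind="stable")]
    hi = 2**bits
    for _, sign in events:
        level = min(hi, max(1, level + int(sign)))
    return level


def counter_update(
    syn: CounterSynapse,
    ltp: int | Sequence[int] | np.ndarray,
    ltd: int | Sequence[int] | np.ndarray,
) -> CounterSynapse:
    """Apply potentiation/depression spikes to a counter synapse.

    ``ltp`` and ``ltd`` may be spike-tick sequences — then events are
    interleaved in time order exactly as the hardware counter would see
    them — or bare counts, in which case all increments are applied before
    all decrements (order only matters at saturation; callers that care
    pass ticks).
    """
    if isinstance(ltp, (int, np.integer)):
        if ltp < 0 or ltd < 0:  # type: ignore[operator]
            raise ValueError("spike counts must be non-negative")
        ltp_ticks = np.arange(ltp, dtype=np.int64)
        ltd_ticks = np.arange(ltp, ltp + int(ltd), dtype=np.int64)
    else:
        ltp_ticks = np.asarray(ltp, dtype=np.int64)
        ltd_ticks = np.asarray(ltd, dtype=np.int64)
    new_level = step_counter_events(syn.level, syn.bits, ltp_ticks, ltd_ticks)
    return replace(syn, level=new_level)


# ---------------------------------------------------------------------------
# functional (closed-form event) route
# ---------------------------------------------------------------------------


def transition_event_ticks(
    q_level: int,
    next_max_level: int,
    rewarded: bool,
    penalized: bool,
    config: "NetworkConfig",
    sojourn_steps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic LTP/LTD spike ticks inside the α window of one transition.

    Ticks are relative to the transition (tick 0).  The γ population, R and
    P neurons phase-reset at the transition; the delayed action train A_dm
    is the continuation of the train the action neuron fired for as long
    as the (state, action) pair persisted — ``sojourn_steps`` control
    intervals of ``config.hold_time`` each — shifted by τ_d, so its phase
    inside the window is inherited from the previous state's sojourn.
    This phase dependence is not a detail: at the counter's clamp bounds
    the order of potentiation and depression spikes decides whether an
    increment survives, and the sojourn-varying phase is what keeps those
    path effects diverse rather than frozen.  OR-gate
    semantics (coincident ticks merge) are applied within each group, and
    the eligibility-trace gating is reproduced exactly: a spike counts only
    if it falls within τ_etw after some A_dm spike (the state train is fast
    enough that every A_dm spike qualifies as a coincidence, so ET coverage
    reduces to the union of τ_etw windows after A_dm spikes).  For most
    parameterizations that union covers the whole α window; where τ_etw is
    shorter than the slowest action interspike gap, spikes landing in the
    uncovered gap are lost — in the spike pipeline and here alike.
    """
    dt = config.dt
    n_alpha = round(config.tau_alpha / dt)
    gamma_rate = config.gamma * config.action_rate(next_max_level)
    ltp_parts = [periodic_ticks(gamma_rate, n_alpha, dt)]
    if rewarded:
        ltp_parts.append(periodic_ticks(config.f_reward, n_alpha, dt))
    ltd_parts = []
    if penalized:
        ltd_parts.append(periodic_ticks(config.f_penalty, n_alpha, dt))
    # A_dm: spikes of the previous sojourn's action train, delayed by tau_d
    if sojourn_steps < 1:
        raise ValueError("sojourn must span at least one control interval")
    n_hold = round(config.hold_time / dt) * sojourn_steps
    n_delay = round(config.tau_d / dt)
    a_dm_all = periodic_ticks(config.action_rate(q_level), n_hold, dt) - n_hold + n_delay
    ltd_parts.append(a_dm_all[(a_dm_all >= 0) & (a_dm_all < n_alpha)])
    ltp = np.union1d(*ltp_parts) if len(ltp_parts) > 1 else ltp_parts[0]
    ltd = np.union1d(*ltd_parts) if len(ltd_parts) > 1 else ltd_parts[0]

    # eligibility-trace coverage: within n_etw ticks after some A_dm spike
    n_etw = round(config.tau_etw / dt)

    def _covered(ticks: np.ndarray) -> np.ndarray:
        if a_dm_all.size == 0:
            return ticks[:0]
        idx = np.searchsorted(a_dm_all, ticks, side="right") - 1
        ok = idx >= 0
        ok[ok] &= (ticks[ok] - a_dm_all[idx[ok]]) < n_etw
        return ticks[ok]

    return _covered(ltp), _covered(ltd)


def functional_update(
    q_level: int,
    reward_count: int,
    penalty_count: int,
    next_max_level: int,
    gamma: float | None = None,
    config: "NetworkConfig | None" = None,
    sojourn_steps: int = 1,
) -> int:
    """Functionally-equivalent counter update for one transition.

    Computes the new level of the (previous state, taken action) synapse
    without simulating waveforms: the contributing spike ticks are
    generated in closed form from the configuration's frequency maps and
    the counter is stepped through the identical interleaved sequence the
    spike pipeline would produce.  Exact equivalence with the spike route
    is the module's central contract.

    ``reward_count``/``penalty_count`` select whether the R and P neurons
    fire (their magnitudes are already encoded in the configured reward and
    penalty frequencies); counts must be 0 or the config's calibrated value.
    """
    if config is None:
        raise ValueError("a NetworkConfig is required")
    if gamma is not None and abs(gamma - config.gamma) > 1e-12:
        config = replace(config, gamma=gamma)
    if reward_count < 0 or penalty_count < 0:
        raise ValueError("spike counts must be non-negative")
    ltp, ltd = transition_event_ticks(
        q_level,
        next_max_level,
        rewarded=reward_count > 0,
        penalized=penalty_count > 0,
        config=config,
        sojourn_steps=sojourn_steps,
    )
    return step_counter_events(q_level, config.bits, ltp, ltd)
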