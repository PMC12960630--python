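"""Discrete-clock spike-signal primitives.

Everything in the simulator runs on a single global clock of resolution
``dt`` (default 10 µs, dropping to 5 µs for configurations whose state
neurons fire at 20 kHz or faster).  Spike times are stored as *integer tick
indices* on that clock, which makes gating, delaying and merging exact —
there is no floating-point coincidence ambiguity anywhere downstream.

The module provides the carriers used by the rest of the package:

* :class:`SpikeTrain` — an ordered set of spike ticks inside a window;
* :class:`PulseSignal` — a binary gate, a union of half-open intervals;
* deterministic periodic rate encoding (:func:`rate_encode`);
* gated spike counting (:func:`count_spikes`), delay lines
  (:func:`delay_train`), digital AND/OR gating (:func:`gate_and`,
  :func:`gate_or`) and the learning-rate pulse (:func:`alpha_pulse`);
* a leaky integrate-and-fire neuron (:func:`lif_step`,
  :func:`simulate_lif_train`).

Rate coding is deterministic and periodic, not Poisson: a train of
frequency *f* started at a (phase-resetting) onset places its first spike
one full period after the onset, so the number of spikes falling in a
window of length τ is exactly ``floor(f·τ)``.  That convention is what
makes the count calibration of the architecture (reward = 1 count,
penalty = 2^bits counts per α window) hold exactly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_DT",
    "SpikeTrain",
    "PulseSignal",
    "LIFParams",
    "LIFState",
    "rate_encode",
    "count_spikes",
    "delay_train",
    "gate_and",
    "gate_or",
    "alpha_pulse",
    "lif_step",
    "simulate_lif_train",
    "period_ticks",
    "periodic_ticks",
    "export_waveforms",
]

DEFAULT_DT = 1e-5
"""Default clock resolution in seconds (10 µs)."""

_TICK_TOL = 1e-6  # relative tolerance when snapping times to the tick grid


def _to_tick(t: float, dt: float, what: str = "time") -> int:
    """Convert a time in seconds to an integer tick, requiring grid alignment."""
    tick = t / dt
    rounded = round(tick)
    if abs(tick - rounded) > _TICK_TOL * max(1.0, abs(tick)):
        raise ValueError(f"{what} {t!r} s is not a multiple of dt={dt!r} s")
    return int(rounded)


def period_ticks(frequency: float, dt: float) -> float:
    """Ideal spike period of a periodic train, in (fractional) ticks."""
    if frequency <= 0:
        raise ValueError("period is undefined for non-positive frequency")
    return 1.0 / (frequency * dt)


def periodic_ticks(frequency: float, n_ticks: int, dt: float) -> np.ndarray:
    """Relative spike ticks of a phase-reset periodic train inside [0, n_ticks).

    Spike i (i ≥ 1) sits at ``floor(i / (f·dt))`` — a phase-accumulator
    placement that quantizes each ideal spike time to the clock grid
    individually.  The period therefore alternates between the floor and
    ceiling of the ideal tick period, and the number of spikes in the
    window is exactly ``floor(f · n_ticks · dt)`` whenever that product is
    not an integer — the property the architecture's count calibration
    relies on.
    """
    if frequency <= 0 or n_ticks <= 0:
        return np.empty(0, dtype=np.int64)
    ideal = period_ticks(frequency, dt)
    n_spikes = int(n_ticks / ideal + 1e-9)  # floor(f * tau)
    i = np.arange(1, n_spikes + 1, dtype=np.float64)
    ticks = np.floor(i * ideal + 1e-6).astype(np.int64)
    return ticks[ticks < n_ticks]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike events on the discrete clock.

    Parameters
    ----------
    dt : float
        Clock resolution in seconds.
    start_tick : int
        First tick of the observation window (may be negative: the
        simulator frequently works in transition-local time where tick 0
        is the state transition).
    n_ticks : int
        Window length in ticks.
    ticks : numpy.ndarray
        Strictly increasing int64 spike ticks, all inside
        ``[start_tick, start_tick + n_ticks)``.
    """

    dt: float
    start_tick: int
    n_ticks: int
    ticks: np.ndarray

    def __post_init__(self) -> None:
        ticks = np.asarray(self.ticks, dtype=np.int64)
        object.__setattr__(self, "ticks", ticks)
        if ticks.size:
            if np.any(np.diff(ticks) <= 0):
                raise ValueError("spike ticks must be strictly increasing")
            if ticks[0] < self.start_tick or ticks[-1] >= self.start_tick + self.n_ticks:
                raise ValueError("spike ticks fall outside the observation window")

    # -- constructors -------------------------------------------------

    @classmethod
    def empty(cls, window_start: float, window_length: float, dt: float = DEFAULT_DT) -> "SpikeTrain":
        start = _to_tick(window_start, dt, "window_start")
        n = _to_tick(window_length, dt, "window_length")
        return cls(dt=dt, start_tick=start, n_ticks=n, ticks=np.empty(0, dtype=np.int64))

    @classmethod
    def from_times(
        cls,
        times: Sequence[float],
        window_start: float,
        window_length: float,
        dt: float = DEFAULT_DT,
    ) -> "SpikeTrain":
        ticks = np.array(sorted(_to_tick(t, dt, "spike time") for t in times), dtype=np.int64)
        start = _to_tick(window_start, dt, "window_start")
        n = _to_tick(window_length, dt, "window_length")
        return cls(dt=dt, start_tick=start, n_ticks=n, ticks=ticks)

    # -- views ---------------------------------------------------------

    @property
    def window_start(self) -> float:
        return self.start_tick * self.dt

    @property
    def window_length(self) -> float:
        return self.n_ticks * self.dt

    @property
    def events(self) -> np.ndarray:
        """Spike times in seconds."""
        return self.ticks * self.dt

    def __len__(self) -> int:
        return int(self.ticks.size)

    def same_clock(self, other: "SpikeTrain") -> bool:
        return math.isclose(self.dt, other.dt, rel_tol=1e-12)


@dataclass(frozen=True)
class PulseSignal:
    """A binary gate: HIGH on a union of disjoint half-open intervals [on, off).

    A single pulse (the usual case — the α pulse, a single eligibility
    window) has one interval; the eligibility-trace generator can produce a
    union of retriggered windows, which collapses back to one interval
    whenever the retrigger gap is shorter than the pulse width.
    """

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for on, off in self.intervals:
            if off < on:
                raise ValueError("pulse interval with negative duration")
            if on < prev_end:
                raise ValueError("pulse intervals must be sorted and disjoint")
            prev_end = off

    @classmethod
    def low(cls) -> "PulseSignal":
        """The always-LOW gate."""
        return cls(intervals=())

    @classmethod
    def pulse(cls, onset: float, duration: float) -> "PulseSignal":
        if duration < 0:
            raise ValueError("pulse duration must be non-negative")
        if duration == 0:
            return cls.low()
        return cls(intervals=((onset, onset + duration),))

    @classmethod
    def union_of(cls, onsets: Iterable[float], width: float) -> "PulseSignal":
        """Union of equal-width pulses, merging overlaps (retrigger semantics)."""
        merged: list[list[float]] = []
        for on in sorted(onsets):
            off = on + width
            if merged and on <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], off)
            else:
                merged.append([on, off])
        return cls(intervals=tuple((a, b) for a, b in merged))

    # -- convenience views matching the single-pulse reading ----------

    @property
    def level(self) -> int:
        return 1 if self.intervals else 0

    @property
    def onset(self) -> float:
        if not self.intervals:
            raise ValueError("always-LOW pulse has no onset")
        return self.intervals[0][0]

    @property
    def duration(self) -> float:
        return sum(off - on for on, off in self.intervals)

    # -- membership ----------------------------------------------------

    def covers(self, t: float) -> bool:
        return any(on <= t < off for on, off in self.intervals)

    def covers_ticks(self, ticks: np.ndarray, dt: float) -> np.ndarray:
        """Boolean mask: which of the given clock ticks fall inside a HIGH interval.

        Interval edges are snapped outward/inward to the tick grid with
        ceil/ceil so a spike exactly on an interval start counts and one
        exactly on the end does not (half-open semantics on the grid).
        """
        mask = np.zeros(len(ticks), dtype=bool)
        for on, off in self.intervals:
            on_tick = math.ceil(on / dt - _TICK_TOL)
            off_tick = math.ceil(off / dt - _TICK_TOL)
            mask |= (ticks >= on_tick) & (ticks < off_tick)
        return mask


# ---------------------------------------------------------------------------
# rate coding and gating
# ---------------------------------------------------------------------------


def rate_encode(
    frequency: float,
    window_start: float,
    window_length: float,
    dt: float = DEFAULT_DT,
) -> SpikeTrain:
    """Deterministic periodic rate encoding of a scalar as a spike train.

    The phase resets at ``window_start``: the first spike occurs one full
    period after the onset, and each subsequent ideal spike time ``i/f`` is
    quantized to the clock grid individually (phase-accumulator placement,
    see :func:`periodic_ticks`).  Consequently a window of length τ
    contains exactly ``floor(frequency · τ)`` spikes whenever f·τ is not an
    integer — which holds for every frequency/window pair the architecture
    calibrates on.

    A zero frequency encodes the value 0 as an empty train.
    """
    if frequency < 0:
        raise ValueError("firing frequency must be non-negative")
    start = _to_tick(window_start, dt, "window_start")
    n = _to_tick(window_length, dt, "window_length")
    if frequency == 0 or n == 0:
        return SpikeTrain(dt=dt, start_tick=start, n_ticks=n, ticks=np.empty(0, dtype=np.int64))
    return SpikeTrain(dt=dt, start_tick=start, n_ticks=n, ticks=start + periodic_ticks(frequency, n, dt))


def count_spikes(train: SpikeTrain, gate: PulseSignal) -> int:
    """Number of spikes that occur while the gate is HIGH."""
    if len(train) == 0:
        return 0
    return int(gate.covers_ticks(train.ticks, train.dt).sum())


def delay_train(train: SpikeTrain, delay: float) -> SpikeTrain:
    """Shift every spike (and the window) by a fixed delay.

    The delay must sit on the clock grid.  Events shifted past the original
    window end are retained — the observation window moves with them, and
    the next processing stage reads whatever portion it needs.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    d = _to_tick(delay, train.dt, "delay")
    return SpikeTrain(
        dt=train.dt,
        start_tick=train.start_tick + d,
        n_ticks=train.n_ticks,
        ticks=train.ticks + d,
    )


def gate_and(train: SpikeTrain, gate: PulseSignal) -> SpikeTrain:
    """Digital AND: keep spikes only where the gate is HIGH."""
    if len(train) == 0:
        return train
    mask = gate.covers_ticks(train.ticks, train.dt)
    return SpikeTrain(
        dt=train.dt,
        start_tick=train.start_tick,
        n_ticks=train.n_ticks,
        ticks=train.ticks[mask],
    )


def gate_or(a: SpikeTrain, b: SpikeTrain) -> SpikeTrain:
    """Digital OR: merge two trains; coincident ticks merge into one spike."""
    if not a.same_clock(b):
        raise ValueError("cannot OR spike trains with different clock resolutions")
    start = min(a.start_tick, b.start_tick)
    end = max(a.start_tick + a.n_ticks, b.start_tick + b.n_ticks)
    ticks = np.union1d(a.ticks, b.ticks)
    return SpikeTrain(dt=a.dt, start_tick=start, n_ticks=end - start, ticks=ticks)


def alpha_pulse(transition_time: float, tau_alpha: float, tau_d: float | None = None) -> PulseSignal:
    """Learning-rate pulse emitted at a state transition.

    The pulse width τ_α encodes the learning rate α (proportionally) and is
    bounded by the delay τ_d, since update-related spikes coexist only for
    τ_d after the transition.
    """
    if tau_d is not None and tau_alpha > tau_d + 1e-12:
        raise ValueError(f"tau_alpha={tau_alpha} exceeds the delay bound tau_d={tau_d}")
    return PulseSignal.pulse(transition_time, tau_alpha)


# ---------------------------------------------------------------------------
# leaky integrate-and-fire
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters.

    The membrane relaxes exponentially toward ``reset`` (which doubles as
    the resting potential) with time constant ``tau_m`` and integrates
    ``gain · input · dt`` per step; crossing ``threshold`` emits a spike
    and resets the membrane.
    """

    tau_m: float
    threshold: float
    reset: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("membrane time constant must be positive")
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed the reset potential")


@dataclass(frozen=True)
class LIFState:
    potential: float = 0.0
    last_spike_time: float = -math.inf


def lif_step(
    state: LIFState,
    params: LIFParams,
    input_current: float,
    dt: float,
    t: float = 0.0,
) -> tuple[LIFState, bool]:
    """Advance a LIF neuron one clock tick; returns (new state, spiked)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    leak = math.exp(-dt / params.tau_m)
    v = params.reset + (state.potential - params.reset) * leak
    v += params.gain * input_current * dt
    if v >= params.threshold:
        return LIFState(potential=params.reset, last_spike_time=t), True
    return LIFState(potential=v, last_spike_time=state.last_spike_time), False


def simulate_lif_train(
    params: LIFParams,
    input_current: float,
    window_start: float,
    window_length: float,
    dt: float = DEFAULT_DT,
) -> SpikeTrain:
    """Drive a LIF neuron with a constant current and record its spikes.

    This is the explicit LIF realization of rate coding.  The architecture's
    contract is the frequency map itself (rate_encode); this routine exists
    to demonstrate that a driven LIF reproduces the closed-form rate
    ``1 / (τ_m · ln(V∞ / (V∞ − θ)))`` of the leaky integrator.
    """
    start = _to_tick(window_start, dt, "window_start")
    n = _to_tick(window_length, dt, "window_length")
    state = LIFState(potential=params.reset)
    ticks = []
    for i in range(n):
        t = (start + i) * dt
        state, spiked = lif_step(state, params, input_current, dt, t)
        if spiked:
            ticks.append(start + i)
    return SpikeTrain(dt=dt, start_tick=start, n_ticks=n, ticks=np.array(ticks, dtype=np.int64))


# ---------------------------------------------------------------------------
# waveform export
# ---------------------------------------------------------------------------


def export_waveforms(
    signals: Mapping[str, SpikeTrain | PulseSignal],
    outdir: str | Path,
) -> Path:
    """Write each signal as a two-column CSV (time_s, value) plus a JSON index.

    Spike trains are written as one row per spike (value 1); pulses as
    rising/falling edge rows.  Returns the path of the index file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index: dict[str, dict] = {}
    for name, sig in signals.items():
        fname = f"{name}.csv"
        with open(outdir / fname, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_s", "value"])
            if isinstance(sig, SpikeTrain):
                for t in sig.events:
                    writer.writerow([f"{t:.9f}", 1])
                index[name] = {"file": fname, "kind": "spike_train", "n_events": len(sig)}
            else:
                for on, off in sig.intervals:
                    writer.writerow([f"{on:.9f}", 1])
                    writer.writerow([f"{off:.9f}", 0])
                index[name] = {"file": fname, "kind": "pulse", "n_intervals": len(sig.intervals)}
    index_path = outdir / "index.json"
    index_path.write_text(json.dumps(index, indent=2))
    return index_path
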