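"""Cart-pole physics, termination rules, and the 19-state quantizer.

The benchmark: a pole hinged on a cart that is pushed with a bang-bang
force of ±10 N every 20 ms.  An episode fails when the cart leaves
±2.4 units or the pole tilts past ±12°, and succeeds after 4 s of balance.

The continuous state (x, ẋ, θ, θ̇) is quantized to 19 discrete states:
x and ẋ each collapse to a single bin, θ to six bins (very fine near
upright), θ̇ to three bins, giving 18 in-bounds cells plus one failure
state s_19.  Bin edges for θ are in degrees and for θ̇ in rad/s — the
published edges carry no units, and this reading makes the outer θ edge
coincide with the ±12° failure bound (both unit choices are overridable
in :class:`QuantizerSpec`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "CartPoleState",
    "PhysicsConstants",
    "QuantizerSpec",
    "EpisodeStatus",
    "initial_state",
    "dynamics_step",
    "check_termination",
    "quantize_state",
    "reward_signal",
    "FAILURE_STATE",
]

FAILURE_STATE = 19


@dataclass(frozen=True)
class CartPoleState:
    """Continuous cart-pole state; θ is stored in radians internally."""

    x: float = 0.0
    x_dot: float = 0.0
    theta: float = 0.0
    theta_dot: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.x, self.x_dot, self.theta, self.theta_dot, self.t)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("cart-pole state must be finite")
        if self.t < 0:
            raise ValueError("elapsed time must be non-negative")

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.theta)


@dataclass(frozen=True)
class PhysicsConstants:
    """Classic cart-pole constants with Euler integration.

    These are the standard published defaults of the toolbox environments
    built on the original pole-balancing formulation: gravity 9.8 m/s²,
    cart 1.0 kg, pole 0.1 kg with half-length 0.5 m, ±10 N force, 20 ms
    control interval.  Integration is explicit Euler with ``substeps``
    sub-intervals per control step (default 10, i.e. a 2 ms integration
    step).  The finer step matters: a single 20 ms Euler step distorts the
    pole dynamics enough to destabilize tabular learning on the coarse
    quantizer, while at 2 ms the control results are insensitive to
    further refinement.

    ``start_jitter`` is the half-width (radians) of the uniform
    perturbation applied to the pole angle at episode reset, as the
    standard toolbox environments do.  It matters more than it looks: from
    an exactly-zero start the dynamics and the quantizer are fully
    deterministic, so once exploration has decayed a greedy policy can
    lock into a failing loop that no further experience escapes.  The
    reset noise keeps episode experience diverse; together with the
    ε-greedy draws and winner-take-all tie resolution it is the task's
    only randomness.
    """

    gravity: float = 9.8
    mass_cart: float = 1.0
    mass_pole: float = 0.1
    half_length: float = 0.5
    force_mag: float = 10.0
    control_interval: float = 0.02
    substeps: int = 10
    start_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.substeps < 1:
            raise ValueError("substeps must be at least 1")

    @property
    def total_mass(self) -> float:
        return self.mass_cart + self.mass_pole

    @property
    def polemass_length(self) -> float:
        return self.mass_pole * self.half_length


def initial_state(jitter: float = 0.0, rng: np.random.Generator | None = None) -> CartPoleState:
    """Episode start: cart at the origin, pole near upright, velocities zero.

    ``jitter`` adds a uniform perturbation in (−jitter, jitter) rad to the
    pole angle, matching the toolbox reset convention; with ``jitter=0``
    the start is the exact unstable equilibrium.
    """
    if jitter:
        if rng is None:
            raise ValueError("jittered initialization needs an rng")
        return CartPoleState(theta=float(rng.uniform(-jitter, jitter)))
    return CartPoleState()


def _accelerations(s: CartPoleState, force: float, c: PhysicsConstants) -> tuple[float, float]:
    """Cart and pole angular accelerations of the standard equations of motion."""
    sin_t, cos_t = math.sin(s.theta), math.cos(s.theta)
    temp = (force + c.polemass_length * s.theta_dot**2 * sin_t) / c.total_mass
    theta_acc = (c.gravity * sin_t - cos_t * temp) / (
        c.half_length * (4.0 / 3.0 - c.mass_pole * cos_t**2 / c.total_mass)
    )
    x_acc = temp - c.polemass_length * theta_acc * cos_t / c.total_mass
    return x_acc, theta_acc


def dynamics_step(state: CartPoleState, force: float, consts: PhysicsConstants) -> CartPoleState:
    """Advance one 20 ms control step under a constant applied force.

    Explicit Euler on the classic cart-pole equations of motion; the
    positions advance with the pre-step velocities, then the velocities
    advance with the computed accelerations.  Deterministic: identical
    inputs give bit-identical outputs.
    """
    h = consts.control_interval / consts.substeps
    x, x_dot, theta, theta_dot = state.x, state.x_dot, state.theta, state.theta_dot
    for _ in range(consts.substeps):
        x_acc, theta_acc = _accelerations(
            CartPoleState(x=x, x_dot=x_dot, theta=theta, theta_dot=theta_dot, t=state.t),
            force,
            consts,
        )
        x += h * x_dot
        theta += h * theta_dot
        x_dot += h * x_acc
        theta_dot += h * theta_acc
    return CartPoleState(
        x=x, x_dot=x_dot, theta=theta, theta_dot=theta_dot, t=state.t + consts.control_interval
    )


class EpisodeStatus(Enum):
    RUNNING = "running"
    FAILED = "failed"
    SUCCEEDED = "succeeded"


def check_termination(
    state: CartPoleState,
    x_limit: float = 2.4,
    theta_limit_deg: float = 12.0,
    time_limit: float = 4.0,
) -> EpisodeStatus:
    """Episode outcome: failure outside the bounds, success after 4 s in them."""
    if abs(state.x) > x_limit or abs(state.theta_deg) > theta_limit_deg:
        return EpisodeStatus.FAILED
    if state.t >= time_limit:
        return EpisodeStatus.SUCCEEDED
    return EpisodeStatus.RUNNING


@dataclass(frozen=True)
class QuantizerSpec:
    """Bin edges of the 19-state quantizer.

    Bins are right-closed, (lo, hi]; interior edges partition each
    variable.  x and ẋ have a single bin each (their edges only matter for
    failure detection, handled separately), θ has six bins and θ̇ three,
    giving 18 in-bounds states ordered θ-outer/θ̇-inner, plus the failure
    state 19.
    """

    theta_edges_deg: tuple[float, ...] = (-12.0, -0.1, -0.01, 0.0, 0.01, 0.1, 12.0)
    theta_dot_edges: tuple[float, ...] = (-math.inf, -0.87, 0.87, math.inf)
    theta_in_degrees: bool = True
    theta_dot_in_rad_per_s: bool = True

    @property
    def n_theta(self) -> int:
        return len(self.theta_edges_deg) - 1

    @property
    def n_theta_dot(self) -> int:
        return len(self.theta_dot_edges) - 1

    @property
    def n_states(self) -> int:
        """In-bounds states plus the failure state."""
        return self.n_theta * self.n_theta_dot + 1


def _bin_index(value: float, interior_edges: np.ndarray) -> int:
    """1-based right-closed bin: number of interior edges strictly below value, plus 1."""
    return int(np.searchsorted(interior_edges, value, side="left")) + 1


def quantize_state(
    state: CartPoleState,
    failed: bool,
    spec: QuantizerSpec = QuantizerSpec(),
) -> int:
    """Map a continuous state to its discrete index 1..19.

    Failure maps to state 19 regardless of the variables; otherwise the
    index is ``(θ_bin − 1) · n_θ̇ + θ̇_bin`` under the canonical ordering
    (θ outer, θ̇ inner), a bijection onto 1..18.
    """
    if failed:
        return FAILURE_STATE
    theta = state.theta_deg if spec.theta_in_degrees else state.theta
    theta_dot = state.theta_dot  # rad/s by default
    theta_bin = _bin_index(theta, np.asarray(spec.theta_edges_deg[1:-1]))
    if not 1 <= theta_bin <= spec.n_theta:
        raise AssertionError(f"in-bounds theta {theta} escaped the quantizer bins")
    td_bin = _bin_index(theta_dot, np.asarray(spec.theta_dot_edges[1:-1]))
    return (theta_bin - 1) * spec.n_theta_dot + td_bin


def reward_signal(new_state_index: int, bits: int = 3) -> int:
    """Reward +1 for any in-bounds state, penalty −2^bits for the failure state.

    The penalty is the most negative value a counter of the given width can
    absorb (−8 for the 3-bit reference configuration).
    """
    if not 1 <= new_state_index <= FAILURE_STATE:
        raise ValueError(f"state index {new_state_index} outside 1..{FAILURE_STATE}")
    if new_state_index == FAILURE_STATE:
        return -(2**bits)
    return 1
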