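"""Episode and run orchestration, learning curves, and the bit-width study.

A *run* is 100 episodes of cart-pole control with one seeded RNG; the
ε-greedy exploration probability starts at 1 and decays by 0.7 per
episode, so early episodes are fully random and the policy is essentially
greedy after roughly twenty.  Each 20 ms control step is one spiking
transition of the architecture.  The score of an episode counts the 20 ms
steps the pole stayed balanced, ceiling 200 (= 4 s).

Performance is summarized the way the reference study reports it: scores
averaged over non-overlapping 20-episode windows, then averaged across 10
independent seeded runs.  The bit-width sweep compares the 2/3/4/5-bit
configurations against conventional real-valued Q-learning with a one-way
ANOVA over per-run summary scores and Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .cartpole import (
    FAILURE_STATE,
    CartPoleState,
    EpisodeStatus,
    PhysicsConstants,
    QuantizerSpec,
    check_termination,
    dynamics_step,
    initial_state,
    quantize_state,
    reward_signal,
)
from .network import (
    NetworkConfig,
    PolicyDraw,
    QTableGrid,
    UpdateTable,
    draw_policy,
    exploitation_winner,
    preset,
    step_transition,
)

__all__ = [
    "EpisodeResult",
    "LearningCurve",
    "AnovaResult",
    "TukeyResult",
    "TrainingResult",
    "epsilon_schedule",
    "run_episode",
    "run_policy_episode",
    "run_training",
    "baseline_q_learning",
    "learning_curve",
    "first_ceiling_window",
    "one_way_anova",
    "tukey_hsd",
    "run_bitwidth_sweep",
    "MAX_SCORE",
    "CEILING_TOLERANCE",
]

MAX_SCORE = 200
#: Stochastic tolerance on "reaches the ceiling": a 20-episode cross-run
#: mean within 5 score points of 200 counts as at ceiling (exploration
#: makes individual runs vary).
CEILING_TOLERANCE = 5.0


@dataclass(frozen=True)
class EpisodeResult:
    """Outcome of one episode: index, score (balanced 20 ms steps), status."""

    episode: int
    score: int
    outcome: EpisodeStatus
    failure_time: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.score <= MAX_SCORE:
            raise ValueError("score outside [0, 200]")


@dataclass(frozen=True)
class LearningCurve:
    """20-episode windowed mean scores, per run and across runs."""

    window: int
    per_run: np.ndarray  # (n_runs, n_windows)
    mean: np.ndarray  # (n_windows,)
    sd: np.ndarray  # (n_windows,)

    @property
    def window_ends(self) -> np.ndarray:
        """Episode index at which each window ends (20, 40, ...)."""
        return (np.arange(self.per_run.shape[1]) + 1) * self.window


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_value: float
    p_value: float


@dataclass(frozen=True)
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float


def epsilon_schedule(episode: int, eps_init: float = 1.0, decay: float = 0.7) -> float:
    """Exploration probability of a 1-based episode: eps_init · decay^(episode−1)."""
    if episode < 1:
        raise ValueError("episodes are 1-based")
    return eps_init * decay ** (episode - 1)


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------


def run_episode(
    grid: QTableGrid,
    config: NetworkConfig,
    consts: PhysicsConstants,
    epsilon: float,
    rng: np.random.Generator,
    mode: str = "functional",
    table: UpdateTable | None = None,
    quantizer: QuantizerSpec = QuantizerSpec(),
    episode_index: int = 1,
    capture: bool = False,
) -> tuple[QTableGrid, EpisodeResult, list[dict]]:
    """Run one cart-pole episode through the spiking architecture.

    Every 20 ms control step applies the current action's force, advances
    the physics, quantizes the new state and performs one spiking
    transition (synapse update + next-action selection).  The score gains
    1 for each step that ends in balance; failure ends the episode after
    the failure transition (which delivers the penalty to the culpable
    synapse), success ends it at 4 s with the maximum score of 200.

    Action 1 pushes with −force_mag, action 2 with +force_mag.  The
    episode starts near upright with the environment's uniform reset
    jitter (``consts.start_jitter``) drawn from ``rng``.
    """
    state = initial_state(consts.start_jitter, rng)
    idx = quantize_state(state, False, quantizer)
    draw = draw_policy(rng, epsilon, config.q)
    action = draw.x if draw.explore else exploitation_winner(grid.row(idx), draw.tiebreak)
    score = 0
    sojourn = 1  # control steps the current (state, action) pair has persisted
    waveforms: list[dict] = []
    forces = np.linspace(-consts.force_mag, consts.force_mag, config.q)
    while True:
        state = dynamics_step(state, float(forces[action - 1]), consts)
        status = check_termination(state)
        failed = status is EpisodeStatus.FAILED
        new_idx = quantize_state(state, failed, quantizer)
        draw = draw_policy(rng, epsilon, config.q)
        grid, next_action, wf = step_transition(
            grid, idx, action, new_idx, failed, draw, config, mode=mode,
            table=table, capture=capture, sojourn_steps=sojourn,
        )
        if capture:
            waveforms.append(wf)
        if failed:
            return grid, EpisodeResult(episode_index, score, status, state.t), waveforms
        sojourn = sojourn + 1 if (new_idx == idx and next_action == action) else 1
        action = next_action
        score += 1
        idx = new_idx
        if status is EpisodeStatus.SUCCEEDED or score >= MAX_SCORE:
            return grid, EpisodeResult(episode_index, score, EpisodeStatus.SUCCEEDED), waveforms


def run_policy_episode(
    policy: Callable[[CartPoleState], float],
    consts: PhysicsConstants = PhysicsConstants(),
) -> EpisodeResult:
    """Score a scripted control policy (state → force), bypassing learning.

    Used to validate the scoring bookkeeping independently of the
    architecture: a policy that balances for the full 4 s scores exactly
    200.  Starts from the exact upright origin (no jitter), so the check
    is fully deterministic.
    """
    state = initial_state()
    score = 0
    while True:
        state = dynamics_step(state, policy(state), consts)
        status = check_termination(state)
        if status is EpisodeStatus.FAILED:
            return EpisodeResult(1, score, status, state.t)
        score += 1
        if status is EpisodeStatus.SUCCEEDED or score >= MAX_SCORE:
            return EpisodeResult(1, score, EpisodeStatus.SUCCEEDED)


@dataclass(frozen=True)
class TrainingResult:
    """Scores and final grid of one training run."""

    scores: np.ndarray  # (n_episodes,)
    outcomes: tuple[EpisodeStatus, ...]
    grid: QTableGrid
    seed: int


def run_training(
    config: NetworkConfig,
    n_episodes: int = 100,
    seed: int = 0,
    mode: str = "functional",
    consts: PhysicsConstants = PhysicsConstants(),
    table: UpdateTable | None = None,
    quantizer: QuantizerSpec = QuantizerSpec(),
) -> TrainingResult:
    """Train one run: sequential episodes sharing the grid, ε decaying per episode.

    Deterministic given (config, seed): the single seeded generator drives
    every ε_π and X draw.
    """
    if n_episodes < 1:
        raise ValueError("need at least one episode")
    rng = np.random.default_rng(seed)
    grid = QTableGrid.from_config(config)
    if table is None and mode == "functional":
        table = UpdateTable(config)
    scores = np.zeros(n_episodes, dtype=np.int64)
    outcomes = []
    for ep in range(1, n_episodes + 1):
        eps = epsilon_schedule(ep, config.epsilon_init, config.epsilon_decay)
        grid, result, _ = run_episode(
            grid, config, consts, eps, rng, mode=mode, table=table,
            quantizer=quantizer, episode_index=ep,
        )
        scores[ep - 1] = result.score
        outcomes.append(result.outcome)
    return TrainingResult(scores=scores, outcomes=tuple(outcomes), grid=grid, seed=seed)


# ---------------------------------------------------------------------------
# conventional Q-learning baseline
# ---------------------------------------------------------------------------


def baseline_q_learning(
    alpha_lr: float = 1.0,
    gamma: float = 0.99,
    n_episodes: int = 100,
    seed: int = 0,
    eps_init: float = 1.0,
    eps_decay: float = 0.7,
    consts: PhysicsConstants = PhysicsConstants(),
    quantizer: QuantizerSpec = QuantizerSpec(),
    penalty_bits: int = 3,
    n_states: int = FAILURE_STATE,
    n_actions: int = 2,
) -> TrainingResult:
    """Conventional tabular Q-learning without bit limitations.

    Same quantizer, rewards (+1 / −2^penalty_bits on failure), ε schedule
    and environment as the spiking architecture, but a real-valued Q table
    updated with Q(S,A) ← Q(S,A) + α(R + γ·max_a Q(S′,a) − Q(S,A)).
    The table starts at zero.
    """
    rng = np.random.default_rng(seed)
    q = np.zeros((n_states, n_actions))
    forces = np.linspace(-consts.force_mag, consts.force_mag, n_actions)
    scores = np.zeros(n_episodes, dtype=np.int64)
    outcomes = []
    for ep in range(1, n_episodes + 1):
        eps = epsilon_schedule(ep, eps_init, eps_decay)
        state = initial_state(consts.start_jitter, rng)
        idx = quantize_state(state, False, quantizer)
        draw = draw_policy(rng, eps, n_actions)
        action = draw.x if draw.explore else exploitation_winner(q[idx - 1], draw.tiebreak)
        score = 0
        while True:
            state = dynamics_step(state, float(forces[action - 1]), consts)
            status = check_termination(state)
            failed = status is EpisodeStatus.FAILED
            new_idx = quantize_state(state, failed, quantizer)
            r = reward_signal(new_idx, penalty_bits)
            target = r + gamma * np.max(q[new_idx - 1])
            # convex form is exact at alpha=1, so equal-intent values stay
            # exactly tied and WTA tie randomization is preserved
            q[idx - 1, action - 1] = (1.0 - alpha_lr) * q[idx - 1, action - 1] + alpha_lr * target
            draw = draw_policy(rng, eps, n_actions)
            action = draw.x if draw.explore else exploitation_winner(q[new_idx - 1], draw.tiebreak)
            if failed:
                break
            score += 1
            idx = new_idx
            if status is EpisodeStatus.SUCCEEDED or score >= MAX_SCORE:
                break
        scores[ep - 1] = score
        outcomes.append(EpisodeStatus.FAILED if failed else EpisodeStatus.SUCCEEDED)
    grid = QTableGrid(n_states, n_actions, bits=penalty_bits)  # placeholder topology
    return TrainingResult(scores=scores, outcomes=tuple(outcomes), grid=grid, seed=seed)


# ---------------------------------------------------------------------------
# learning curves and statistics
# ---------------------------------------------------------------------------


def learning_curve(scores: np.ndarray, window: int = 20) -> LearningCurve:
    """Windowed mean scores per run plus the cross-run mean and SD.

    ``scores`` is (n_runs, n_episodes); a trailing partial window is
    dropped.  The cross-run mean of a window equals the mean of the
    per-run window means (equal run lengths).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n_runs, n_episodes = scores.shape
    n_windows = n_episodes // window
    trimmed = scores[:, : n_windows * window]
    per_run = trimmed.reshape(n_runs, n_windows, window).mean(axis=2)
    return LearningCurve(
        window=window,
        per_run=per_run,
        mean=per_run.mean(axis=0),
        sd=per_run.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(n_windows),
    )


def first_ceiling_window(curve: LearningCurve, tolerance: float = CEILING_TOLERANCE) -> int | None:
    """End episode of the first window whose cross-run mean is at ceiling.

    Returns None if no window reaches ``MAX_SCORE − tolerance``.
    """
    at_ceiling = np.nonzero(curve.mean >= MAX_SCORE - tolerance)[0]
    if at_ceiling.size == 0:
        return None
    return int(curve.window_ends[at_ceiling[0]])


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with the full SS/df/MS decomposition.

    The between/within sums of squares are computed directly (they are the
    reported quantities); the p-value comes from the F distribution.  With
    zero within-group variance and equal means, F is defined as 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two groups of at least two values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_value = 0.0 if ms_between == 0 else np.inf
        p_value = 1.0 if ms_between == 0 else 0.0
    else:
        f_value = ms_between / ms_within
        p_value = float(sps.f.sf(f_value, df_between, df_within))
    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_between + ss_within),
        df_between=df_between,
        df_within=df_within,
        ms_between=float(ms_between),
        ms_within=float(ms_within),
        f_value=float(f_value),
        p_value=p_value,
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha_level: float = 0.05,
) -> list[TukeyResult]:
    """Tukey honestly-significant-difference pairwise comparisons.

    Thin wrapper over the studentized-range procedure (scipy), returning
    per-pair mean differences, the (1−α) simultaneous interval and the
    adjusted p-value.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(len(arrays))]
    res = sps.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1 - alpha_level)
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        out.append(
            TukeyResult(
                group_a=labels[i],
                group_b=labels[j],
                mean_diff=float(res.statistic[i, j]),
                ci_low=float(ci.low[i, j]),
                ci_high=float(ci.high[i, j]),
                p_value=float(res.pvalue[i, j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bit-width sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepResult:
    """Curves and statistics of the bit-width comparison."""

    curves: dict  # label -> LearningCurve
    final_window_scores: dict  # label -> (n_runs,) per-run final-window means
    anova: AnovaResult
    tukey: list[TukeyResult]


def run_bitwidth_sweep(
    bit_widths: Sequence[int] = (2, 3, 4, 5),
    include_baseline: bool = True,
    n_runs: int = 10,
    n_episodes: int = 100,
    base_seed: int = 0,
    mode: str = "functional",
    configs: Sequence[NetworkConfig] | None = None,
) -> SweepResult:
    """Train every bit-width configuration (plus the baseline) over seeded runs.

    Run r of every condition uses seed ``base_seed + r``.  The statistic
    entering ANOVA/Tukey is each run's mean score over the final 20-episode
    window (10 values per condition — the degrees-of-freedom structure of a
    5×10 design).
    """
    if configs is None:
        configs = [preset(b) for b in bit_widths]
    curves: dict[str, LearningCurve] = {}
    finals: dict[str, np.ndarray] = {}
    conditions: list[tuple[str, Callable[[int], TrainingResult]]] = []
    if include_baseline:
        conditions.append(
            ("q_learning", lambda s: baseline_q_learning(n_episodes=n_episodes, seed=s))
        )
    for cfg in configs:
        conditions.append(
            (
                f"{cfg.bits}-bit",
                lambda s, c=cfg: run_training(c, n_episodes=n_episodes, seed=s, mode=mode),
            )
        )
    for label, trainer in conditions:
        scores = np.stack([trainer(base_seed + r).scores for r in range(n_runs)])
        curve = learning_curve(scores)
        curves[label] = curve
        finals[label] = curve.per_run[:, -1]
    anova = one_way_anova(list(finals.values()))
    tukey = tukey_hsd(list(finals.values()), labels=list(finals))
    return SweepResult(curves=curves, final_window_scores=finals, anova=anova, tukey=tukey)
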