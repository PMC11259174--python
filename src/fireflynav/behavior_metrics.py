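"""Behavioral analysis battery.

Psychometric / ROC stopping-accuracy curves, signed radial error via
idealized circular arcs, trajectory length and curvature, reward rate,
test-time TD errors, and the no-generalization counterfactual replay
(recorded training-task actions replayed under novel task dynamics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from fireflynav.task_env import (
    EpisodeRecord,
    PerturbationProfile,
    TaskConfig,
    WorldState,
    step as env_step,
)

__all__ = [
    "RocResult",
    "TrialOutcome",
    "arc_length",
    "classify_shoot",
    "radial_error",
    "psychometric_curve",
    "psychometric_and_roc",
    "default_boundary_grid",
    "trajectory_length",
    "trajectory_curvature",
    "mean_trial_curvature",
    "reward_rate",
    "td_error_eval",
    "no_generalization_replay",
    "trial_outcomes",
]


# ---------------------------------------------------------------------------
# idealized circular arcs and under/overshoot
# ---------------------------------------------------------------------------

def arc_length(x: float, y: float) -> float:
    """Arc length of the circle through the origin (initial heading 90 deg)
    passing through (x, y).

    ``L = 2 r arcsin(sqrt(x^2+y^2) / (2 r))`` with ``r = (x^2+y^2) / (2|x|)``;
    the straight-ahead limit x -> 0 gives L -> |y|.  The formula is even in
    x (mirror symmetry).
    """
    x = float(x)
    y = float(y)
    d2 = x * x + y * y
    if d2 == 0.0:
        raise ValueError("arc length undefined at the origin")
    ax = abs(x)
    d = math.sqrt(d2)
    if ax < 1e-12 * d:
        return abs(y)
    r = d2 / (2.0 * ax)
    # sqrt(d2)/(2r) = |x|/d  <= 1 always
    return 2.0 * r * math.asin(min(1.0, ax / d))


def classify_shoot(stop, target) -> str:
    """"overshoot" if the stop lies farther along its idealized arc than the
    target does along its own; ties count as undershoot."""
    ls = arc_length(stop[0], stop[1])
    lg = arc_length(target[0], target[1])
    return "overshoot" if ls > lg else "undershoot"


def radial_error(stop, target) -> float:
    """Signed radial error: Euclidean stop-target distance, positive for
    overshoot and negative for undershoot."""
    dist = math.hypot(stop[0] - target[0], stop[1] - target[1])
    sign = 1.0 if classify_shoot(stop, target) == "overshoot" else -1.0
    return sign * dist


# ---------------------------------------------------------------------------
# psychometric / ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    boundaries: np.ndarray       # cm
    true_curve: np.ndarray       # fraction "rewarded" at each boundary
    shuffled_curve: np.ndarray
    auc: float


def default_boundary_grid(n: int = 60, lo: float = 5.0,
                          hi: float = 400.0) -> np.ndarray:
    """Log-spaced hypothetical reward-boundary radii."""
    return np.geomspace(lo, hi, n)


def psychometric_curve(distances: np.ndarray,
                       boundaries: np.ndarray) -> np.ndarray:
    """Fraction of trials whose stop-target distance is inside each
    hypothetical boundary."""
    d = np.asarray(distances, dtype=float)[:, None]
    return (d < np.asarray(boundaries)[None, :]).mean(axis=0)


def psychometric_and_roc(stops, targets,
                         boundaries: Optional[np.ndarray] = None,
                         rng: Optional[np.random.Generator] = None) -> RocResult:
    """ROC analysis of stopping accuracy.

    The true psychometric curve uses stop-target distances; the shuffled
    curve permutes targets across trials.  The AUC integrates the parametric
    (shuffled, true) curve by the trapezoid rule with endpoints (0,0), (1,1)
    appended; chance (true == shuffled) gives exactly 0.5.
    """
    stops = np.asarray(stops, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if boundaries is None:
        boundaries = default_boundary_grid()
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size == 0:
        raise ValueError("empty boundary grid")
    rng = rng or np.random.default_rng(0)

    dist_true = np.linalg.norm(stops - targets, axis=1)
    perm = rng.permutation(len(targets))
    dist_shuf = np.linalg.norm(stops - targets[perm], axis=1)

    true_curve = psychometric_curve(dist_true, boundaries)
    shuf_curve = psychometric_curve(dist_shuf, boundaries)

    xs = np.concatenate([[0.0], shuf_curve, [1.0]])
    ys = np.concatenate([[0.0], true_curve, [1.0]])
    order = np.argsort(xs, kind="stable")
    auc = float(np.trapezoid(ys[order], xs[order]))
    return RocResult(boundaries, true_curve, shuf_curve, auc)


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

def trajectory_length(xy: np.ndarray) -> float:
    """Sum of segment lengths of an (N, 2) trajectory."""
    xy = np.asarray(xy, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def trajectory_curvature(xy: np.ndarray, dt: float = 0.1,
                         drop_stationary: bool = True) -> np.ndarray:
    """Per-step unsigned curvature |x'y'' - y'x''| / (x'^2+y'^2)^(3/2).

    Derivatives use first-order one-sided differences at the endpoints and
    second-order central differences inside.  Steps with (near-)zero speed
    have undefined curvature and are dropped (returned array may be shorter).
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points for curvature")
    x, y = xy[:, 0], xy[:, 1]
    xp = np.gradient(x, dt, edge_order=1)
    yp = np.gradient(y, dt, edge_order=1)
    xpp = np.gradient(xp, dt, edge_order=1)
    ypp = np.gradient(yp, dt, edge_order=1)
    speed2 = xp * xp + yp * yp
    ok = speed2 > 1e-12
    if not drop_stationary and not np.all(ok):
        raise ValueError("stationary segment: curvature undefined")
    num = np.abs(xp * ypp - yp * xpp)
    return num[ok] / speed2[ok] ** 1.5


def mean_trial_curvature(xy: np.ndarray, dt: float = 0.1) -> float:
    """Trial-mean curvature after excluding steps above the trial's own 95th
    percentile (outlier rule applied per trial, before averaging)."""
    k = trajectory_curvature(xy, dt)
    if len(k) == 0:
        return float("nan")
    thresh = np.percentile(k, 95)
    return float(np.mean(k[k <= thresh]))


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

@dataclass
class TrialOutcome:
    stop: tuple[float, float]
    target: tuple[float, float]
    radial_error: float          # signed cm
    overshoot: bool
    n_steps: int
    rewarded: bool
    duration: float              # s


def trial_outcomes(episodes: Sequence[EpisodeRecord]) -> list[TrialOutcome]:
    out = []
    for ep in episodes:
        stop = ep.stop_location
        target = ep.target
        err = radial_error(stop, target)
        out.append(TrialOutcome(
            stop=(float(stop[0]), float(stop[1])),
            target=(float(target[0]), float(target[1])),
            radial_error=err,
            overshoot=err > 0,
            n_steps=len(ep),
            rewarded=ep.rewarded,
            duration=ep.duration,
        ))
    return out


def reward_rate(episodes: Sequence[EpisodeRecord]) -> float:
    """Rewarded trials per second of time spent."""
    total_time = sum(ep.duration for ep in episodes)
    if total_time <= 0:
        raise ValueError("zero total duration")
    return sum(int(ep.rewarded) for ep in episodes) / total_time


# ---------------------------------------------------------------------------
# test-time TD error
# ---------------------------------------------------------------------------

def _episode_inputs(episode: EpisodeRecord, agent, config: TaskConfig):
    """Reconstruct the per-step network inputs i_t for a recorded episode.

    For EKF agents the belief sequence is a deterministic function of the
    recorded target, actions, and observations, so it is re-run here.
    """
    from fireflynav.agent_nets import encode_belief, encode_observation
    from fireflynav.belief_filter import EkfTracker, NoiseModel

    if agent.ekf_mode:
        tracker = EkfTracker(NoiseModel.from_config(config), config)
        tracker.reset(tuple(episode.target))
        rows = [encode_belief(tracker.belief, config)]
        for t_idx in range(1, len(episode)):
            tracker.step(episode.actions[t_idx - 1],
                         episode.observations[t_idx, :2])
            rows.append(encode_belief(tracker.belief, config))
        return np.array(rows)
    obs = np.array([encode_observation(o, config)
                    for o in episode.observations])
    prev_a = np.vstack([np.zeros(2), episode.actions[:-1]])
    return np.concatenate([obs, prev_a], axis=1)


def td_error_eval(episode: EpisodeRecord, agent,
                  config: Optional[TaskConfig] = None) -> np.ndarray:
    """Per-step |r_t + (1 - D_t) gamma Q1(i', a') - Q1(i, a)| for a trained
    agent on a recorded episode.

    Only the first critic is used; the next action is the trained actor's
    (no exploration, no target networks).  ``agent`` is any object exposing
    ``actor``, ``critics`` and ``ekf_mode`` (e.g. a
    :class:`~fireflynav.rl_training.TD3Trainer`).
    """
    config = config or episode.config
    gamma = config.gamma
    inputs = _episode_inputs(episode, agent, config)
    actions = episode.actions
    rewards = episode.rewards
    dones = episode.done_flags.astype(float)
    N = len(episode)
    critic = agent.critics[0]

    if agent.ekf_mode:
        q, _ = critic.forward(inputs, actions)
        a_next, _ = agent.actor.forward(inputs)
        q_next_all, _ = critic.forward(inputs, a_next)
        q_next = np.empty(N)
        q_next[:-1] = q_next_all[1:]
        q_next[-1] = 0.0
    else:
        a_state = agent.actor.init_state(1)
        c_state = critic.init_state(1)
        q = np.empty(N)
        q_next = np.zeros(N)
        c_states = []
        a_hats = []
        for t in range(N):
            x = inputs[t:t + 1]
            a_hat, a_state, _ = agent.actor.step(x, a_state)
            a_hats.append(a_hat)
            qt, c_state, _ = critic.step(x, actions[t:t + 1], c_state)
            q[t] = qt[0]
            c_states.append(c_state)
        for t in range(N - 1):
            qn, _, _ = critic.step(inputs[t + 1:t + 2], a_hats[t + 1],
                                   c_states[t])
            q_next[t] = qn[0]
    return np.abs(rewards + (1.0 - dones) * gamma * q_next - q)


# ---------------------------------------------------------------------------
# no-generalization counterfactual replay
# ---------------------------------------------------------------------------

def no_generalization_replay(actions: np.ndarray, target,
                             config: TaskConfig,
                             profile: Optional[PerturbationProfile] = None
                             ) -> np.ndarray:
    """Noise-free rollout of a stored action sequence under a (possibly
    novel) task configuration; returns the (N, 7) state sequence."""
    actions = np.asarray(actions, dtype=float)
    state = WorldState.initial(*target)
    states = [state.as_array()]
    t = 0.0
    for a in actions[:-1]:
        state = env_step(state, a, config, profile=profile, rng=None, t=t)
        t += config.dt
        states.append(state.as_array())
    return np.array(states)
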