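"""Twin-delayed deterministic policy-gradient training.

Two algorithms share one trainer:

* feedforward TD3 on EKF beliefs — one-step transition tuples, batch 256;
* recurrent TD3 — whole equal-length trajectories (batch 16) with
  backpropagation through time, since the networks' beliefs live in their
  hidden states.

Both use twin critics with a min-bootstrap target, slowly-moving target
networks (tau = 0.005), clipped target-action smoothing noise, exploration
noise suppressed below the action threshold so stops stay stops, and a
replay buffer that stores every item together with its mirror image across
the y axis.  Training proceeds in three phases split by validation accuracy
(20% / 80%), with per-phase learning rate, exploration SD, and observation
noise.
"""

from __future__ import annotations

import copy
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from fireflynav._nn import Adam, global_norm_clip
from fireflynav.agent_nets import (
    AgentSpec,
    FeedforwardActor,
    RecurrentActor,
    RecurrentCritic,
    build_actor,
    build_critic,
    encode_belief,
    encode_observation,
    mirror_action,
    mirror_encoded_belief,
    mirror_encoded_observation,
)
from fireflynav.belief_filter import EkfTracker, NoiseModel
from fireflynav.task_env import (
    Observation,
    TaskConfig,
    WorldState,
    observe,
    reward_and_done,
    run_episode,
    sample_target,
    step as env_step,
)

__all__ = [
    "TrainSchedule",
    "OptimizerConfig",
    "ReplayBuffer",
    "explore_action",
    "target_smoothed_action",
    "soft_update",
    "critic_update",
    "actor_update",
    "recurrent_critic_update",
    "recurrent_actor_update",
    "TD3Trainer",
    "train_agent",
    "select_checkpoint",
    "EkfPolicy",
    "RnnPolicy",
    "Checkpoint",
]


@dataclass(frozen=True)
class OptimizerConfig:
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1.5e-4
    weight_decay: float = 0.0


@dataclass(frozen=True)
class TrainSchedule:
    """Three-phase hyperparameter schedule plus update cadences."""

    learning_rates: tuple[float, float, float] = (3e-4, 3e-4, 5e-5)
    sigma_exp: tuple[float, float, float] = (0.8, 0.5, 0.4)
    sigma_o_active: tuple[bool, bool, bool] = (False, True, True)
    phase_thresholds: tuple[float, float] = (0.2, 0.8)
    critic_period: int = 4          # env interactions per critic update
    actor_delay: int = 2            # critic updates per actor update
    tau: float = 0.005
    gamma: float = 0.97
    batch_steps: int = 256          # EKF (step-tuple) mode
    batch_trajectories: int = 16    # recurrent (trajectory) mode
    buffer_steps: int = 1_600_000
    buffer_trajectories: int = 100_000
    trials_after_phase1: int = 10_000
    checkpoint_every: int = 500
    validation_trials: int = 300
    grad_clip: float = 1.0          # recurrent mode only
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def lr(self, phase: int) -> float:
        return self.learning_rates[phase - 1]

    def exploration_sd(self, phase: int) -> float:
        return self.sigma_exp[phase - 1]


class ReplayBuffer:
    """FIFO experience buffer.

    ``mode="steps"`` stores one-step transition tuples ``(i, a, r, i', D)``.
    ``mode="trajectories"`` stores whole trials and samples equal-length
    batches: a trial duration is drawn with probability proportional to its
    bucket occupancy, then trajectories are drawn uniformly within.
    Every ``add`` inserts both the item and its mirror (insertion count 2).
    """

    def __init__(self, mode: str, capacity: int):
        if mode not in ("steps", "trajectories"):
            raise ValueError(f"unknown buffer mode {mode!r}")
        self.mode = mode
        self.capacity = capacity
        self._items: deque = deque()
        self._buckets: dict[int, deque] = {}
        self.n_inserted = 0

    def __len__(self) -> int:
        return len(self._items)

    def _insert(self, item) -> None:
        if len(self._items) >= self.capacity:
            old = self._items.popleft()
            if self.mode == "trajectories":
                self._buckets[len(old["r"])].popleft()
        self._items.append(item)
        if self.mode == "trajectories":
            self._buckets.setdefault(len(item["r"]), deque()).append(item)
        self.n_inserted += 1

    def add(self, item, mirror_item) -> None:
        self._insert(item)
        self._insert(mirror_item)

    def sample_steps(self, batch: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self._items), size=batch)
        items = [self._items[j] for j in idx]
        return tuple(np.stack([it[k] for it in items])
                     for k in ("i", "a", "r", "i_next", "D"))

    def sample_trajectories(self, batch: int, rng: np.random.Generator):
        """Returns dict of arrays with shape (N, batch, ...)."""
        anchor = self._items[int(rng.integers(0, len(self._items)))]
        bucket = self._buckets[len(anchor["r"])]
        idx = rng.integers(0, len(bucket), size=batch)
        trajs = [bucket[j] for j in idx]
        out = {}
        for key in ("i", "a", "r", "D", "i_next"):
            out[key] = np.stack([tr[key] for tr in trajs], axis=1)
        return out


def explore_action(a_hat, sigma_exp: float, a_star: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Add exploration noise and clip, unless the proposed action is a stop
    (both components below the action threshold), which is left untouched."""
    a_hat = np.asarray(a_hat, dtype=float)
    if np.all(np.abs(a_hat) < a_star):
        return a_hat.copy()
    return np.clip(a_hat + rng.normal(0.0, sigma_exp, size=a_hat.shape), -1.0, 1.0)


def target_smoothed_action(a_target, rng: np.random.Generator,
                           noise_sd: float = 0.05,
                           noise_clip: float = 0.1) -> np.ndarray:
    """Target-policy smoothing: add clipped Gaussian noise, clip to [-1, 1]."""
    a_target = np.asarray(a_target, dtype=float)
    noise = np.clip(rng.normal(0.0, noise_sd, size=a_target.shape),
                    -noise_clip, noise_clip)
    return np.clip(a_target + noise, -1.0, 1.0)


def soft_update(online, target, tau: float = 0.005) -> None:
    """Exponential moving average of every parameter: p' <- tau p + (1-tau) p'."""
    for k, p in online.params.items():
        target.params[k][...] = tau * p + (1.0 - tau) * target.params[k]


# ---------------------------------------------------------------------------
# feedforward (EKF) updates
# ---------------------------------------------------------------------------

def critic_update(batch, critics, target_critics, target_actor,
                  optimizers, gamma: float, rng: np.random.Generator) -> float:
    """One twin-critic regression step on a batch of step tuples.

    Returns the mean squared TD loss over both critics.
    """
    i, a, r, i_next, D = batch
    a_next_raw, _ = target_actor.forward(i_next)
    a_next = target_smoothed_action(a_next_raw, rng)
    q1n, _ = target_critics[0].forward(i_next, a_next)
    q2n, _ = target_critics[1].forward(i_next, a_next)
    q_min = np.minimum(q1n, q2n)
    y = r + (1.0 - D) * gamma * q_min
    total = 0.0
    M = len(r)
    for critic, opt in zip(critics, optimizers):
        critic.zero_grad()
        q, ctx = critic.forward(i, a)
        err = q - y
        total += float(np.mean(err ** 2))
        critic.backward(ctx, (2.0 / M) * err)
        opt.step()
    return total / 2.0


def actor_update(batch_inputs, actor, first_critic, optimizer) -> float:
    """Gradient ascent of the first critic's value of the actor's action.

    The critic's weights are left untouched (its gradient accumulators are
    cleared afterwards).  Returns the objective J (mean Q).
    """
    i = batch_inputs
    actor.zero_grad()
    a_hat, actor_ctx = actor.forward(i)
    q, critic_ctx = first_critic.forward(i, a_hat)
    M = len(q)
    # ascend: dJ/dQ = 1/M; minimize -J
    _, da = first_critic.backward(critic_ctx, np.full(M, -1.0 / M))
    actor.backward(actor_ctx, da)
    optimizer.step()
    first_critic.zero_grad()
    return float(np.mean(q))


# ---------------------------------------------------------------------------
# recurrent (trajectory) updates
# ---------------------------------------------------------------------------

def _run_critic_traj(critic: RecurrentCritic, i_seq, a_seq):
    """Forward a critic over a trajectory batch; returns (q (N,M), states
    after each step, contexts)."""
    N, M = i_seq.shape[0], i_seq.shape[1]
    state = critic.init_state(M)
    qs, states, ctxs = [], [], []
    for t in range(N):
        q, state, ctx = critic.step(i_seq[t], a_seq[t], state)
        qs.append(q)
        states.append(state)
        ctxs.append(ctx)
    return np.stack(qs), states, ctxs


def recurrent_critic_update(batch, critics, target_critics, target_actor,
                            optimizers, gamma: float, rng: np.random.Generator,
                            grad_clip: float = 1.0) -> float:
    """Twin-critic regression over a batch of equal-length trajectories.

    The learning target at step t uses the target networks' hidden states
    obtained by running them along the *recorded* inputs and actions, then
    stepping once ahead with the smoothed target action.
    """
    i_seq, a_seq, r_seq, D_seq, i_next_seq = (
        batch["i"], batch["a"], batch["r"], batch["D"], batch["i_next"])
    N, M = r_seq.shape
    if i_seq.ndim != 3:
        raise ValueError("trajectory batch must be (N, M, dim)")

    # hidden states of target nets along the recorded trajectory
    ta_state = target_actor.init_state(M)
    tc_states = [c.init_state(M) for c in target_critics]
    y = np.empty((N, M))
    for t in range(N):
        # one-step-ahead evaluation from the current hidden states
        a_next_raw, _, _ = target_actor.step(i_next_seq[t], ta_state)
        a_next = target_smoothed_action(a_next_raw, rng)
        q_next = []
        for c, st in zip(target_critics, tc_states):
            qn, _, _ = c.step(i_next_seq[t], a_next, st)
            q_next.append(qn)
        y[t] = r_seq[t] + (1.0 - D_seq[t]) * gamma * np.minimum(*q_next)
        # advance target hidden states along the recorded data
        _, ta_state, _ = target_actor.step(i_seq[t], ta_state)
        tc_states = [c.step(i_seq[t], a_seq[t], st)[1]
                     for c, st in zip(target_critics, tc_states)]

    total = 0.0
    for critic, opt in zip(critics, optimizers):
        critic.zero_grad()
        q, _, ctxs = _run_critic_traj(critic, i_seq, a_seq)
        err = q - y
        total += float(np.mean(err ** 2))
        dstate = None
        scale = 2.0 / (N * M)
        for t in range(N - 1, -1, -1):
            _, _, dstate = critic.step_backward(ctxs[t], scale * err[t], dstate)
        global_norm_clip(critic.grads, grad_clip)
        opt.step()
    return total / 2.0


def recurrent_actor_update(batch, actor: RecurrentActor,
                           first_critic: RecurrentCritic, optimizer,
                           grad_clip: float = 1.0) -> float:
    """BPTT gradient ascent of the first critic's value of the actor's
    actions over whole trajectories; critic weights are unchanged."""
    i_seq = batch["i"]
    N, M = i_seq.shape[0], i_seq.shape[1]
    actor.zero_grad()

    a_state = actor.init_state(M)
    a_ctxs, a_hats = [], []
    for t in range(N):
        a_hat, a_state, ctx = actor.step(i_seq[t], a_state)
        a_ctxs.append(ctx)
        a_hats.append(a_hat)
    q, _, c_ctxs = _run_critic_traj(first_critic, i_seq, np.stack(a_hats))

    # backward through the critic to collect per-step action gradients
    da_seq = [None] * N
    dstate = None
    scale = -1.0 / (N * M)        # maximize mean Q
    for t in range(N - 1, -1, -1):
        _, da, dstate = first_critic.step_backward(
            c_ctxs[t], np.full(M, scale), dstate)
        da_seq[t] = da
    # backward through the actor
    dstate = None
    for t in range(N - 1, -1, -1):
        _, dstate = actor.step_backward(a_ctxs[t], da_seq[t], dstate)
    global_norm_clip(actor.grads, grad_clip)
    optimizer.step()
    first_critic.zero_grad()
    return float(np.mean(q))


# ---------------------------------------------------------------------------
# policies (greedy rollout wrappers for validation/testing)
# ---------------------------------------------------------------------------

class EkfPolicy:
    """EKF-belief policy for :func:`fireflynav.task_env.run_episode`.

    The EKF is (re)initialized from the noiseless target observation at
    t = 0.  ``exploration`` optionally adds training-time noise.
    """

    def __init__(self, actor: FeedforwardActor, noise: NoiseModel,
                 config: TaskConfig, freeze_gain: bool = False,
                 exploration_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None):
        self.actor = actor
        self.config = config
        self.tracker = EkfTracker(noise, config, freeze_gain=freeze_gain)
        self.exploration_sd = exploration_sd
        self.rng = rng
        self.prev_action = np.zeros(2)
        self.last_input: Optional[np.ndarray] = None

    def reset(self) -> None:
        self.prev_action = np.zeros(2)
        self.tracker.belief = None
        self.last_input = None

    def __call__(self, obs: Observation, t: float) -> np.ndarray:
        if self.tracker.belief is None:
            self.tracker.reset((obs.o_gx, obs.o_gy))
        else:
            self.tracker.step(self.prev_action, obs)
        i = encode_belief(self.tracker.belief, self.config)
        self.last_input = i
        a = self.actor.act(i)
        if self.exploration_sd > 0:
            a = explore_action(a, self.exploration_sd,
                               self.config.action_threshold, self.rng)
        self.prev_action = a
        return a

    def hidden_snapshot(self) -> dict[str, np.ndarray]:
        return {"belief": self.last_input.copy()}


class RnnPolicy:
    """Recurrent-actor policy; hidden state and previous action reset to
    zeros at trial start."""

    def __init__(self, actor: RecurrentActor, config: TaskConfig,
                 exploration_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None):
        self.actor = actor
        self.config = config
        self.exploration_sd = exploration_sd
        self.rng = rng
        self.state = actor.init_state(1)
        self.prev_action = np.zeros(2)
        self.last_input: Optional[np.ndarray] = None
        self._acts: dict[str, np.ndarray] = {}

    def reset(self) -> None:
        self.state = self.actor.init_state(1)
        self.prev_action = np.zeros(2)
        self.last_input = None
        self._acts = {}

    def __call__(self, obs: Observation, t: float) -> np.ndarray:
        x = np.concatenate([encode_observation(obs.as_array(), self.config),
                            self.prev_action])
        self.last_input = x
        a, self.state, ctx = self.actor.step(x, self.state)
        self._acts = {k: v[0] for k, v in
                      self.actor.stage_activations(ctx).items()}
        a = a[0]
        if self.exploration_sd > 0:
            a = explore_action(a, self.exploration_sd,
                               self.config.action_threshold, self.rng)
        self.prev_action = a
        return a

    def hidden_snapshot(self) -> dict[str, np.ndarray]:
        return dict(self._acts)


# ---------------------------------------------------------------------------
# trainer
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    trial: int
    phase: int
    actor_state: dict
    critic_states: tuple[dict, dict]


@dataclass
class TrainResult:
    checkpoints: list[Checkpoint]
    curve: list[dict]               # per-checkpoint metrics
    spec: AgentSpec
    schedule: TrainSchedule
    trials_run: int
    phase: int

    def curve_table(self):
        import pandas as pd
        return pd.DataFrame(self.curve)


class TD3Trainer:
    """Interaction/update loop for both EKF-TD3 and recurrent TD3.

    One seed governs weight initialization, environment noise, exploration,
    and buffer sampling.
    """

    def __init__(self, spec: AgentSpec, schedule: TrainSchedule,
                 config: TaskConfig, seed: int = 0):
        if (spec.actor_kind == "ekf") != (spec.critic_kind == "ekf"):
            # mixed EKF/recurrent agents (e.g. holistic EKF) are rolled out
            # with the recurrent algorithm; not needed at desk scale
            raise NotImplementedError("mixed EKF/recurrent training not supported")
        self.spec = spec
        self.schedule = schedule
        self.base_config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.ekf_mode = spec.actor_kind == "ekf"

        init_rng = np.random.default_rng(seed)
        self.actor = build_actor(spec, init_rng)
        self.critics = [build_critic(spec, init_rng), build_critic(spec, init_rng)]
        self.target_actor = copy.deepcopy(self.actor)
        self.target_critics = [copy.deepcopy(c) for c in self.critics]

        opt = schedule.optimizer
        self.actor_opt = Adam(self.actor, lr=schedule.lr(1),
                              beta1=opt.beta1, beta2=opt.beta2, eps=opt.eps)
        self.critic_opts = [Adam(c, lr=schedule.lr(1), beta1=opt.beta1,
                                 beta2=opt.beta2, eps=opt.eps)
                            for c in self.critics]

        if self.ekf_mode:
            self.buffer = ReplayBuffer("steps", schedule.buffer_steps)
        else:
            self.buffer = ReplayBuffer("trajectories",
                                       schedule.buffer_trajectories)

        self.phase = 1
        self.env_steps = 0
        self.critic_updates = 0
        self.actor_updates = 0
        self.trials = 0
        self.trials_since_phase1: Optional[int] = None
        self.checkpoints: list[Checkpoint] = []
        self.curve: list[dict] = []

    # -- configuration per phase -------------------------------------------
    def phase_config(self) -> TaskConfig:
        if self.schedule.sigma_o_active[self.phase - 1]:
            return self.base_config
        return self.base_config.replace(alpha_o=0.0)

    def _set_lr(self) -> None:
        lr = self.schedule.lr(self.phase)
        self.actor_opt.lr = lr
        for opt in self.critic_opts:
            opt.lr = lr

    # -- one training trial -------------------------------------------------
    def _maybe_update(self) -> None:
        sched = self.schedule
        if self.env_steps % sched.critic_period != 0:
            return
        batch_size = sched.batch_steps if self.ekf_mode else sched.batch_trajectories
        if len(self.buffer) < max(2 * batch_size, 64):
            return
        if self.ekf_mode:
            batch = self.buffer.sample_steps(batch_size, self.rng)
            critic_update(batch, self.critics, self.target_critics,
                          self.target_actor, self.critic_opts,
                          sched.gamma, self.rng)
        else:
            batch = self.buffer.sample_trajectories(batch_size, self.rng)
            recurrent_critic_update(batch, self.critics, self.target_critics,
                                    self.target_actor, self.critic_opts,
                                    sched.gamma, self.rng, sched.grad_clip)
        self.critic_updates += 1
        if self.critic_updates % sched.actor_delay == 0:
            if self.ekf_mode:
                actor_update(batch[0], self.actor, self.critics[0],
                             self.actor_opt)
            else:
                recurrent_actor_update(batch, self.actor, self.critics[0],
                                       self.actor_opt, sched.grad_clip)
            self.actor_updates += 1
            soft_update(self.actor, self.target_actor, sched.tau)
            for c, tc in zip(self.critics, self.target_critics):
                soft_update(c, tc, sched.tau)

    def _run_training_trial(self) -> None:
        config = self.phase_config()
        sigma_exp = self.schedule.exploration_sd(self.phase)
        a_star = config.action_threshold
        rng = self.rng
        target = sample_target(rng, config)
        state = WorldState.initial(*target)

        if self.ekf_mode:
            tracker = EkfTracker(NoiseModel.from_config(config), config)
            tracker.reset(target)
            i_t = encode_belief(tracker.belief, config)
        else:
            actor_state = self.actor.init_state(1)
            prev_a = np.zeros(2)
            obs0 = observe(state, 0.0, config, rng)
            i_t = np.concatenate([encode_observation(obs0.as_array(), config),
                                  prev_a])
            traj_i, traj_a, traj_r, traj_D = [], [], [], []

        started = False
        t = 0.0
        while True:
            if self.ekf_mode:
                a_hat = self.actor.act(i_t)
            else:
                a_hat_b, actor_state, _ = self.actor.step(i_t, actor_state)
                a_hat = a_hat_b[0]
            a = explore_action(a_hat, sigma_exp, a_star, rng)
            r, D = reward_and_done(state, a, t, config, started)
            started = started or bool(np.any(np.abs(a) > a_star))
            self.env_steps += 1

            if D:
                i_next = i_t.copy()   # unused: bootstrap truncated at D=1
            else:
                state = env_step(state, a, config, rng=rng, t=t)
                t += config.dt
                obs = observe(state, t, config, rng)
                if self.ekf_mode:
                    tracker.step(a, obs)
                    i_next = encode_belief(tracker.belief, config)
                else:
                    i_next = np.concatenate(
                        [encode_observation(obs.as_array(), config), a])

            if self.ekf_mode:
                item = {"i": i_t, "a": a, "r": r, "i_next": i_next,
                        "D": float(D)}
                mirror = {"i": mirror_encoded_belief(i_t),
                          "a": mirror_action(a), "r": r,
                          "i_next": mirror_encoded_belief(i_next),
                          "D": float(D)}
                self.buffer.add(item, mirror)
            else:
                traj_i.append(i_t)
                traj_a.append(a)
                traj_r.append(r)
                traj_D.append(float(D))
                if D:
                    traj_i.append(i_next)   # sentinel for i'_{N-1}

            self._maybe_update()
            if D:
                break
            i_t = i_next

        if not self.ekf_mode:
            i_arr = np.array(traj_i)
            item = {"i": i_arr[:-1], "a": np.array(traj_a),
                    "r": np.array(traj_r), "D": np.array(traj_D),
                    "i_next": i_arr[1:]}
            m_i = mirror_encoded_observation(i_arr)
            m_i[:, 5] *= -1.0   # the efference-copy a_omega channel
            mirror = {"i": m_i[:-1], "a": mirror_action(item["a"]),
                      "r": item["r"].copy(), "D": item["D"].copy(),
                      "i_next": m_i[1:]}
            self.buffer.add(item, mirror)
        self.trials += 1
        if self.trials_since_phase1 is not None:
            self.trials_since_phase1 += 1

    # -- evaluation ---------------------------------------------------------
    def greedy_policy(self, config: Optional[TaskConfig] = None,
                      freeze_gain: bool = False):
        """Greedy rollout policy on ``config`` (defaults to the training
        task).  With ``freeze_gain`` the EKF uses the *training* noise model
        (and hence the training Kalman gain) even if ``config`` differs."""
        config = config or self.base_config
        if self.ekf_mode:
            noise_source = self.base_config if freeze_gain else config
            return EkfPolicy(self.actor, NoiseModel.from_config(noise_source),
                             config, freeze_gain=freeze_gain)
        return RnnPolicy(self.actor, config)

    def validate(self, n_trials: Optional[int] = None,
                 seed: int = 12345) -> dict:
        """Greedy rollouts on the current phase's task; returns fraction
        rewarded, reward rate, and mean TD error."""
        from fireflynav.behavior_metrics import td_error_eval

        n = n_trials or self.schedule.validation_trials
        config = self.phase_config()
        rng = np.random.default_rng(seed)
        policy = self.greedy_policy(config)
        rewarded = 0
        total_time = 0.0
        td_errors = []
        for _ in range(n):
            ep = run_episode(policy, config, rng)
            rewarded += int(ep.rewarded)
            total_time += ep.duration
            td = td_error_eval(ep, self, config=config)
            td_errors.append(float(np.mean(td)))
        return {
            "frac_rewarded": rewarded / n,
            "reward_rate": rewarded / total_time,
            "td_error": float(np.mean(td_errors)),
        }

    # -- main loop ----------------------------------------------------------
    def _checkpoint(self) -> Checkpoint:
        ck = Checkpoint(
            trial=self.trials,
            phase=self.phase,
            actor_state=self.actor.state_dict(),
            critic_states=(self.critics[0].state_dict(),
                           self.critics[1].state_dict()),
        )
        self.checkpoints.append(ck)
        return ck

    def load_checkpoint(self, ck: Checkpoint) -> None:
        self.actor.load_state_dict(ck.actor_state)
        for c, st in zip(self.critics, ck.critic_states):
            c.load_state_dict(st)

    def train(self, max_trials: int = 100_000,
              stop_frac: float = 1.01,
              progress: Optional[Callable[[dict], None]] = None) -> TrainResult:
        """Run until the schedule's post-phase-1 budget (or ``max_trials``)
        is exhausted, validating and checkpointing every 500 trials.
        ``stop_frac`` optionally stops early once validation accuracy
        reaches it (desk-scale shortcut; >1 disables)."""
        sched = self.schedule
        while self.trials < max_trials:
            for _ in range(sched.checkpoint_every):
                self._run_training_trial()
                if (self.trials_since_phase1 is not None
                        and self.trials_since_phase1 >= sched.trials_after_phase1):
                    break
            metrics = self.validate()
            if not np.isfinite(metrics["td_error"]):
                raise RuntimeError(
                    f"training diverged (non-finite TD error) at trial {self.trials}")
            row = {"trial": self.trials, "phase": self.phase, **metrics}
            self.curve.append(row)
            if progress is not None:
                progress(row)
            if self.phase >= 2:
                self._checkpoint()
            acc = metrics["frac_rewarded"]
            if self.phase == 1 and acc >= sched.phase_thresholds[0]:
                self.phase = 2
                self.trials_since_phase1 = 0
                self._set_lr()
                self._checkpoint()
            elif self.phase == 2 and acc >= sched.phase_thresholds[1]:
                self.phase = 3
                self._set_lr()
            if acc >= stop_frac:
                break
            if (self.trials_since_phase1 is not None
                    and self.trials_since_phase1 >= sched.trials_after_phase1):
                break
        return TrainResult(self.checkpoints, self.curve, self.spec,
                           self.schedule, self.trials, self.phase)


def train_agent(spec: AgentSpec, schedule: TrainSchedule, config: TaskConfig,
                seed: int = 0, max_trials: int = 100_000,
                stop_frac: float = 1.01,
                progress: Optional[Callable[[dict], None]] = None
                ) -> tuple[TD3Trainer, TrainResult]:
    """Convenience wrapper: build a trainer, run it, return both."""
    trainer = TD3Trainer(spec, schedule, config, seed=seed)
    result = trainer.train(max_trials=max_trials, stop_frac=stop_frac,
                           progress=progress)
    return trainer, result


def select_checkpoint(checkpoints: Sequence, reward_rates) -> int:
    """Index of the checkpoint with the highest reward rate averaged across
    test sets; ties break to the earliest checkpoint.

    ``reward_rates`` is (n_checkpoints, n_test_sets) or (n_checkpoints,).
    """
    if len(checkpoints) == 0:
        raise ValueError("empty checkpoint list")
    rates = np.atleast_2d(np.asarray(reward_rates, dtype=float))
    if rates.shape[0] == 1 and len(checkpoints) > 1:
        rates = rates.T
    if rates.shape[0] != len(checkpoints):
        raise ValueError("reward-rate table does not match checkpoint list")
    mean_rates = rates.mean(axis=1)
    return int(np.argmax(mean_rates))   # argmax returns the first maximum
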