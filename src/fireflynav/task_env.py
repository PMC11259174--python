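"""POMDP "firefly" navigation simulator.

The environment state is a 7-vector ``[x, y, theta, v, omega, gx, gy]``
(positions in cm, head direction in degrees, velocities in cm/s and deg/s,
target position in cm).  A trial starts at the origin facing 90 deg; a target
is sampled uniformly over an annular sector (100-400 cm, +/-35 deg about
straight ahead) and is observable only during the first 0.3 s.  Dimensionless
joystick actions in [-1, 1]^2 are mapped to velocities by the joystick gain
``G = (200 cm/s, 90 deg/s)``, optionally scaled by a gain multiplier and
offset by a Gaussian-profile perturbation velocity.  Observations carry the
velocities (noisy optic flow) and, while visible, the target.

This module doubles as the synthetic-data generator for every downstream
analysis: :func:`run_episode` rolls out an arbitrary policy and records a
columnar :class:`EpisodeRecord`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "WorldState",
    "JoystickAction",
    "Observation",
    "PerturbationProfile",
    "EpisodeRecord",
    "sample_target",
    "perturbation_velocity",
    "step",
    "observe",
    "reward_and_done",
    "mirror_episode",
    "run_episode",
    "EPISODE_COLUMNS",
]

#: column order for serialized episodes (one row per time step)
EPISODE_COLUMNS = [
    "t", "x", "y", "theta", "v", "omega", "gx", "gy",
    "a_v", "a_omega", "o_v", "o_omega", "o_gx", "o_gy",
    "target_visible", "r", "done",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters; defaults are the training-task values."""

    dt: float = 0.1                      # s
    gain: tuple[float, float] = (200.0, 90.0)   # (cm/s, deg/s) at 1x
    gain_multiplier: float = 1.0         # n >= 1 ("n x gain" task)
    alpha_a: float = 0.2                 # process-noise level, units of n*G
    alpha_o: float = 0.1                 # observation-noise level, units of n*G
    reward_radius: float = 65.0          # d*, cm
    reward_amplitude: float = 10.0
    action_threshold: float = 0.1        # a*
    max_duration: float = 3.4            # s
    target_visible_duration: float = 0.3  # s (inclusive)
    gamma: float = 0.97
    arena_radius: float = 7000.0         # tracked, not enforced
    target_distance_range: tuple[float, float] = (100.0, 400.0)  # cm
    target_angle_range: tuple[float, float] = (55.0, 125.0)      # deg

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if min(self.gain) <= 0:
            raise ValueError(f"gain components must be positive, got {self.gain}")
        if self.gain_multiplier <= 0:
            raise ValueError("gain_multiplier must be positive")

    # -- derived quantities -------------------------------------------------
    @property
    def effective_gain(self) -> np.ndarray:
        """n * G, the action-to-velocity map actually in force."""
        return self.gain_multiplier * np.asarray(self.gain, dtype=float)

    @property
    def sigma_a(self) -> np.ndarray:
        """Process-noise SD sigma_a = alpha_a * n * G, per velocity component."""
        return self.alpha_a * self.effective_gain

    @property
    def sigma_o(self) -> np.ndarray:
        """Observation-noise SD sigma_o = alpha_o * n * G."""
        return self.alpha_o * self.effective_gain

    @property
    def reward_cov(self) -> np.ndarray:
        """Sigma_r = (d*/1.5)^2 * I2 used for the partial (Gaussian) reward."""
        return (self.reward_radius / 1.5) ** 2 * np.eye(2)

    @property
    def max_steps(self) -> int:
        """Number of steps until timeout (the step at t >= max_duration ends)."""
        return int(math.floor(self.max_duration / self.dt + 1e-9)) + 1

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["gain"] = list(d["gain"])
        d["target_distance_range"] = list(d["target_distance_range"])
        d["target_angle_range"] = list(d["target_angle_range"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TaskConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        for key in ("gain", "target_distance_range", "target_angle_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def replace(self, **kwargs) -> "TaskConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class WorldState:
    """The 7-component environment state."""

    x: float
    y: float
    theta: float    # deg, not wrapped
    v: float        # cm/s
    omega: float    # deg/s
    gx: float
    gy: float

    @classmethod
    def initial(cls, gx: float, gy: float) -> "WorldState":
        return cls(0.0, 0.0, 90.0, 0.0, 0.0, gx, gy)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta, self.v, self.omega,
                         self.gx, self.gy])

    @property
    def target(self) -> np.ndarray:
        return np.array([self.gx, self.gy])

    def distance_to_target(self) -> float:
        return math.hypot(self.x - self.gx, self.y - self.gy)


# the action type is a plain length-2 array; this alias documents intent
JoystickAction = np.ndarray


def clip_action(action) -> np.ndarray:
    """Clip both joystick components to [-1, 1]."""
    return np.clip(np.asarray(action, dtype=float), -1.0, 1.0)


@dataclass(frozen=True)
class Observation:
    """Masked noisy observation: optic-flow velocities plus the target while
    visible.  When the target is invisible its components are zero."""

    o_v: float
    o_omega: float
    o_gx: float
    o_gy: float
    target_visible: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.o_v, self.o_omega, self.o_gx, self.o_gy])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([self.o_v, self.o_omega])


@dataclass(frozen=True)
class PerturbationProfile:
    """Gaussian-envelope passive velocity: peak at ``t_p``, SD 0.2 s,
    truncated to the window [t_p - 0.5, t_p + 0.5]."""

    t_p: float
    p_v_peak: float      # cm/s
    p_omega_peak: float  # deg/s

    def velocity(self, t: float) -> np.ndarray:
        return perturbation_velocity(t, self)

    def mirrored(self) -> "PerturbationProfile":
        return PerturbationProfile(self.t_p, self.p_v_peak, -self.p_omega_peak)


def sample_target(rng: np.random.Generator, config: TaskConfig) -> tuple[float, float]:
    """Sample a target uniformly (in 2-D area) over the annular sector.

    The polar angle is uniform on the configured range; the radius is
    ``sqrt(U(r_min^2, r_max^2))`` so the planar density is uniform.
    """
    r_min, r_max = config.target_distance_range
    a_min, a_max = config.target_angle_range
    g_theta = math.radians(rng.uniform(a_min, a_max))
    g_r = math.sqrt(rng.uniform(r_min ** 2, r_max ** 2))
    return g_r * math.cos(g_theta), g_r * math.sin(g_theta)


def perturbation_velocity(t: float, profile: Optional[PerturbationProfile]) -> np.ndarray:
    """Perturbation (p_v, p_omega) at time ``t``; zero outside the 1-s window."""
    if profile is None:
        return np.zeros(2)
    if not (profile.t_p - 0.5 <= t <= profile.t_p + 0.5):
        return np.zeros(2)
    envelope = math.exp(-0.5 * ((t - profile.t_p) / 0.2) ** 2)
    return envelope * np.array([profile.p_v_peak, profile.p_omega_peak])


def step(
    state: WorldState,
    action,
    config: TaskConfig,
    profile: Optional[PerturbationProfile] = None,
    rng: Optional[np.random.Generator] = None,
    t: float = 0.0,
) -> WorldState:
    """One environment transition.

    Position and heading advance with the *current* (pre-update) velocities;
    the new velocities are ``n*G o a + p_t`` plus zero-mean Gaussian process
    noise (SD ``sigma_a``) on the two velocity components only.  ``t`` is the
    trial time of the state being left (the perturbation is indexed by it).
    """
    a = clip_action(action)
    dt = config.dt
    th = math.radians(state.theta)
    x = state.x + dt * state.v * math.cos(th)
    y = state.y + dt * state.v * math.sin(th)
    theta = state.theta + dt * state.omega

    n_gain = config.effective_gain
    p = perturbation_velocity(t, profile)
    vel = n_gain * a + p
    if rng is not None:
        sd = config.sigma_a
        if np.any(sd > 0):
            vel = vel + rng.normal(0.0, 1.0, size=2) * sd
    return WorldState(x, y, theta, float(vel[0]), float(vel[1]),
                      state.gx, state.gy)


def observe(
    state: WorldState,
    t: float,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
) -> Observation:
    """Emit the masked noisy observation of ``state`` at trial time ``t``.

    Velocities are always observed; the target only while ``t`` is within the
    visibility window (inclusive).  Noise applies to the velocity components
    only and is exactly zero at ``t == 0``.
    """
    visible = t <= config.target_visible_duration + 1e-12
    vel = np.array([state.v, state.omega])
    if rng is not None and t > 0:
        sd = config.sigma_o
        if np.any(sd > 0):
            vel = vel + rng.normal(0.0, 1.0, size=2) * sd
    if visible:
        return Observation(float(vel[0]), float(vel[1]), state.gx, state.gy, True)
    return Observation(float(vel[0]), float(vel[1]), 0.0, 0.0, False)


def reward_and_done(
    state: WorldState,
    action,
    t: float,
    config: TaskConfig,
    started: bool,
) -> tuple[float, int]:
    """Evaluate reward r_t and done flag D_t for taking ``action`` in ``state``.

    ``started`` is the per-trial latch: has any earlier action component
    exceeded the action threshold a*?  A stop (both |components| < a* after
    the start) ends the trial and pays r = 10 inside the reward zone or the
    Gaussian partial reward outside it.  A timeout ends the trial with r = 0.
    """
    a = clip_action(action)
    a_star = config.action_threshold
    stopped = started and abs(a[0]) < a_star and abs(a[1]) < a_star
    timeout = t >= config.max_duration - 1e-9
    if stopped:
        d = np.array([state.x - state.gx, state.y - state.gy])
        dist = float(np.linalg.norm(d))
        if dist < config.reward_radius:
            return config.reward_amplitude, 1
        prec = 1.0 / (config.reward_radius / 1.5) ** 2
        return config.reward_amplitude * math.exp(-0.5 * prec * float(d @ d)), 1
    if timeout:
        return 0.0, 1
    return 0.0, 0


@dataclass
class EpisodeRecord:
    """Per-trial sequences, one row per step (all arrays share length N)."""

    states: np.ndarray           # (N, 7)
    observations: np.ndarray     # (N, 4)
    target_visible: np.ndarray   # (N,) bool
    actions: np.ndarray          # (N, 2)
    rewards: np.ndarray          # (N,)
    done_flags: np.ndarray       # (N,) int, 1 only at the final step
    config: TaskConfig = field(default_factory=TaskConfig)
    profile: Optional[PerturbationProfile] = None
    seed: Optional[int] = None
    hidden: Optional[dict] = None   # optional per-module (N, width) snapshots

    def __post_init__(self) -> None:
        n = len(self.states)
        for name in ("observations", "target_visible", "actions",
                     "rewards", "done_flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != states length {n}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def target(self) -> np.ndarray:
        return self.states[0, 5:7].copy()

    @property
    def stop_location(self) -> np.ndarray:
        return self.states[-1, 0:2].copy()

    @property
    def total_reward(self) -> float:
        return float(self.rewards.sum())

    @property
    def rewarded(self) -> bool:
        return self.total_reward >= self.config.reward_amplitude - 1e-9

    @property
    def duration(self) -> float:
        return len(self) * self.config.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.config.dt

    # -- serialization ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.times,
            "x": self.states[:, 0], "y": self.states[:, 1],
            "theta": self.states[:, 2], "v": self.states[:, 3],
            "omega": self.states[:, 4], "gx": self.states[:, 5],
            "gy": self.states[:, 6],
            "a_v": self.actions[:, 0], "a_omega": self.actions[:, 1],
            "o_v": self.observations[:, 0], "o_omega": self.observations[:, 1],
            "o_gx": self.observations[:, 2], "o_gy": self.observations[:, 3],
            "target_visible": self.target_visible.astype(int),
            "r": self.rewards, "done": self.done_flags,
        })
        return df[EPISODE_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: Optional[TaskConfig] = None) -> "EpisodeRecord":
        config = config or TaskConfig()
        states = df[["x", "y", "theta", "v", "omega", "gx", "gy"]].to_numpy(float)
        obs = df[["o_v", "o_omega", "o_gx", "o_gy"]].to_numpy(float)
        return cls(
            states=states,
            observations=obs,
            target_visible=df["target_visible"].to_numpy(bool),
            actions=df[["a_v", "a_omega"]].to_numpy(float),
            rewards=df["r"].to_numpy(float),
            done_flags=df["done"].to_numpy(int),
            config=config,
        )

    @classmethod
    def from_csv(cls, path, config: Optional[TaskConfig] = None) -> "EpisodeRecord":
        return cls.from_dataframe(pd.read_csv(path), config=config)


def episodes_to_hdf5(episodes: Sequence[EpisodeRecord], path) -> None:
    """Write a batch of episodes, one HDF5 group per trial."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, ep in enumerate(episodes):
            grp = fh.create_group(f"trial_{i:06d}")
            df = ep.to_dataframe()
            for col in EPISODE_COLUMNS:
                grp.create_dataset(col, data=df[col].to_numpy())
            grp.attrs["config_yaml"] = ep.config.to_yaml()
            if ep.hidden:
                hgrp = grp.create_group("hidden")
                for name, arr in ep.hidden.items():
                    hgrp.create_dataset(name, data=arr)


def episodes_from_hdf5(path) -> list[EpisodeRecord]:
    import h5py

    episodes = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            grp = fh[key]
            df = pd.DataFrame({col: grp[col][()] for col in EPISODE_COLUMNS})
            cfg = TaskConfig.from_yaml(grp.attrs["config_yaml"])
            ep = EpisodeRecord.from_dataframe(df, config=cfg)
            if "hidden" in grp:
                ep.hidden = {name: grp["hidden"][name][()]
                             for name in grp["hidden"]}
            episodes.append(ep)
    return episodes


def mirror_episode(episode: EpisodeRecord) -> EpisodeRecord:
    """Reflect an episode across the y axis.

    x-like quantities (x, gx, o_gx) and rotational quantities (omega,
    a_omega, o_omega) are negated; theta reflects about 90 deg; forward
    quantities and rewards are unchanged.  The result is dynamically
    consistent with the transition model.
    """
    states = episode.states.copy()
    states[:, 0] *= -1.0             # x
    states[:, 2] = 180.0 - states[:, 2]  # theta
    states[:, 4] *= -1.0             # omega
    states[:, 5] *= -1.0             # gx
    obs = episode.observations.copy()
    obs[:, 1] *= -1.0                # o_omega
    obs[:, 2] *= -1.0                # o_gx
    actions = episode.actions.copy()
    actions[:, 1] *= -1.0
    profile = episode.profile.mirrored() if episode.profile is not None else None
    return EpisodeRecord(
        states=states,
        observations=obs,
        target_visible=episode.target_visible.copy(),
        actions=actions,
        rewards=episode.rewards.copy(),
        done_flags=episode.done_flags.copy(),
        config=episode.config,
        profile=profile,
        seed=episode.seed,
    )


def run_episode(
    policy: Callable,
    config: TaskConfig,
    rng: np.random.Generator,
    profile: Optional[PerturbationProfile] = None,
    target: Optional[tuple[float, float]] = None,
    record_hidden: bool = False,
) -> EpisodeRecord:
    """Roll out ``policy`` for one trial and record every step.

    ``policy`` is a callable ``policy(obs, t) -> action``; if it has a
    ``reset()`` method it is called at trial start (hidden-state contract).
    If ``record_hidden`` and the policy exposes ``hidden_snapshot()``, the
    returned mapping of module name -> activity vector is stored per step.
    """
    if target is None:
        target = sample_target(rng, config)
    state = WorldState.initial(*target)
    if hasattr(policy, "reset"):
        policy.reset()

    states, observations, visible, actions, rewards, dones = [], [], [], [], [], []
    hidden: dict[str, list] = {}
    started = False
    t = 0.0
    while True:
        obs = observe(state, t, config, rng)
        action = clip_action(policy(obs, t))
        r, done = reward_and_done(state, action, t, config, started)
        started = started or bool(np.any(np.abs(action) > config.action_threshold))

        states.append(state.as_array())
        observations.append(obs.as_array())
        visible.append(obs.target_visible)
        actions.append(action)
        rewards.append(r)
        dones.append(done)
        if record_hidden and hasattr(policy, "hidden_snapshot"):
            for name, vec in policy.hidden_snapshot().items():
                hidden.setdefault(name, []).append(np.asarray(vec, float).copy())
        if done:
            break
        state = step(state, action, config, profile, rng, t=t)
        t += config.dt

    return EpisodeRecord(
        states=np.array(states),
        observations=np.array(observations),
        target_visible=np.array(visible, dtype=bool),
        actions=np.array(actions),
        rewards=np.array(rewards),
        done_flags=np.array(dones, dtype=int),
        config=config,
        profile=profile,
        hidden={k: np.array(v) for k, v in hidden.items()} if hidden else None,
    )
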