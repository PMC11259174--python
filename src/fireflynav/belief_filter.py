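"""Model-based belief: extended Kalman filter in target-relative coordinates.

The belief is a Gaussian over the 5-dim state ``[x, y, theta, v, omega]``
where position is expressed relative to the target (the initial mean is
``[-gx0, -gy0, 90, 0, 0]``), so the target enters only through the initial
condition and the observation reduces to the two velocity components.

Because the commanded velocities fully reset the velocity components of the
state, the linearization Jacobian has all-zero velocity rows; the predicted
velocity variances equal the process-noise variances regardless of the prior
covariance, and the Kalman gain is therefore a constant of the two noise
models (see :func:`kalman_gain_schedule`).

A bootstrap particle filter over the same 5-dim relative state is provided
as an independent verification oracle for the exact Bayesian recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fireflynav.task_env import (
    EpisodeRecord,
    Observation,
    TaskConfig,
    clip_action,
)

__all__ = [
    "Belief",
    "NoiseModel",
    "ekf_init",
    "ekf_predict",
    "ekf_update",
    "kalman_gain_schedule",
    "particle_filter_oracle",
    "EkfTracker",
]

EPS = 1e-8   # minimal variance floor / initial covariance scale

# 2x5 observation matrix selecting (v, omega)
H_OBS = np.zeros((2, 5))
H_OBS[0, 3] = 1.0
H_OBS[1, 4] = 1.0

DEG = math.pi / 180.0


@dataclass
class Belief:
    """Gaussian posterior: 5-dim mean (relative coords, cm/deg units) and
    5x5 covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(5)
        self.cov = np.asarray(self.cov, dtype=float).reshape(5, 5)

    def check_psd(self, tol: float = 1e-10) -> None:
        w = np.linalg.eigvalsh(0.5 * (self.cov + self.cov.T))
        if w.min() < -tol:
            raise ValueError(f"covariance not PSD (min eigenvalue {w.min():g})")

    def copy(self) -> "Belief":
        return Belief(self.mean.copy(), self.cov.copy())


@dataclass(frozen=True)
class NoiseModel:
    """Process / observation noise covariances used by the filter.

    ``sigma_a`` and ``sigma_o`` are the per-component SDs (cm/s, deg/s);
    zero entries are floored at sqrt(EPS) variance.
    """

    sigma_a: tuple[float, float]
    sigma_o: tuple[float, float]

    @classmethod
    def from_config(cls, config: TaskConfig) -> "NoiseModel":
        sa = config.sigma_a
        so = config.sigma_o
        return cls((float(sa[0]), float(sa[1])), (float(so[0]), float(so[1])))

    @property
    def Sigma_a(self) -> np.ndarray:
        """5x5 process-noise covariance (velocity entries only)."""
        S = np.zeros((5, 5))
        S[3, 3] = max(self.sigma_a[0] ** 2, EPS)
        S[4, 4] = max(self.sigma_a[1] ** 2, EPS)
        return S

    @property
    def Sigma_o(self) -> np.ndarray:
        """2x2 diagonal observation-noise covariance."""
        return np.diag([max(self.sigma_o[0] ** 2, EPS),
                        max(self.sigma_o[1] ** 2, EPS)])


def ekf_init(target: tuple[float, float]) -> Belief:
    """Initial belief for a trial with target (gx, gy)."""
    gx, gy = target
    mean = np.array([-gx, -gy, 90.0, 0.0, 0.0])
    return Belief(mean, EPS * np.eye(5))


def _f_env5(mean: np.ndarray, action, config: TaskConfig) -> np.ndarray:
    """Noise-free 5-dim transition (first five rows of the full dynamics)."""
    a = clip_action(action)
    dt = config.dt
    th = mean[2] * DEG
    n_gain = config.effective_gain
    return np.array([
        mean[0] + dt * mean[3] * math.cos(th),
        mean[1] + dt * mean[3] * math.sin(th),
        mean[2] + dt * mean[4],
        n_gain[0] * a[0],
        n_gain[1] * a[1],
    ])


def _jacobian(mean: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Linearization of the 5-dim transition at ``mean``.

    Rows 4-5 are all zero: the commanded velocity fully resets the state's
    velocity components.  The heading is stored in degrees, so the
    d(position)/d(theta) entries carry the deg->rad factor.
    """
    dt = config.dt
    th = mean[2] * DEG
    v = mean[3]
    A = np.zeros((5, 5))
    A[0, 0] = 1.0
    A[0, 2] = -v * dt * math.sin(th) * DEG
    A[0, 3] = dt * math.cos(th)
    A[1, 1] = 1.0
    A[1, 2] = v * dt * math.cos(th) * DEG
    A[1, 3] = dt * math.sin(th)
    A[2, 2] = 1.0
    A[2, 4] = dt
    return A


def ekf_predict(
    belief: Belief,
    action,
    noise: NoiseModel,
    config: TaskConfig,
) -> Belief:
    """Prediction step: propagate mean through the noise-free dynamics and
    covariance through the Jacobian plus process noise."""
    belief.check_psd()
    mean = _f_env5(belief.mean, action, config)
    A = _jacobian(belief.mean, config)
    cov = A @ belief.cov @ A.T + noise.Sigma_a
    cov = 0.5 * (cov + cov.T)
    return Belief(mean, cov)


def ekf_update(belief_pred: Belief, obs, noise: NoiseModel,
               gain: np.ndarray | None = None) -> Belief:
    """Measurement update with the 2-dim velocity observation.

    ``obs`` may be an :class:`~fireflynav.task_env.Observation` (target rows
    ignored) or a length-2 array.  If ``gain`` is given (a frozen 5x2 Kalman
    gain) it is used instead of the gain computed from ``belief_pred``.
    """
    if isinstance(obs, Observation):
        o = obs.velocities
    else:
        o = np.asarray(obs, dtype=float).reshape(-1)[:2]
    P = belief_pred.cov
    if gain is None:
        S = H_OBS @ P @ H_OBS.T + noise.Sigma_o
        try:
            gain = P @ H_OBS.T @ np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:   # pragma: no cover - eps floor
            raise ValueError("singular innovation covariance") from exc
    innovation = o - H_OBS @ belief_pred.mean
    mean = belief_pred.mean + gain @ innovation
    cov = (np.eye(5) - gain @ H_OBS) @ P
    cov = 0.5 * (cov + cov.T)
    return Belief(mean, cov)


def kalman_gain_schedule(noise: NoiseModel) -> np.ndarray:
    """The constant one-step Kalman gain (5x2) implied by the zero-row
    velocity Jacobian: nonzero only in the velocity rows, where each entry is
    sigma_a^2 / (sigma_a^2 + sigma_o^2) for its component."""
    Sa = noise.Sigma_a
    So = noise.Sigma_o
    K = np.zeros((5, 2))
    K[3, 0] = Sa[3, 3] / (Sa[3, 3] + So[0, 0])
    K[4, 1] = Sa[4, 4] / (Sa[4, 4] + So[1, 1])
    return K


class EkfTracker:
    """Stateful convenience wrapper running the EKF along a trial.

    ``freeze_gain`` pins the Kalman gain to the value implied by ``noise``
    (the training-time noise model) even if the environment is later run
    with different noise levels.
    """

    def __init__(self, noise: NoiseModel, config: TaskConfig,
                 freeze_gain: bool = False):
        self.noise = noise
        self.config = config
        self.frozen_gain = kalman_gain_schedule(noise) if freeze_gain else None
        self.belief: Belief | None = None

    def reset(self, target: tuple[float, float]) -> Belief:
        self.belief = ekf_init(target)
        return self.belief

    def step(self, action, obs) -> Belief:
        """Predict with ``action`` then update with the next observation."""
        if self.belief is None:
            raise RuntimeError("EkfTracker.reset() must be called first")
        pred = ekf_predict(self.belief, action, self.noise, self.config)
        self.belief = ekf_update(pred, obs, self.noise, gain=self.frozen_gain)
        return self.belief


def _pf_transition(particles: np.ndarray, action, config: TaskConfig,
                   noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Vectorized exact transition for the particle cloud (n, 5)."""
    a = clip_action(action)
    dt = config.dt
    th = particles[:, 2] * DEG
    out = np.empty_like(particles)
    out[:, 0] = particles[:, 0] + dt * particles[:, 3] * np.cos(th)
    out[:, 1] = particles[:, 1] + dt * particles[:, 3] * np.sin(th)
    out[:, 2] = particles[:, 2] + dt * particles[:, 4]
    n_gain = config.effective_gain
    sa = np.sqrt([noise.Sigma_a[3, 3], noise.Sigma_a[4, 4]])
    vel = n_gain * a + rng.normal(size=(len(particles), 2)) * sa
    out[:, 3] = vel[:, 0]
    out[:, 4] = vel[:, 1]
    return out


def particle_filter_oracle(
    episode: EpisodeRecord,
    noise: NoiseModel,
    n_particles: int = 100_000,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Bootstrap particle filter over the 5-dim relative state.

    Returns one (mean, covariance) pair per step of ``episode``.  Raises if
    the effective sample size collapses below 10 (degeneracy).
    """
    rng = rng or np.random.default_rng(0)
    config = episode.config
    gx, gy = episode.target
    so = np.sqrt([noise.Sigma_o[0, 0], noise.Sigma_o[1, 1]])

    # initial cloud around the exact initial relative state
    init = np.array([-gx, -gy, 90.0, 0.0, 0.0])
    particles = init + rng.normal(size=(n_particles, 5)) * math.sqrt(EPS)
    weights = np.full(n_particles, 1.0 / n_particles)

    moments: list[tuple[np.ndarray, np.ndarray]] = []
    mean = np.average(particles, axis=0, weights=weights)
    cov = np.cov(particles.T, aweights=weights, bias=True)
    moments.append((mean, cov))

    for t_idx in range(1, len(episode)):
        action = episode.actions[t_idx - 1]
        particles = _pf_transition(particles, action, config, noise, rng)
        o = episode.observations[t_idx, :2]
        z = (o - particles[:, 3:5]) / so
        logw = -0.5 * np.sum(z * z, axis=1)
        logw -= logw.max()
        weights = np.exp(logw)
        weights /= weights.sum()
        ess = 1.0 / np.sum(weights ** 2)
        if ess < 10:
            raise RuntimeError(f"particle degeneracy at step {t_idx} (ESS={ess:.1f})")
        mean = np.average(particles, axis=0, weights=weights)
        cov = np.cov(particles.T, aweights=weights, bias=True)
        moments.append((mean, cov))
        # systematic resampling
        positions = (rng.random() + np.arange(n_particles)) / n_particles
        idx = np.searchsorted(np.cumsum(weights), positions)
        particles = particles[np.minimum(idx, n_particles - 1)]
        weights = np.full(n_particles, 1.0 / n_particles)

    return moments


def pack_cov(P: np.ndarray) -> np.ndarray:
    """Upper-triangular packing of a 5x5 covariance -> length-15 vector."""
    iu = np.triu_indices(5)
    return np.asarray(P)[iu]


def unpack_cov(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_cov`."""
    iu = np.triu_indices(5)
    P = np.zeros((5, 5))
    P[iu] = packed
    return P + np.triu(P, 1).T


def beliefs_to_frame(beliefs):
    """Serialize a belief trajectory: columns s_hat_1..5 and the packed
    upper-triangular covariance P_1..15 (one row per step, aligned with the
    episode rows)."""
    import pandas as pd

    rows = np.array([np.concatenate([b.mean, pack_cov(b.cov)])
                     for b in beliefs])
    cols = ([f"s_hat_{i}" for i in range(1, 6)]
            + [f"P_{i}" for i in range(1, 16)])
    return pd.DataFrame(rows, columns=cols)


def beliefs_from_frame(df) -> list[Belief]:
    mean_cols = [f"s_hat_{i}" for i in range(1, 6)]
    cov_cols = [f"P_{i}" for i in range(1, 16)]
    return [Belief(row[mean_cols].to_numpy(float),
                   unpack_cov(row[cov_cols].to_numpy(float)))
            for _, row in df.iterrows()]
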