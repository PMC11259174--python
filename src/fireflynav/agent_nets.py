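"""Actor and critic networks with graded module specialization.

Architecture family (critics 1-5 are ordered by increasing specialization):

================  ==========================================================
actor 1           holistic: one 220-unit LSTM over {o_t, a_{t-1}}
actor 2           two 128-unit LSTMs in sequence
actor 3           128-unit LSTM followed by a 2x300 ReLU MLP ("modular")
actor "ekf"       feedforward 2x300 MLP over the EKF belief {mean, cov}
critic 1          holistic: one 220-unit LSTM; a_t joins the input
critic 2          two LSTMs; a_t visible to both modules
critic 3          LSTM + MLP; a_t visible to both modules
critic 4          two LSTMs; a_t routed ONLY into the second
critic 5          LSTM + MLP; a_t routed ONLY into the second ("modular")
critic "ekf"      feedforward MLP over {belief, a_t}
================  ==========================================================

Specialization is structural: in critics 4 and 5 there simply is no input
path carrying the action into the first module, so value computation cannot
occur before action injection.  Total trainable parameter counts are matched
across the recurrent variants to within 10%.

Inputs are normalized at the interface (positions / 400 cm, angles / 90 deg,
velocities / joystick gain); see :func:`encode_observation` and
:func:`encode_belief`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from fireflynav._nn import MLP, Linear, LSTMCell, Network
from fireflynav.belief_filter import Belief, pack_cov
from fireflynav.task_env import TaskConfig

__all__ = [
    "AgentSpec",
    "build_actor",
    "build_critic",
    "FeedforwardActor",
    "FeedforwardCritic",
    "RecurrentActor",
    "RecurrentCritic",
    "count_parameters",
    "encode_observation",
    "encode_belief",
    "belief_scales",
    "mirror_encoded_observation",
    "mirror_encoded_belief",
    "POSITION_SCALE",
    "ANGLE_SCALE",
]

POSITION_SCALE = 400.0   # cm, max target distance
ANGLE_SCALE = 90.0       # deg

Kind = Union[int, str]

_VALID_ACTORS = {1, 2, 3, "ekf"}
_VALID_CRITICS = {1, 2, 3, 4, 5, "ekf"}


@dataclass(frozen=True)
class AgentSpec:
    """Architecture descriptor plus the seeds/widths needed to build it."""

    actor_kind: Kind = 3
    critic_kind: Kind = 5
    holistic_width: int = 220
    recurrent_width: int = 128
    feedforward_widths: tuple[int, ...] = (300, 300)
    obs_dim: int = 4
    action_dim: int = 2
    belief_dim: int = 20      # 5 mean + 15 packed covariance entries
    seed: int = 0

    def __post_init__(self) -> None:
        if self.actor_kind not in _VALID_ACTORS:
            raise ValueError(f"unknown actor kind {self.actor_kind!r}")
        if self.critic_kind not in _VALID_CRITICS:
            raise ValueError(f"unknown critic kind {self.critic_kind!r}")

    @property
    def recurrent(self) -> bool:
        """True if the *actor* needs recurrent (trajectory) training."""
        return self.actor_kind != "ekf" or self.critic_kind != "ekf"

    @property
    def input_dim(self) -> int:
        """Per-step state-related input dimension i_t for the actor."""
        if self.actor_kind == "ekf":
            return self.belief_dim
        return self.obs_dim + self.action_dim   # {o_t, a_{t-1}}


# ---------------------------------------------------------------------------
# input encoding
# ---------------------------------------------------------------------------

def _gain(config: TaskConfig) -> np.ndarray:
    # normalization uses the 1x training gain; the agent does not know n
    return np.asarray(config.gain, dtype=float)


def encode_observation(obs: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Normalize a raw 4-vector observation [o_v, o_omega, o_gx, o_gy]."""
    g = _gain(config)
    o = np.asarray(obs, dtype=float)
    return np.array([o[0] / g[0], o[1] / g[1],
                     o[2] / POSITION_SCALE, o[3] / POSITION_SCALE])


def belief_scales(config: TaskConfig) -> np.ndarray:
    g = _gain(config)
    return np.array([POSITION_SCALE, POSITION_SCALE, ANGLE_SCALE, g[0], g[1]])


def encode_belief(belief: Belief, config: TaskConfig) -> np.ndarray:
    """Normalize the belief mean and packed upper-triangular covariance into
    the 20-dim input vector for EKF-input networks."""
    s = belief_scales(config)
    mean = belief.mean / s
    cov = belief.cov / np.outer(s, s)
    return np.concatenate([mean, pack_cov(cov)])


def mirror_encoded_observation(obs: np.ndarray) -> np.ndarray:
    """Reflect a (possibly batched) encoded observation across the y axis."""
    out = np.array(obs, dtype=float, copy=True)
    out[..., 1] *= -1.0   # o_omega
    out[..., 2] *= -1.0   # o_gx
    return out


_MIRROR_SIGNS5 = np.array([-1.0, 1.0, -1.0, 1.0, -1.0])


def mirror_encoded_belief(i_t: np.ndarray) -> np.ndarray:
    """Reflect an encoded 20-dim belief input across the y axis.

    The mean transform is affine (x -> -x, theta -> 180 - theta,
    omega -> -omega); the covariance conjugates by diag(-1,1,-1,1,-1).
    """
    out = np.array(i_t, dtype=float, copy=True)
    out[..., 0] *= -1.0
    out[..., 2] = 180.0 / ANGLE_SCALE - out[..., 2]
    out[..., 4] *= -1.0
    iu, ju = np.triu_indices(5)
    signs = _MIRROR_SIGNS5[iu] * _MIRROR_SIGNS5[ju]
    out[..., 5:] *= signs
    return out


def mirror_action(action: np.ndarray) -> np.ndarray:
    out = np.array(action, dtype=float, copy=True)
    out[..., 1] *= -1.0
    return out


# ---------------------------------------------------------------------------
# feedforward (EKF-input) networks
# ---------------------------------------------------------------------------

class FeedforwardActor(Network):
    """MLP actor over the encoded EKF belief; tanh-bounded output."""

    def __init__(self, n_in: int, widths: tuple[int, ...],
                 action_dim: int, rng: np.random.Generator):
        super().__init__()
        self.mlp = self.add("mlp", MLP(n_in, widths, rng))
        self.head = self.add("head", Linear(self.mlp.n_out, action_dim, rng))
        self.n_in = n_in

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected input dim {self.n_in}, got {x.shape[1]}")
        feats, mlp_ctx = self.mlp.forward(x)
        y, head_ctx = self.head.forward(feats)
        a = np.tanh(y)
        return a, (mlp_ctx, head_ctx, a)

    def backward(self, ctx, da: np.ndarray) -> np.ndarray:
        mlp_ctx, head_ctx, a = ctx
        dy = da * (1.0 - a * a)
        dfeats = self.head.backward(head_ctx, dy)
        return self.mlp.backward(mlp_ctx, dfeats)

    def act(self, x: np.ndarray) -> np.ndarray:
        a, _ = self.forward(x)
        return a[0]


class FeedforwardCritic(Network):
    """MLP critic over {encoded belief, action}; linear scalar output."""

    def __init__(self, n_in: int, widths: tuple[int, ...],
                 action_dim: int, rng: np.random.Generator):
        super().__init__()
        self.mlp = self.add("mlp", MLP(n_in + action_dim, widths, rng))
        self.head = self.add("head", Linear(self.mlp.n_out, 1, rng))
        self.n_in = n_in
        self.action_dim = action_dim

    def forward(self, x: np.ndarray, a: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        a = np.atleast_2d(np.asarray(a, dtype=float))
        z = np.concatenate([x, a], axis=1)
        feats, mlp_ctx = self.mlp.forward(z)
        q, head_ctx = self.head.forward(feats)
        return q[:, 0], (mlp_ctx, head_ctx)

    def backward(self, ctx, dq: np.ndarray):
        mlp_ctx, head_ctx = ctx
        dfeats = self.head.backward(head_ctx, np.atleast_2d(dq).reshape(-1, 1))
        dz = self.mlp.backward(mlp_ctx, dfeats)
        return dz[:, :self.n_in], dz[:, self.n_in:]


# ---------------------------------------------------------------------------
# recurrent networks
# ---------------------------------------------------------------------------

@dataclass
class _Stage:
    kind: str            # "lstm" | "mlp"
    module: object
    takes_action: bool
    name: str


def _actor_stages(spec: AgentSpec) -> list[tuple[str, str, bool]]:
    if spec.actor_kind == 1:
        return [("lstm220", "lstm", False)]
    if spec.actor_kind == 2:
        return [("rnn1", "lstm", False), ("rnn2", "lstm", False)]
    if spec.actor_kind == 3:
        return [("rnn1", "lstm", False), ("mlp", "mlp", False)]
    raise ValueError(f"actor kind {spec.actor_kind!r} is not recurrent")


def _critic_stages(spec: AgentSpec) -> list[tuple[str, str, bool]]:
    k = spec.critic_kind
    if k == 1:
        return [("lstm220", "lstm", True)]
    if k == 2:
        return [("rnn1", "lstm", True), ("rnn2", "lstm", True)]
    if k == 3:
        return [("rnn1", "lstm", True), ("mlp", "mlp", True)]
    if k == 4:
        return [("rnn1", "lstm", False), ("rnn2", "lstm", True)]
    if k == 5:
        return [("rnn1", "lstm", False), ("mlp", "mlp", True)]
    raise ValueError(f"critic kind {k!r} is not recurrent")


class _RecurrentNet(Network):
    """Shared machinery for staged recurrent actors/critics.

    ``step`` consumes the per-step input (and the action, for critics),
    threading each LSTM stage's (h, c).  ``step_backward`` runs the exact
    reverse pass; BPTT over a trajectory is a loop over step contexts.
    """

    def __init__(self, spec: AgentSpec, stages: list[tuple[str, str, bool]],
                 n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.n_in = n_in
        self.action_dim = spec.action_dim
        self.stages: list[_Stage] = []
        width = spec.holistic_width if len(stages) == 1 else spec.recurrent_width
        prev = None
        for name, kind, takes_action in stages:
            in_dim = n_in if prev is None else prev
            if takes_action:
                in_dim += spec.action_dim
            if kind == "lstm":
                module = self.add(name, LSTMCell(in_dim, width, rng))
                prev = width
            else:
                module = self.add(name, MLP(in_dim, spec.feedforward_widths, rng))
                prev = module.n_out
            self.stages.append(_Stage(kind, module, takes_action, name))
        self.head = self.add("head", Linear(prev, n_out, rng))
        self.takes_action = any(s[2] for s in stages)

    @property
    def lstm_stages(self) -> list[_Stage]:
        return [s for s in self.stages if s.kind == "lstm"]

    def init_state(self, batch: int = 1) -> list[tuple[np.ndarray, np.ndarray]]:
        """All-zero hidden state (the trial-start reset contract)."""
        out = []
        for s in self.lstm_stages:
            w = s.module.width
            out.append((np.zeros((batch, w)), np.zeros((batch, w))))
        return out

    def _step_core(self, x: np.ndarray, action, state):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected input dim {self.n_in}, got {x.shape[1]}")
        if self.takes_action:
            if action is None:
                raise ValueError("this network requires the action input")
            action = np.atleast_2d(np.asarray(action, dtype=float))
        elif action is not None:
            raise ValueError("action routed to a network that does not accept it")
        feats = x
        new_state = []
        ctxs = []
        activations = {}
        li = 0
        for s in self.stages:
            inp = np.concatenate([feats, action], axis=1) if s.takes_action else feats
            if s.kind == "lstm":
                h, c = state[li]
                feats, c_new, ctx = s.module.forward(inp, h, c)
                new_state.append((feats, c_new))
                li += 1
            else:
                feats, ctx = s.module.forward(inp)
            ctxs.append((s, ctx, inp.shape[1]))
            activations[s.name] = feats
        y, head_ctx = self.head.forward(feats)
        return y, new_state, (ctxs, head_ctx), activations

    def _step_backward_core(self, ctx, dy: np.ndarray, dstate_next):
        """Reverse one step.  ``dstate_next`` carries gradient arriving from
        the future into this step's output state; returns (dx, da, dstate_prev)
        where dstate_prev flows into the previous step."""
        ctxs, head_ctx = ctx
        dfeats = self.head.backward(head_ctx, dy)
        da_total = None
        dstate_prev: list = [None] * len(self.lstm_stages)
        li = len(self.lstm_stages)
        for s, s_ctx, in_dim in reversed(ctxs):
            if s.kind == "lstm":
                li -= 1
                dh_in = dfeats
                if dstate_next is not None and dstate_next[li] is not None:
                    dh_in = dh_in + dstate_next[li][0]
                    dc_in = dstate_next[li][1]
                else:
                    dc_in = np.zeros_like(dh_in)
                dinp, dh_prev, dc_prev = s.module.backward(s_ctx, dh_in, dc_in)
                dstate_prev[li] = (dh_prev, dc_prev)
            else:
                dinp = s.module.backward(s_ctx, dfeats)
            if s.takes_action:
                da = dinp[:, in_dim - self.action_dim:]
                da_total = da if da_total is None else da_total + da
                dfeats = dinp[:, :in_dim - self.action_dim]
            else:
                dfeats = dinp
        return dfeats, da_total, dstate_prev


class RecurrentActor(_RecurrentNet):
    def __init__(self, spec: AgentSpec, rng: np.random.Generator):
        n_in = spec.obs_dim + spec.action_dim
        super().__init__(spec, _actor_stages(spec), n_in, spec.action_dim, rng)

    def step(self, x, state):
        y, new_state, core_ctx, acts = self._step_core(x, None, state)
        a = np.tanh(y)
        return a, new_state, (core_ctx, a, acts)

    def step_backward(self, ctx, da, dstate_next=None):
        core_ctx, a, _ = ctx
        dy = np.atleast_2d(da) * (1.0 - a * a)
        dx, _, dstate_prev = self._step_backward_core(core_ctx, dy, dstate_next)
        return dx, dstate_prev

    def stage_activations(self, ctx) -> dict[str, np.ndarray]:
        return ctx[2]


class RecurrentCritic(_RecurrentNet):
    def __init__(self, spec: AgentSpec, rng: np.random.Generator):
        n_in = spec.obs_dim + spec.action_dim
        super().__init__(spec, _critic_stages(spec), n_in, 1, rng)

    def step(self, x, action, state):
        y, new_state, core_ctx, acts = self._step_core(x, action, state)
        return y[:, 0], new_state, (core_ctx, acts)

    def step_backward(self, ctx, dq, dstate_next=None):
        core_ctx, _ = ctx
        dy = np.asarray(dq, dtype=float).reshape(-1, 1)
        return self._step_backward_core(core_ctx, dy, dstate_next)

    def stage_activations(self, ctx) -> dict[str, np.ndarray]:
        return ctx[1]


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_actor(spec: AgentSpec, rng: Optional[np.random.Generator] = None):
    rng = rng or np.random.default_rng(spec.seed)
    if spec.actor_kind == "ekf":
        return FeedforwardActor(spec.belief_dim, spec.feedforward_widths,
                                spec.action_dim, rng)
    return RecurrentActor(spec, rng)


def build_critic(spec: AgentSpec, rng: Optional[np.random.Generator] = None):
    rng = rng or np.random.default_rng(spec.seed + 1)
    if spec.critic_kind == "ekf":
        return FeedforwardCritic(spec.belief_dim, spec.feedforward_widths,
                                 spec.action_dim, rng)
    return RecurrentCritic(spec, rng)


def count_parameters(net_or_spec, which: str = "critic") -> int:
    """Exact trainable-parameter count of a network (or of the network a
    spec would build; ``which`` selects actor or critic)."""
    if isinstance(net_or_spec, AgentSpec):
        rng = np.random.default_rng(0)
        net = (build_actor(net_or_spec, rng) if which == "actor"
               else build_critic(net_or_spec, rng))
        return net.n_parameters()
    return net_or_spec.n_parameters()
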