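"""Checkpoint archives: one ``.npz`` per save holding all module weights,
optimizer moments, the trial counter, and the agent spec as embedded YAML."""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import yaml

from fireflynav.agent_nets import AgentSpec, build_actor
from fireflynav.task_env import TaskConfig

__all__ = ["save_checkpoint", "load_checkpoint", "load_policy"]


def _spec_yaml(spec: AgentSpec) -> str:
    d = dataclasses.asdict(spec)
    d["feedforward_widths"] = list(d["feedforward_widths"])
    return yaml.safe_dump(d, sort_keys=False)


def _spec_from_yaml(text: str) -> AgentSpec:
    d = yaml.safe_load(text)
    d["feedforward_widths"] = tuple(d["feedforward_widths"])
    return AgentSpec(**d)


def save_checkpoint(trainer, ck, path) -> None:
    arrays = {"_trial": np.array(ck.trial), "_phase": np.array(ck.phase)}
    for k, v in ck.actor_state.items():
        arrays[f"actor/{k}"] = v
    for j, cs in enumerate(ck.critic_states):
        for k, v in cs.items():
            arrays[f"critic{j}/{k}"] = v
    for j, opt in enumerate([trainer.actor_opt, *trainer.critic_opts]):
        st = opt.state_dict()
        arrays[f"opt{j}/_t"] = np.array(st["t"])
        arrays[f"opt{j}/_lr"] = np.array(st["lr"])
        for k, v in st["m"].items():
            arrays[f"opt{j}/m/{k}"] = v
        for k, v in st["v"].items():
            arrays[f"opt{j}/v/{k}"] = v
    arrays["_spec_yaml"] = np.array(_spec_yaml(trainer.spec))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[AgentSpec, dict, list[dict], int]:
    with np.load(path, allow_pickle=False) as data:
        spec = _spec_from_yaml(str(data["_spec_yaml"]))
        trial = int(data["_trial"])
        actor_state = {k[len("actor/"):]: data[k] for k in data.files
                       if k.startswith("actor/")}
        critic_states = []
        for j in (0, 1):
            prefix = f"critic{j}/"
            critic_states.append({k[len(prefix):]: data[k]
                                  for k in data.files if k.startswith(prefix)})
    return spec, actor_state, critic_states, trial


def load_policy(path, config: Optional[TaskConfig] = None,
                freeze_gain: bool = False):
    """Rebuild the greedy rollout policy stored in a checkpoint archive."""
    from fireflynav.belief_filter import NoiseModel
    from fireflynav.rl_training import EkfPolicy, RnnPolicy

    config = config or TaskConfig()
    spec, actor_state, _, _ = load_checkpoint(path)
    actor = build_actor(spec)
    actor.load_state_dict(actor_state)
    if spec.actor_kind == "ekf":
        return EkfPolicy(actor, NoiseModel.from_config(config), config,
                         freeze_gain=freeze_gain)
    return RnnPolicy(actor, config)
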