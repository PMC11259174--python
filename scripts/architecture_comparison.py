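#!/usr/bin/env python
"""Train recurrent agents across critic architectures and compare validation
TD errors and reward rates (directional check: modular critics reach lower
TD error than holistic critics at matched trial counts).

This is a long-running study (numpy BPTT on CPU), offered as a script rather
than a test.  Scale it with --trials / --seeds / --width.

Usage:
    python scripts/architecture_comparison.py --seeds 3 --trials 1500 \
        --out results/arch_comparison.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from fireflynav.agent_nets import AgentSpec
from fireflynav.rl_training import TD3Trainer, TrainSchedule
from fireflynav.task_env import TaskConfig


def run_one(critic_kind, actor_kind, seed, trials, width, max_trials):
    spec = AgentSpec(actor_kind=actor_kind, critic_kind=critic_kind,
                     recurrent_width=width,
                     holistic_width=int(width * 220 / 128), seed=seed)
    sched = TrainSchedule(trials_after_phase1=trials, checkpoint_every=250,
                          validation_trials=100)
    trainer = TD3Trainer(spec, sched, TaskConfig(), seed=seed)
    result = trainer.train(max_trials=max_trials)
    final = trainer.validate(200)
    return {
        "critic_kind": critic_kind,
        "actor_kind": actor_kind,
        "seed": seed,
        "trials_run": result.trials_run,
        "phase": result.phase,
        **{f"final_{k}": v for k, v in final.items()},
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=3)
    parser.add_argument("--trials", type=int, default=1500,
                        help="budget after phase 1")
    parser.add_argument("--max-trials", type=int, default=6000)
    parser.add_argument("--width", type=int, default=32,
                        help="recurrent width (desk scale; paper: 128)")
    parser.add_argument("--critics", type=int, nargs="+", default=[1, 5],
                        help="critic kinds to compare (paper: 1-5)")
    parser.add_argument("--actor", type=int, default=3)
    parser.add_argument("--out", type=Path,
                        default=Path("results/arch_comparison.csv"))
    args = parser.parse_args()

    rows = []
    for critic_kind in args.critics:
        for seed in range(args.seeds):
            row = run_one(critic_kind, args.actor, seed, args.trials,
                          args.width, args.max_trials)
            print(row, flush=True)
            rows.append(row)
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    by_critic = df.groupby("critic_kind")["final_td_error"].mean()
    print("\nmean validation TD error by critic kind:")
    print(by_critic.to_string())
    if {1, 5} <= set(by_critic.index):
        direction = "<=" if by_critic[5] <= by_critic[1] else ">"
        print(f"\nmodular (5) {direction} holistic (1)")


if __name__ == "__main__":
    main()
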