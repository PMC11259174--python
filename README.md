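# fireflynav

Desk-scale re-implementation of a partially observable "firefly" navigation
study: a POMDP steering simulator, an extended-Kalman-filter (EKF) belief
model in target-relative coordinates, twin-delayed deterministic
policy-gradient (TD3) agents with graded module specialization, and the
behavioral/neural analysis battery used to characterize them.

Everything runs on synthetic data generated by the simulator itself; there
are no external datasets. All neural networks (MLPs and LSTMs) and both TD3
variants (feedforward on EKF beliefs; recurrent with whole-trajectory replay
and BPTT) are implemented in numpy with hand-written gradients, verified
against finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `fireflynav.task_env` | simulator: target sampling, unicycle transition with process noise, masked noisy observation, reward/done, gain & perturbation variants, episode records (CSV/HDF5), mirroring |
| `fireflynav.belief_filter` | EKF in relative coordinates, constant Kalman-gain schedule, bootstrap particle-filter oracle |
| `fireflynav.agent_nets` | actor/critic family (holistic, two-recurrent, recurrent+feedforward, action-to-second-module variants, EKF-input feedforward), input encoders, parameter counting |
| `fireflynav.rl_training` | replay buffers (step tuples / equal-length trajectories, mirror-augmented), exploration & target smoothing, twin-critic and delayed actor updates, 3-phase schedule, checkpoint selection |
| `fireflynav.behavior_metrics` | psychometric/ROC/AUC, signed radial error via idealized arcs, trajectory length & curvature, reward rate, test-time TD errors, no-generalization replays |
| `fireflynav.neural_probe` | spatial tuning maps, ridge decoding with trial-level splits, decoding error, uncertainty sweeps and Kalman-gain fingerprint correlations |
| `fireflynav.experiment_cli` / `fireflynav.cli` | scripted EKF controller (fast fixture policy), perturbation sampling, seeded recipes, click CLI |

## CLI

```bash
fireflynav recipe run --out out/smoke                 # scripted-controller smoke run
fireflynav analyze behavior --episodes out/smoke/seed_0 --out report.csv
fireflynav train --agent agent.yaml --seed 0 --trials 3000 --out out/train
fireflynav eval --checkpoint out/train/checkpoint_0002500.npz --trials 500 --out out/eval
fireflynav replay-nogen --episodes out/eval --task gain2.yaml --out nogen.csv
fireflynav sweep-uncertainty --trials 500 --out sweep.json
```

`agent.yaml` holds `AgentSpec` fields, e.g.

```yaml
actor_kind: ekf        # 1 | 2 | 3 | ekf
critic_kind: ekf       # 1..5 | ekf
feedforward_widths: [300, 300]
```

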