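import numpy as np
import pytest

from fireflynav._nn import Adam
from fireflynav.agent_nets import AgentSpec, build_actor, build_critic
from fireflynav.rl_training import (
    ReplayBuffer,
    TD3Trainer,
    TrainSchedule,
    actor_update,
    critic_update,
    explore_action,
    recurrent_actor_update,
    recurrent_critic_update,
    select_checkpoint,
    soft_update,
    target_smoothed_action,
)
from fireflynav.task_env import TaskConfig


def small_ekf_spec(**kw):
    d = dict(actor_kind="ekf", critic_kind="ekf", feedforward_widths=(16, 16),
             seed=0)
    d.update(kw)
    return AgentSpec(**d)


def small_rnn_spec(**kw):
    d = dict(actor_kind=3, critic_kind=5, recurrent_width=6,
             feedforward_widths=(8,), seed=0)
    d.update(kw)
    return AgentSpec(**d)


class TestExploreAction:
    def test_noise_suppressed_below_threshold(self, rng):
        a = np.array([0.05, -0.02])
        out = explore_action(a, 0.8, 0.1, rng)
        np.testing.assert_array_equal(out, a)

    def test_clipped(self, rng):
        for _ in range(100):
            out = explore_action(np.array([1.0, 1.0]), 2.0, 0.1, rng)
            assert np.all(out <= 1.0) and np.all(out >= -1.0)

    def test_noise_moment(self, rng):
        a = np.array([0.5, 0.5])
        pre_clip = np.array([explore_action(a, 0.4, 0.1, rng)
                             for _ in range(40_000)])
        # with sigma=0.4 at 0.5 the clip bites slightly; check on the raw
        # residuals of the unclipped portion via a direct draw comparison
        draws = a + rng.normal(0, 0.4, size=(40_000, 2))
        for q in (10, 25, 50, 75):
            np.testing.assert_allclose(
                np.percentile(pre_clip, q, axis=0),
                np.percentile(np.clip(draws, -1, 1), q, axis=0), atol=0.02)


class TestTargetSmoothedAction:
    def test_noise_clipped_before_adding(self):
        class Stub:
            def normal(self, loc, sd, size):
                return np.array([0.3, -0.3])
        out = target_smoothed_action(np.array([0.0, 0.0]), Stub())
        np.testing.assert_allclose(out, [0.1, -0.1])

    def test_zero_noise_identity(self):
        class Stub:
            def normal(self, loc, sd, size):
                return np.zeros(2)
        a = np.array([0.4, -0.9])
        np.testing.assert_array_equal(target_smoothed_action(a, Stub()), a)

    def test_added_noise_sd_matches_clipped_normal_moment(self, rng):
        from scipy import stats
        a = np.zeros(2)
        outs = np.array([target_smoothed_action(a, rng)
                         for _ in range(100_000)])
        # closed form for a clipped (not truncated) normal at +-2 sigma
        k = 2.0
        var_unit = ((2 * stats.norm.cdf(k) - 1) - 2 * k * stats.norm.pdf(k)
                    + 2 * k ** 2 * stats.norm.sf(k))
        expected_sd = 0.05 * np.sqrt(var_unit)
        np.testing.assert_allclose(outs.std(axis=0), expected_sd, rtol=0.02)


class TestSoftUpdate:
    def test_fixed_point(self):
        net = build_actor(small_ekf_spec())
        tgt = build_actor(small_ekf_spec())
        tgt.load_state_dict(net.state_dict())
        soft_update(net, tgt, 0.005)
        for k in net.params:
            np.testing.assert_allclose(tgt.params[k], net.params[k])

    def test_single_step_value(self):
        net = build_actor(small_ekf_spec())
        tgt = build_actor(small_ekf_spec(seed=1))
        for p in net.params.values():
            p[...] = 1.0
        for p in tgt.params.values():
            p[...] = 0.0
        soft_update(net, tgt, 0.005)
        for p in tgt.params.values():
            np.testing.assert_allclose(p, 0.005)

    def test_geometric_closed_form(self):
        net = build_actor(small_ekf_spec())
        tgt = build_actor(small_ekf_spec(seed=1))
        w = 0.7
        for p in net.params.values():
            p[...] = w
        for p in tgt.params.values():
            p[...] = 0.0
        k = 20
        for _ in range(k):
            soft_update(net, tgt, 0.005)
        expected = w * (1 - (1 - 0.005) ** k)
        for p in tgt.params.values():
            np.testing.assert_allclose(p, expected, rtol=1e-12)


class _StubActor:
    """Target actor emitting a fixed action."""

    def __init__(self, a):
        self.a = np.asarray(a, dtype=float)

    def forward(self, x):
        return np.tile(self.a, (len(np.atleast_2d(x)), 1)), None


class _StubCritic:
    """Target critic with a fixed scalar output."""

    def __init__(self, q):
        self.q = float(q)

    def forward(self, x, a):
        return np.full(len(np.atleast_2d(x)), self.q), None


class _NoNoise:
    def normal(self, loc, sd, size):
        return np.zeros(size)


class TestCriticUpdate:
    def _nets(self):
        spec = small_ekf_spec()
        rng = np.random.default_rng(0)
        critics = [build_critic(spec, rng), build_critic(spec, rng)]
        opts = [Adam(c, lr=1e-3) for c in critics]
        return critics, opts

    def test_terminal_target_ignores_critics(self, rng):
        critics, opts = self._nets()
        batch = (rng.normal(size=(8, 20)), rng.uniform(-1, 1, (8, 2)),
                 np.full(8, 10.0), rng.normal(size=(8, 20)), np.ones(8))
        # target critics return huge values; terminal transitions ignore them
        before = [c.state_dict() for c in critics]
        critic_update(batch, critics, [_StubCritic(1e6), _StubCritic(1e6)],
                      _StubActor([0, 0]), opts, 0.97, _NoNoise())
        # regression target was exactly 10 => loss finite and small-ish
        q, _ = critics[0].forward(batch[0], batch[1])
        assert np.all(np.isfinite(q))
        for k, v in critics[0].state_dict().items():
            if not np.allclose(v, before[0][k]):
                break
        else:
            pytest.fail("critic parameters unchanged")

    def test_min_of_target_critics(self, rng):
        critics, opts = self._nets()
        i = rng.normal(size=(4, 20))
        batch = (i, rng.uniform(-1, 1, (4, 2)), np.zeros(4),
                 rng.normal(size=(4, 20)), np.zeros(4))
        # compute y through the update by regressing a fresh critic many times
        tc = [_StubCritic(3.0), _StubCritic(5.0)]
        for _ in range(2000):
            critic_update(batch, critics, tc, _StubActor([0.2, 0.1]), opts,
                          0.97, _NoNoise())
        q, _ = critics[0].forward(batch[0], batch[1])
        np.testing.assert_allclose(q, 0.97 * 3.0, atol=0.01)

    def test_two_step_mdp_converges_to_q_star(self, rng):
        # 2-step MDP: s0 --a--> s1 --a--> terminal r=10.
        # With stub target critics pinned to Q*(s1)=10, repeated updates
        # drive Q(s0) -> gamma*10 and Q(s1) -> 10 (within 1e-3).
        critics, opts = self._nets()
        i0 = np.zeros(20)
        i1 = np.ones(20)
        a = np.array([0.5, 0.0])
        batch = (np.stack([i0, i1]), np.stack([a, a]),
                 np.array([0.0, 10.0]), np.stack([i1, i1]),
                 np.array([0.0, 1.0]))

        class PerStateCritic:
            def forward(self, x, a):
                return np.where(np.atleast_2d(x)[:, 0] > 0.5, 10.0, 9.7), None

        tc = [PerStateCritic(), PerStateCritic()]
        for _ in range(4000):
            critic_update(batch, critics, tc, _StubActor(a), opts, 0.97,
                          _NoNoise())
        q, _ = critics[0].forward(np.stack([i0, i1]), np.stack([a, a]))
        np.testing.assert_allclose(q, [9.7, 10.0], atol=1e-3)


class TestActorUpdate:
    def test_quadratic_bowl_oracle(self, rng):
        spec = small_ekf_spec()
        actor = build_actor(spec)
        opt = Adam(actor, lr=3e-3)

        class BowlCritic:
            """Q = -sum((a - 0.3)^2); analytic gradient."""

            def forward(self, x, a):
                self._a = np.atleast_2d(a)
                return -np.sum((self._a - 0.3) ** 2, axis=1), None

            def backward(self, ctx, dq):
                da = -2.0 * (self._a - 0.3) * np.atleast_2d(dq).reshape(-1, 1)
                return None, da

            def zero_grad(self):
                pass

        i = rng.normal(size=(32, 20))
        for _ in range(800):
            actor_update(i, actor, BowlCritic(), opt)
        a, _ = actor.forward(i)
        np.testing.assert_allclose(a, 0.3, atol=0.02)

    def test_critic_frozen(self, rng):
        spec = small_ekf_spec()
        actor = build_actor(spec)
        critic = build_critic(spec)
        opt = Adam(actor, lr=1e-3)
        before = critic.state_dict()
        actor_update(rng.normal(size=(8, 20)), actor, critic, opt)
        after = critic.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
            np.testing.assert_array_equal(critic.grads[k], 0.0)

    def test_actor_critic_update_ratio(self):
        # counter audit: one actor update per two critic updates
        cfg = TaskConfig()
        sched = TrainSchedule()
        trainer = TD3Trainer(small_ekf_spec(), sched, cfg, seed=0)
        for _ in range(60):
            trainer._run_training_trial()
        assert trainer.critic_updates > 20
        assert trainer.actor_updates == trainer.critic_updates // 2


class TestRecurrentUpdates:
    def _batch(self, rng, N=5, M=3, dim=6):
        return {
            "i": rng.normal(size=(N, M, dim)),
            "a": rng.uniform(-1, 1, (N, M, 2)),
            "r": rng.normal(size=(N, M)) * 0.1,
            "D": np.concatenate([np.zeros((N - 1, M)), np.ones((1, M))]),
            "i_next": rng.normal(size=(N, M, dim)),
        }

    def test_critic_update_reduces_loss(self, rng):
        spec = small_rnn_spec()
        nrng = np.random.default_rng(0)
        critics = [build_critic(spec, nrng), build_critic(spec, nrng)]
        tcs = [build_critic(spec, nrng), build_critic(spec, nrng)]
        ta = build_actor(spec, nrng)
        opts = [Adam(c, lr=3e-3) for c in critics]
        batch = self._batch(rng)
        losses = [recurrent_critic_update(batch, critics, tcs, ta, opts,
                                          0.97, _NoNoise())
                  for _ in range(60)]
        assert losses[-1] < losses[0] * 0.5

    def test_actor_update_increases_q(self, rng):
        spec = small_rnn_spec()
        nrng = np.random.default_rng(0)
        actor = build_actor(spec, nrng)
        critic = build_critic(spec, nrng)
        opt = Adam(actor, lr=3e-3)
        batch = self._batch(rng)
        before = critic.state_dict()
        js = [recurrent_actor_update(batch, actor, critic, opt)
              for _ in range(80)]
        assert js[-1] > js[0]
        for k in before:
            np.testing.assert_array_equal(critic.state_dict()[k], before[k])

    def test_unequal_lengths_rejected(self, rng):
        spec = small_rnn_spec()
        critics = [build_critic(spec), build_critic(spec)]
        bad = self._batch(rng)
        bad["i"] = bad["i"][:, :, :].reshape(-1, 6)   # not (N, M, dim)
        with pytest.raises(ValueError):
            recurrent_critic_update(bad, critics, critics,
                                    build_actor(spec),
                                    [Adam(c) for c in critics], 0.97,
                                    _NoNoise())


class TestReplayBuffer:
    def test_fifo_capacity(self):
        buf = ReplayBuffer("steps", capacity=10)
        for k in range(10):
            buf.add({"i": k}, {"i": -k})
        assert len(buf) == 10
        assert buf._items[0]["i"] == 5     # oldest five pairs evicted
        assert buf.n_inserted == 20

    def test_mirror_doubles_insertions(self):
        buf = ReplayBuffer("steps", capacity=1000)
        for k in range(7):
            buf.add({"i": k}, {"i": -k})
        assert buf.n_inserted == 14
        assert len(buf) == 14

    def test_trajectory_equal_length_batches(self, rng):
        buf = ReplayBuffer("trajectories", capacity=100)
        for k in range(30):
            n = int(rng.integers(3, 8))
            traj = {"i": rng.normal(size=(n, 6)),
                    "a": rng.uniform(-1, 1, (n, 2)),
                    "r": np.zeros(n), "D": np.zeros(n),
                    "i_next": rng.normal(size=(n, 6))}
            buf.add(traj, traj)
        for _ in range(10):
            batch = buf.sample_trajectories(4, rng)
            assert batch["i"].ndim == 3
            assert batch["i"].shape[1] == 4

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            ReplayBuffer("episodes", 10)


class TestSchedule:
    def test_printed_values(self):
        s = TrainSchedule()
        assert s.learning_rates == (3e-4, 3e-4, 5e-5)
        assert s.sigma_exp == (0.8, 0.5, 0.4)
        assert s.sigma_o_active == (False, True, True)
        assert s.critic_period == 4
        assert s.actor_delay == 2
        assert s.tau == 0.005
        assert s.gamma == 0.97
        assert s.batch_steps == 256
        assert s.batch_trajectories == 16
        assert s.buffer_steps == 1_600_000
        assert s.buffer_trajectories == 100_000
        assert s.optimizer.eps == 1.5e-4
        assert s.optimizer.weight_decay == 0.0

    def test_phase1_sigma_o_off(self):
        trainer = TD3Trainer(small_ekf_spec(), TrainSchedule(), TaskConfig(),
                             seed=0)
        assert trainer.phase_config().alpha_o == 0.0
        trainer.phase = 2
        assert trainer.phase_config().alpha_o == TaskConfig().alpha_o

    def test_learning_rate_never_increases(self):
        s = TrainSchedule()
        assert s.lr(1) >= s.lr(2) >= s.lr(3)


class TestDeterminism:
    def test_same_seed_same_short_run(self):
        cfg = TaskConfig()
        sched = TrainSchedule(checkpoint_every=30, validation_trials=20)

        def run():
            tr = TD3Trainer(small_ekf_spec(), sched, cfg, seed=3)
            for _ in range(60):
                tr._run_training_trial()
            return tr.actor.state_dict(), tr.validate(20)

        s1, v1 = run()
        s2, v2 = run()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])
        assert v1 == v2

    def test_twin_critic_min_inequality(self, rng):
        # bootstrap target uses min(Q1', Q2') <= each individually
        q1 = rng.normal(size=100)
        q2 = rng.normal(size=100)
        m = np.minimum(q1, q2)
        assert np.all(m <= q1) and np.all(m <= q2)


class TestSelectCheckpoint:
    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_checkpoint([], [])

    def test_single(self):
        assert select_checkpoint(["a"], [[0.3]]) == 0

    def test_unique_max(self):
        rates = [[0.1, 0.2], [0.5, 0.6], [0.4, 0.4]]
        assert select_checkpoint(list("abc"), rates) == 1

    def test_tie_breaks_earliest(self):
        rates = [[0.2], [0.5], [0.5], [0.1]]
        assert select_checkpoint(list("abcd"), rates) == 1

    def test_mean_across_test_sets(self):
        rates = [[0.9, 0.0], [0.4, 0.6]]       # means 0.45 vs 0.5
        assert select_checkpoint(list("ab"), rates) == 1


class TestMixedAgentRejected:
    def test_mixed_ekf_rnn_not_supported(self):
        with pytest.raises(NotImplementedError):
            TD3Trainer(AgentSpec(actor_kind="ekf", critic_kind=1),
                       TrainSchedule(), TaskConfig(), seed=0)
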