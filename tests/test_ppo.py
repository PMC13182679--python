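"""Actor-critic PPO: masking, returns, clipped loss, gradients, learning."""

import numpy as np
import pytest

from gammaplan.nets import ActorNet, Adam, Conv3d, CriticNet
from gammaplan.ppo import (
    PPOAgent,
    PPOConfig,
    PPOMemory,
    Transition,
    actor_batch_gradients,
    actor_forward,
    critic_batch_gradients,
    masked_log_softmax,
    ppo_loss,
    ppo_update,
    returns_and_advantages,
    sample_action,
)


def _fill_memory(memory, rewards, values, dones, rng, shape=(4, 3, 3, 3)):
    n_actions = 2 * 27
    for r, v, d in zip(rewards, values, dones):
        mask = np.zeros(n_actions, bool)
        mask[: n_actions // 2] = True
        memory.store(
            Transition(
                state=(rng.random(shape) > 0.5).astype(np.uint8),
                mask=mask,
                action=int(rng.integers(n_actions // 2)),
                log_prob=float(-rng.random()),
                value=float(v),
                reward=float(r),
                done=bool(d),
            )
        )


class TestMaskedSoftmax:
    def test_single_executable_action_gets_probability_one(self):
        scores = np.array([[5.0, -2.0, 7.0]])
        mask = np.array([[False, True, False]])
        p = np.exp(masked_log_softmax(scores, mask))
        np.testing.assert_array_equal(p, [[0.0, 1.0, 0.0]])

    def test_uniform_scores_give_uniform_over_executable(self):
        scores = np.zeros((1, 10))
        mask = np.zeros((1, 10), bool)
        mask[0, [1, 4, 7]] = True
        p = np.exp(masked_log_softmax(scores, mask))
        assert p[0, [1, 4, 7]] == pytest.approx([1 / 3] * 3)
        assert p[0, ~mask[0]].sum() == 0.0

    def test_matches_enumeration_oracle(self, rng):
        """Masked probabilities equal softmax enumerated by hand over <=100 actions."""
        for _ in range(20):
            n = int(rng.integers(2, 100))
            scores = rng.normal(0, 3, size=(1, n))
            mask = rng.random(n) < 0.5
            mask[rng.integers(n)] = True
            p = np.exp(masked_log_softmax(scores, mask[None]))[0]
            exe = np.flatnonzero(mask)
            e = np.exp(scores[0, exe] - scores[0, exe].max())
            oracle = e / e.sum()
            assert p[exe] == pytest.approx(oracle, abs=1e-6)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(p[~mask] == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_log_softmax(np.zeros((1, 4)), np.zeros((1, 4), bool))


class TestSampleAction:
    def test_certain_action_always_selected(self, rng):
        p = np.array([0.0, 1.0, 0.0])
        for _ in range(10):
            idx, logp = sample_action(p, rng)
            assert idx == 1 and logp == 0.0

    def test_reproducible_given_seed(self):
        p = np.array([0.3, 0.4, 0.3])
        draws1 = [sample_action(p, np.random.default_rng(42))[0] for _ in range(5)]
        draws2 = [sample_action(p, np.random.default_rng(42))[0] for _ in range(5)]
        assert draws1 == draws2

    def test_empirical_frequencies_match(self, rng):
        p = np.array([0.2, 0.5, 0.3])
        n = 10_000
        counts = np.bincount([sample_action(p, rng)[0] for _ in range(n)], minlength=3)
        sigma = np.sqrt(p * (1 - p) * n)
        assert np.all(np.abs(counts - p * n) < 3 * sigma)

    def test_degenerate_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_action(np.array([np.nan, 0.5]), rng)


class TestReturnsAndAdvantages:
    def test_two_step_worked_example(self, rng):
        memory = PPOMemory()
        _fill_memory(memory, [1.0, 0.0], [0.3, 0.0], [False, True], rng)
        returns, adv = returns_and_advantages(memory, gamma=0.99)
        assert returns == pytest.approx([1.0, 0.0])
        assert adv == pytest.approx([0.7, 0.0])

    def test_zero_rewards_give_negative_values(self, rng):
        memory = PPOMemory()
        values = [0.5, -0.2, 0.1]
        _fill_memory(memory, [0, 0, 0], values, [False, False, True], rng)
        _, adv = returns_and_advantages(memory, gamma=0.9)
        assert adv == pytest.approx([-v for v in values])

    def test_matches_double_loop_oracle(self, rng):
        """Per-episode discounting equals the O(T^2) brute-force sum."""
        memory = PPOMemory()
        T, gamma = 17, 0.95
        rewards = rng.normal(size=T)
        dones = [False] * T
        dones[6] = dones[11] = dones[16] = True
        _fill_memory(memory, rewards, rng.normal(size=T), dones, rng)
        returns, _ = returns_and_advantages(memory, gamma)
        start = 0
        for end in (7, 12, 17):
            for t in range(start, end):
                oracle = sum(gamma ** (k - t) * rewards[k] for k in range(t, end))
                assert returns[t] == pytest.approx(oracle, abs=1e-9)
            start = end

    def test_unterminated_memory_rejected(self, rng):
        memory = PPOMemory()
        _fill_memory(memory, [1.0], [0.0], [False], rng)
        with pytest.raises(ValueError, match="terminal"):
            returns_and_advantages(memory, 0.99)


class TestPPOLoss:
    def test_unit_ratio_reduces_to_mean_advantage(self):
        cfg = PPOConfig()
        adv = np.array([0.5, -1.0, 2.0])
        lp = np.log([0.3, 0.2, 0.5])
        total, actor, critic = ppo_loss(lp, lp, adv, np.zeros(3), np.zeros(3), cfg)
        assert actor == pytest.approx(-adv.mean())
        assert critic == 0.0

    def test_clip_arithmetic_positive_advantage(self):
        cfg = PPOConfig(clip_epsilon=0.2)
        old = np.array([0.0])
        new = np.log([1.5])
        _, actor, _ = ppo_loss(new, old, np.array([1.0]), np.zeros(1), np.zeros(1), cfg)
        assert actor == pytest.approx(-1.2)  # min(1.5, clip->1.2)

    def test_clip_arithmetic_negative_advantage(self):
        cfg = PPOConfig(clip_epsilon=0.2)
        _, actor, _ = ppo_loss(
            np.log([1.5]), np.array([0.0]), np.array([-1.0]), np.zeros(1), np.zeros(1), cfg
        )
        assert actor == pytest.approx(1.5)  # pessimistic min(-1.5, -1.2)

    def test_surrogate_between_clipped_bounds(self, rng):
        cfg = PPOConfig()
        for _ in range(20):
            new, old = rng.normal(0, 0.5, 2)
            adv = rng.normal()
            ratio = np.exp(new - old)
            clipped = np.clip(ratio, 0.8, 1.2) * adv
            _, actor, _ = ppo_loss(
                np.array([new]), np.array([old]), np.array([adv]),
                np.zeros(1), np.zeros(1), cfg,
            )
            lo, hi = min(ratio * adv, clipped), max(ratio * adv, clipped)
            assert lo - 1e-9 <= -actor <= hi + 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ppo_loss(np.zeros(2), np.zeros(3), np.zeros(2), np.zeros(2), np.zeros(2), PPOConfig())


class TestGradients:
    def _numeric_grad(self, loss_fn, param, eps=1e-3):
        g = np.zeros_like(param, dtype=np.float64)
        it = np.nditer(param, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = param[i]
            param[i] = orig + eps
            hi = loss_fn()
            param[i] = orig - eps
            lo = loss_fn()
            param[i] = orig
            g[i] = (hi - lo) / (2 * eps)
        return g

    def test_actor_gradient_matches_finite_differences(self, rng):
        """Analytic clipped-surrogate gradient vs central differences, toy policy."""
        cfg = PPOConfig(entropy_coef=0.01)
        policy = ActorNet(n_collimators=2, hidden_channels=2, seed=0)
        B, shape = 3, (4, 3, 3, 3)
        states = rng.random((B,) + shape).astype(np.float32)
        n_actions = 2 * 27
        masks = rng.random((B, n_actions)) < 0.6
        masks[:, 0] = True
        actions = np.array([int(rng.choice(np.flatnonzero(m))) for m in masks])
        old_lp = rng.uniform(-2, -0.5, B)
        adv = rng.normal(size=B)

        def loss_fn():
            scores = policy.forward(states).reshape(B, -1)
            logp = masked_log_softmax(scores, masks)
            p = np.exp(logp)
            new_lp = logp[np.arange(B), actions]
            ratio = np.exp(new_lp - old_lp)
            surr = np.minimum(
                ratio * adv, np.clip(ratio, 1 - cfg.clip_epsilon, 1 + cfg.clip_epsilon) * adv
            )
            ent = -np.where(p > 0, p * logp, 0.0).sum(axis=1).mean()
            return -surr.mean() - cfg.entropy_coef * ent

        _, _, grads = actor_batch_gradients(policy, states, masks, actions, old_lp, adv, cfg)
        params = policy.parameters()
        for p, g in zip(params, grads):
            numeric = self._numeric_grad(loss_fn, p)
            assert g == pytest.approx(numeric, abs=1e-3), "analytic vs numeric gradient"

    def test_critic_gradient_matches_finite_differences(self, rng):
        cfg = PPOConfig(value_loss_coef=0.5)
        value = CriticNet(hidden_channels=2, seed=1)
        B = 3
        states = rng.random((B, 4, 3, 3, 3)).astype(np.float32)
        returns = rng.normal(size=B).astype(np.float32)

        def loss_fn():
            v = value.forward(states)
            return cfg.value_loss_coef * float(np.mean((v - returns) ** 2))

        _, grads = critic_batch_gradients(value, states, returns, cfg)
        for p, g in zip(value.parameters(), grads):
            numeric = self._numeric_grad(loss_fn, p)
            assert g == pytest.approx(numeric, abs=1e-3)

    def test_zero_gradient_leaves_parameters_unchanged(self, rng):
        """Zero advantages + perfect critic + no entropy: Adam does nothing."""
        cfg = PPOConfig(entropy_coef=0.0)
        agent = PPOAgent(n_collimators=2, cfg=cfg, seed=0)
        memory = agent.memory
        state = (rng.random((4, 3, 3, 3)) > 0.5).astype(np.uint8)
        mask = np.ones(2 * 27, bool)
        # reward 0 everywhere and value estimate forced to the true return 0
        x = state[None].astype(np.float32)
        v = float(agent.value.forward(x)[0])
        memory.store(Transition(state, mask, 0, -1.0, v, v * 0.0, True))
        # make value prediction exactly equal the return by zeroing the head
        agent.value.layers[-1].w[:] = 0
        agent.value.layers[-1].b[:] = 0
        before_p = [p.copy() for p in agent.policy.parameters()]
        memory.transitions[0] = Transition(state, mask, 0, -1.0, 0.0, 0.0, True)
        agent.update(np.random.default_rng(0))
        after_p = agent.policy.parameters()
        for b, a in zip(before_p, after_p):
            np.testing.assert_allclose(a, b, atol=1e-7)


class TestMemory:
    def test_store_then_clear(self, rng):
        m = PPOMemory()
        _fill_memory(m, [1] * 5, [0] * 5, [False] * 4 + [True], rng)
        assert len(m) == 5
        m.clear()
        assert len(m) == 0

    def test_batches_partition_indices(self, rng):
        m = PPOMemory()
        _fill_memory(m, [0] * 19, [0] * 19, [True] * 19, rng)
        batches = m.batch_indices(8, rng)
        assert [len(b) for b in batches] == [8, 8, 3]
        assert sorted(np.concatenate(batches)) == list(range(19))

    def test_transition_fields_roundtrip(self, rng):
        m = PPOMemory()
        _fill_memory(m, [0.25], [1.5], [True], rng)
        t = m.transitions[0]
        assert (t.reward, t.value, t.done) == (0.25, 1.5, True)

    def test_invalid_log_prob_rejected(self):
        with pytest.raises(ValueError):
            Transition(np.zeros((4, 1, 1, 1), np.uint8), np.ones(4, bool), 0, 0.5, 0, 0, True)


class TestLearning:
    def test_update_is_deterministic(self, rng):
        traces = []
        for _ in range(2):
            policy = ActorNet(2, hidden_channels=2, seed=3)
            value = CriticNet(hidden_channels=2, seed=4)
            memory = PPOMemory()
            fill_rng = np.random.default_rng(9)
            _fill_memory(memory, [1, 0, 0.5], [0.1, 0.2, 0.3], [False, False, True], fill_rng)
            traces.append(ppo_update(policy, value, memory, PPOConfig(), 11))
        assert traces[0] == traces[1]

    def test_bandit_learns_rewarding_arm(self):
        """Two-action bandit, rewards {1, 0}: the rewarding arm dominates."""
        cfg = PPOConfig(hidden_channels=2)
        agent = PPOAgent(n_collimators=4, cfg=cfg, seed=0)
        rng = np.random.default_rng(0)
        state_arr = np.ones((4, 1, 1, 1), np.float32)
        mask = np.array([True, True, False, False])  # two executable actions
        for _ in range(200):
            probs = actor_forward(agent.policy, state_arr, mask)
            action, logp = sample_action(probs, rng)
            v = float(agent.value.forward(state_arr[None])[0])
            reward = 1.0 if action == 0 else 0.0
            agent.store(
                Transition(state_arr.astype(np.uint8), mask, action, logp, v, reward, True)
            )
            agent.update(rng)
        final = actor_forward(agent.policy, state_arr, mask)
        assert final[0] > 0.95

    def test_critic_descends_on_fixed_batch(self, rng):
        cfg = PPOConfig(learning_rate=1e-3)
        value = CriticNet(hidden_channels=2, seed=5)
        states = rng.random((6, 4, 5, 5, 5)).astype(np.float32)
        returns = rng.normal(size=6).astype(np.float32)
        opt = Adam(value.parameters(), cfg.learning_rate)
        first = None
        for _ in range(5):
            loss, grads = critic_batch_gradients(value, states, returns, cfg)
            first = loss if first is None else first
            opt.step(grads)
        loss_final, _ = critic_batch_gradients(value, states, returns, cfg)
        assert loss_final <= first

    def test_empty_memory_rejected(self):
        with pytest.raises(ValueError):
            ppo_update(ActorNet(2, 2, 0), CriticNet(2, 0), PPOMemory(), PPOConfig(), 0)
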