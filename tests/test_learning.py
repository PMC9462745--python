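import numpy as np
import pytest

from taubank import _kernels
from taubank.agent import action_sums, AgentParams
from taubank.integrators import NoisyReadout, make_grid
from taubank.learning import (
    CriticParams,
    TrainingConfig,
    critic_grad,
    critic_value,
    td_step,
    trace_update,
    train,
)
from taubank.task import TaskParams


class TestCritic:
    def test_zero_critic(self):
        c = CriticParams.zeros(4)
        y = NoisyReadout(np.ones(4), np.ones(4))
        assert critic_value(y, c) == 0.0

    def test_single_tau_arithmetic(self):
        c = CriticParams(w_s=np.array([0.5]), w_c=np.array([0.0]), b_v=0.1)
        y = NoisyReadout(np.array([-0.4]), np.array([0.9]))
        assert critic_value(y, c, abs_signal=True) == pytest.approx(0.3)

    def test_abs_feature_sign_invariant(self):
        rng = np.random.default_rng(0)
        c = CriticParams(w_s=rng.normal(size=5), w_c=rng.normal(size=5), b_v=0.2)
        y = NoisyReadout(rng.normal(size=5), rng.uniform(size=5))
        flipped = NoisyReadout(-y.y_signal, y.y_clock)
        assert critic_value(y, c, abs_signal=True) == pytest.approx(
            critic_value(flipped, c, abs_signal=True)
        )
        # the signed default is not sign invariant in general
        assert critic_value(y, c) != pytest.approx(critic_value(flipped, c))


class TestTDStep:
    @pytest.mark.parametrize(
        "prev_V,next_V,r,terminal,gamma,expected",
        [
            (0.6, 0.0, 1.0, True, 1.0, 0.4),
            (0.5, 0.5, 0.0, False, 1.0, 0.0),
            (0.3, 0.0, 0.0, True, 1.0, -0.3),
            (0.2, 0.5, 0.0, False, 0.9, 0.25),
        ],
    )
    def test_examples(self, prev_V, next_V, r, terminal, gamma, expected):
        assert td_step(prev_V, next_V, r, terminal, gamma) == pytest.approx(expected)


class TestTraces:
    def test_lambda_zero_is_instantaneous_gradient(self):
        e = np.array([5.0, -2.0])
        g = np.array([0.1, 0.2])
        assert np.allclose(trace_update(e, g, gamma=1.0, lam=0.0), g)

    def test_accumulation(self):
        e = np.zeros(2)
        g = np.ones(2)
        for _ in range(3):
            e = trace_update(e, g, gamma=1.0, lam=0.5)
        assert np.allclose(e, 1 + 0.5 + 0.25)


class TestGradientCorrectness:
    def test_critic_gradient_is_feature_vector(self):
        rng = np.random.default_rng(1)
        y = NoisyReadout(rng.normal(size=6), rng.uniform(size=6))
        c = CriticParams(rng.normal(size=6), rng.normal(size=6), 0.3)
        g_ws, g_wc, g_b = critic_grad(y)
        h = 1e-6
        for i in range(6):
            c2 = c.copy()
            c2.w_s[i] += h
            up = critic_value(y, c2)
            c2.w_s[i] -= 2 * h
            dn = critic_value(y, c2)
            assert g_ws[i] == pytest.approx((up - dn) / (2 * h), abs=1e-6)


class TestKernelConsistency:
    def test_policy_terms_matches_reference(self):
        """The jitted policy arithmetic equals the numpy reference."""
        rng = np.random.default_rng(3)
        g = make_grid()
        for _ in range(50):
            p = AgentParams(
                theta_s=rng.normal(0, 1, (3, 10)),
                theta_c=rng.normal(0, 1, (3, 10)),
                b=rng.normal(0, 1, 3),
                taus=g.taus,
            )
            y = NoisyReadout(rng.normal(0, 0.3, 10), rng.uniform(0, 1, 10))
            ss, sc, prob = _kernels.policy_terms(
                p.theta_s, p.theta_c, p.b, y.y_signal, y.y_clock
            )
            ref = action_sums(y, p)
            assert np.allclose(ss, ref.sigma_s, atol=1e-12)
            assert np.allclose(sc, ref.sigma_c, atol=1e-12)
            assert np.allclose(prob, ref.p, atol=1e-12)


class TestTraining:
    def test_learning_improves_reward(self):
        """Mean reward over the last tenth of training exceeds the first
        tenth, for ten independent seeds."""
        task = TaskParams()
        grid = make_grid()
        decay = grid.decay(task.dt)
        gain = 1.0 - decay
        cfg = TrainingConfig()
        n_ep = 6000
        for seed in range(10):
            p = AgentParams.zeros(grid, b_wait=cfg.b_wait_init)
            c = CriticParams.zeros(grid.n_tau)
            mus = np.random.default_rng(seed).normal(0, task.sigma_mu, n_ep)
            rewards, _, _ = _kernels.train_episodes(
                p.theta_s, p.theta_c, p.b, c.w_s, c.w_c, np.array([0.0]),
                decay, gain, mus, task.sample_std, task.sigma_I, task.n_steps,
                cfg.lr_actor, cfg.lr_critic, cfg.lambda_actor,
                cfg.lambda_critic, cfg.gamma, True, False, 1000 + seed,
            )
            tenth = n_ep // 10
            assert rewards[-tenth:].mean() > rewards[:tenth].mean()

    def test_divergence_guard(self):
        cfg = TrainingConfig(
            lr_actor=2.0,
            lr_critic=2.0,
            n_episodes_max=2000,
            checkpoint_every=1000,
            eval_episodes=100,
            coherence_episodes=50,
            seed=0,
        )
        with pytest.raises(FloatingPointError):
            train(TaskParams(), make_grid(), cfg)

    def test_single_tau_variant_requires_tau(self):
        with pytest.raises(ValueError):
            train(TaskParams(), None, TrainingConfig(), variant="single_tau")

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainingConfig(lr_actor=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(lambda_actor=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(gamma=0.0)


class TestTrainedStructure:
    def test_signal_weights_approximately_antisymmetric(self, default_run):
        """After training, right and left signal weights mirror each other
        (theta_right ~= -theta_left), reflecting the task's symmetry."""
        p = default_run.params
        asym = np.max(np.abs(p.theta_s[2] + p.theta_s[0]))
        scale = np.max(np.abs(p.theta_s[2]))
        assert asym / scale < 0.2

    def test_no_clock_variant_keeps_clock_weights_zero(self, seed_artifacts):
        for art in seed_artifacts:
            assert np.all(art.no_clock.params.theta_c == 0.0)
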