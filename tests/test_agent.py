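import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taubank.agent import (
    A_LEFT,
    A_RIGHT,
    A_WAIT,
    AgentParams,
    act,
    action_sums,
    delta_sigma_clock,
    log_policy_grad,
    restrict_to_single_tau,
    softmax_policy,
    strip_clock,
)
from taubank.integrators import NoisyReadout, make_grid


def random_params(rng, n_tau=10, scale=1.0):
    return AgentParams(
        theta_s=rng.normal(0, scale, (3, n_tau)),
        theta_c=rng.normal(0, scale, (3, n_tau)),
        b=rng.normal(0, scale, 3),
        taus=make_grid(n_tau).taus,
    )


def random_readout(rng, n_tau=10):
    return NoisyReadout(
        y_signal=rng.normal(0, 0.3, n_tau), y_clock=rng.uniform(0, 1, n_tau)
    )


class TestActionSums:
    def test_null_parameters(self):
        g = make_grid()
        p = AgentParams.zeros(g)
        out = action_sums(random_readout(np.random.default_rng(0)), p)
        assert np.all(out.sigma == 0)
        assert np.allclose(out.p, 1 / 3)

    def test_single_tau_arithmetic(self):
        p = AgentParams(
            theta_s=np.array([[0.0], [0.0], [2.0]]),
            theta_c=np.zeros((3, 1)),
            b=np.array([0.0, 0.0, -0.3]),
            taus=np.array([1.0]),
        )
        out = action_sums(NoisyReadout(np.array([0.5]), np.array([0.2])), p)
        assert out.sigma[A_RIGHT] == pytest.approx(0.7)

    def test_wait_uses_absolute_value(self):
        """Mirror-symmetric parameters: negating the signal swaps the
        left/right sums and leaves the wait sum unchanged."""
        rng = np.random.default_rng(5)
        g = make_grid()
        p = AgentParams.zeros(g)
        p.theta_s[A_RIGHT] = rng.normal(0, 1, g.n_tau)
        p.theta_s[A_LEFT] = -p.theta_s[A_RIGHT]
        p.theta_s[A_WAIT] = rng.normal(0, 1, g.n_tau)
        p.theta_c[A_LEFT] = p.theta_c[A_RIGHT] = rng.normal(0, 1, g.n_tau)
        p.b[A_LEFT] = p.b[A_RIGHT] = 0.4
        y = random_readout(rng)
        mirrored = NoisyReadout(-y.y_signal, y.y_clock)
        a, b = action_sums(y, p), action_sums(mirrored, p)
        assert a.sigma[A_LEFT] == pytest.approx(b.sigma[A_RIGHT], abs=1e-12)
        assert a.sigma[A_WAIT] == pytest.approx(b.sigma[A_WAIT], abs=1e-12)

    def test_decomposition_identity(self):
        """dSigma_right = dSigma^s - dSigma^c holds step by step."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = random_params(rng)
            out = action_sums(random_readout(rng), p)
            assert out.dsr == pytest.approx(out.ds_s - out.ds_c, abs=1e-12)
            assert out.dsr == pytest.approx(
                out.sigma[A_RIGHT] - out.sigma[A_WAIT], abs=1e-12
            )

    def test_shape_mismatch(self):
        p = AgentParams.zeros(make_grid(5, 0.1, 1.0))
        with pytest.raises(ValueError):
            action_sums(random_readout(np.random.default_rng(0), n_tau=10), p)


class TestSoftmax:
    def test_symmetric(self):
        assert np.allclose(softmax_policy(np.zeros(3)), 1 / 3)

    def test_hand_value(self):
        p = softmax_policy(np.array([0.0, 0.0, 1.0]))
        assert p[2] == pytest.approx(np.e / (2 + np.e), abs=1e-12)

    @given(
        st.lists(st.floats(-30, 30), min_size=3, max_size=3),
        st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=200)
    def test_shift_invariance_and_normalisation(self, sums, shift):
        sums = np.array(sums)
        p1 = softmax_policy(sums)
        p2 = softmax_policy(sums + shift)
        assert abs(p1.sum() - 1.0) < 1e-12
        assert np.allclose(p1, p2, atol=1e-12)

    def test_overflow_safe(self):
        p = softmax_policy(np.array([1000.0, 0.0, -1000.0]))
        assert p[0] == pytest.approx(1.0)

    def test_non_finite_raises(self):
        with pytest.raises(FloatingPointError):
            softmax_policy(np.array([np.nan, 0.0, 0.0]))


class TestAct:
    def test_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(act(np.array([0, 1, 0]), rng) == 0 for _ in range(50))

    def test_frequencies(self):
        rng = np.random.default_rng(1)
        p = np.array([0.2, 0.5, 0.3])
        draws = np.array([act(p, rng) for _ in range(100_000)])
        freqs = [(draws == a).mean() for a in (-1, 0, 1)]
        assert np.allclose(freqs, p, atol=0.005)

    def test_deterministic_replay(self):
        p = np.array([0.3, 0.4, 0.3])
        a = [act(p, np.random.default_rng(77)) for _ in range(1)]
        b = [act(p, np.random.default_rng(77)) for _ in range(1)]
        assert a == b


class TestPolicyGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        h = 1e-6
        for _ in range(20):
            p = random_params(rng, scale=0.5)
            y = random_readout(rng)
            for row in range(3):
                g_ts, g_tc, g_b = log_policy_grad(y, p, row)
                for _ in range(5):
                    a = rng.integers(3)
                    i = rng.integers(p.n_tau)
                    q = p.copy()
                    q.theta_s[a, i] += h
                    up = np.log(action_sums(y, q).p[row])
                    q.theta_s[a, i] -= 2 * h
                    dn = np.log(action_sums(y, q).p[row])
                    fd = (up - dn) / (2 * h)
                    assert g_ts[a, i] == pytest.approx(fd, abs=1e-5)


class TestComparativeVariants:
    def test_single_tau_has_nine_parameters(self):
        p = restrict_to_single_tau(AgentParams.zeros(make_grid()), 2.0)
        assert p.n_params == 9
        assert p.n_tau == 1

    def test_single_tau_embedding(self):
        """A full agent with weights only at one tau equals the restricted
        agent's policy on matched single-tau read-outs."""
        g = make_grid()
        full = AgentParams.zeros(g, b_wait=1.0)
        i = 4
        full.theta_s[A_RIGHT, i] = 2.0
        full.theta_c[A_WAIT, i] = -0.5
        restricted = restrict_to_single_tau(full, float(g.taus[i]))
        rng = np.random.default_rng(2)
        y_full = NoisyReadout(np.zeros(g.n_tau), np.zeros(g.n_tau))
        y_full.y_signal[i] = 0.4
        y_full.y_clock[i] = 0.6
        y_one = NoisyReadout(np.array([0.4]), np.array([0.6]))
        assert np.allclose(
            action_sums(y_full, full).p, action_sums(y_one, restricted).p
        )

    def test_strip_clock(self):
        rng = np.random.default_rng(8)
        p = random_params(rng)
        stripped = strip_clock(p)
        y = random_readout(rng)
        out = action_sums(y, stripped)
        assert np.allclose(out.sigma_c, stripped.b)
        assert out.ds_c == pytest.approx(p.b[A_WAIT] - p.b[A_RIGHT])
        # signal pathway untouched
        assert action_sums(y, p).ds_s == pytest.approx(out.ds_s)

    def test_delta_sigma_clock_matches_noise_free_readout(self):
        rng = np.random.default_rng(21)
        p = random_params(rng)
        t = np.array([0.05, 0.5, 1.7])
        curve = delta_sigma_clock(p, t)
        for j, tj in enumerate(t):
            xc = 1.0 - np.exp(-tj / p.taus)
            out = action_sums(NoisyReadout(np.zeros(p.n_tau), xc), p)
            assert curve[j] == pytest.approx(out.ds_c, abs=1e-12)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        p = random_params(np.random.default_rng(4))
        path = tmp_path / "params.json"
        p.save(path)
        q = AgentParams.load(path)
        assert np.array_equal(p.theta_s, q.theta_s)
        assert np.array_equal(p.theta_c, q.theta_c)
        assert np.array_equal(p.b, q.b)
        assert np.array_equal(p.taus, q.taus)
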