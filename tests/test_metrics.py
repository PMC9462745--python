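import numpy as np
import pytest

from taubank import metrics
from taubank.agent import AgentParams
from taubank.integrators import make_grid
from taubank.simulate import EvalBatch, run_batch
from taubank.task import TaskParams


def make_batch(dsr, steps, actions, mus=None, coherence=12.8, dt=0.01):
    """Synthetic evaluation batch with given per-step traces."""
    n_ep, n_steps = dsr.shape
    actions = np.asarray(actions)
    if mus is None:
        mus = np.where(actions >= 0, 0.3, -0.3)
    rewards = ((actions == 1) & (mus > 0) | (actions == -1) & (mus < 0)).astype(
        float
    )
    return EvalBatch(
        mus=np.asarray(mus, float),
        actions=actions,
        steps=np.asarray(steps),
        rewards=rewards,
        dt=dt,
        n_steps_max=n_steps,
        coherence=coherence,
        dsr=dsr.astype(np.float32),
        dss=dsr.astype(np.float32),
    )


class TestAlignedCurves:
    def test_identical_traces_average_to_trace(self):
        n_ep, n_steps = 150, 100
        trace = np.linspace(0, 1, n_steps)
        dsr = np.tile(trace, (n_ep, 1))
        b = make_batch(dsr, np.full(n_ep, n_steps), np.ones(n_ep, int))
        cs = metrics.build_aligned_curves({12.8: b, 25.6: b}, window=0.3)
        curve = cs.curves[12.8]
        defined = ~np.isnan(curve)
        # at lag -j the average equals trace[n_steps - 1 - j]
        expected = trace[n_steps - 1 - np.arange(len(curve))[::-1]]
        assert np.allclose(curve[defined], expected[defined], atol=1e-6)

    def test_min_count_rule_omits_sparse_coherence(self):
        n_steps = 80
        dsr = np.random.default_rng(0).normal(size=(99, n_steps))
        sparse = make_batch(dsr, np.full(99, n_steps), np.ones(99, int))
        rich = make_batch(
            np.zeros((200, n_steps)), np.full(200, n_steps), np.ones(200, int)
        )
        with pytest.warns(UserWarning, match="curve omitted"):
            cs = metrics.build_aligned_curves(
                {3.2: sparse, 12.8: rich, 25.6: rich}, min_count=100
            )
        assert 3.2 not in cs.curves
        assert 12.8 in cs.curves

    def test_interval_shrinks_where_counts_drop(self):
        """Episodes deciding early cannot contribute to long lags."""
        n_steps = 100
        rng = np.random.default_rng(1)
        steps = np.concatenate([np.full(150, 20), np.full(80, 90)])
        dsr = rng.normal(size=(230, n_steps))
        b = make_batch(dsr, steps, np.ones(230, int))
        cs = metrics.build_aligned_curves({12.8: b, 25.6: b}, window=0.6)
        curve = cs.curves[12.8]
        # lags longer than 20 steps are supported only by the 80 late
        # deciders (< min_count), so the curve shrinks to short lags
        assert np.isnan(curve[0])
        assert not np.isnan(curve[-1])
        assert cs.counts[12.8][-1] == 230

    def test_zero_coherence_uses_chosen_right(self):
        n_steps = 50
        dsr = np.zeros((300, n_steps))
        actions = np.array([1, -1] * 150)
        b = make_batch(
            dsr, np.full(300, n_steps), actions, mus=np.zeros(300), coherence=0.0
        )
        cs = metrics.build_aligned_curves({0.0: b, 12.8: b}, window=0.2, min_count=50)
        assert 0.0 in cs.curves
        assert cs.counts[0.0][-1] == 150  # only the 'right' choosers


class TestSignalNeutrality:
    def _curves(self, arrays, dt=0.01):
        L = len(arrays[0])
        lags = -dt * np.arange(L)[::-1]
        return metrics.AlignedCurveSet(
            lags=lags,
            curves={float(i): np.asarray(a, float) for i, a in enumerate(arrays)},
            counts={float(i): np.full(L, 1000) for i in range(len(arrays))},
            min_count=100,
        )

    def test_identical_curves_capped(self):
        c = np.linspace(0, 1, 30)
        assert metrics.signal_neutrality(self._curves([c, c, c])) == pytest.approx(
            metrics.DEGENERACY_CAP
        )

    def test_constant_curves_at_extremes(self):
        cs = self._curves([np.zeros(30), np.ones(30)])
        assert metrics.signal_neutrality(cs) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(size=40) for _ in range(4)]
        base = metrics.signal_neutrality(self._curves(arrays))
        scaled = metrics.signal_neutrality(
            self._curves([3.7 * a - 1.2 for a in arrays])
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_needs_two_curves(self):
        with pytest.raises(ValueError):
            metrics.signal_neutrality(self._curves([np.zeros(10)]))


class TestCV:
    def test_exponential_cv_approaches_one(self):
        x = np.random.default_rng(0).exponential(2.0, 200_000)
        assert metrics.cv(x) == pytest.approx(1.0, abs=0.01)

    def test_gamma_shape_four(self):
        x = np.random.default_rng(1).gamma(4.0, 1.0, 200_000)
        assert metrics.cv(x) == pytest.approx(0.5, abs=0.01)

    def test_constant_is_zero(self):
        assert metrics.cv(np.full(10, 3.0)) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            metrics.cv(np.array([1.0]))


class TestScalarProperty:
    def test_hand_value(self):
        # two-point samples {m - s, m + s}: mean m, sample std s sqrt(2)
        set_a = np.array([1 - 0.4 / np.sqrt(2), 1 + 0.4 / np.sqrt(2)])  # CV 0.4
        set_b = np.array([1 - 0.6 / np.sqrt(2), 1 + 0.6 / np.sqrt(2)])  # CV 0.6
        assert metrics.scalar_property({3.2: set_a, 51.2: set_b}) == pytest.approx(
            5.0
        )

    def test_identical_distributions_capped(self):
        x = np.array([0.5, 1.0, 1.5])
        assert metrics.scalar_property({1.0: x, 2.0: x}) == pytest.approx(
            metrics.DEGENERACY_CAP
        )

    def test_needs_two_valid(self):
        with pytest.raises(ValueError):
            metrics.scalar_property({1.0: np.array([1.0, 2.0])})


class TestGammaFit:
    @pytest.mark.parametrize("shape", [1.0, 3.0, 10.0])
    def test_parameter_recovery(self, shape):
        rts = np.random.default_rng(33).gamma(shape, 0.2, 10_000)
        fit = metrics.gamma_fit(rts)
        assert fit["shape"] == pytest.approx(shape, rel=0.05)
        assert fit["cv"] == pytest.approx(1 / np.sqrt(fit["shape"]), abs=1e-12)

    def test_unit_mean_rescaling(self):
        rts = np.random.default_rng(7).gamma(3.0, 0.2, 5_000)
        fit = metrics.gamma_fit(rts)
        x = np.linspace(0, 20, 400_000)
        mean = np.trapezoid(x * fit["unit_mean_pdf"](x), x)
        assert mean == pytest.approx(1.0, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            metrics.gamma_fit(np.ones(10))  # too few
        with pytest.raises(ValueError):
            metrics.gamma_fit(np.concatenate([np.ones(60), [-1.0]]))


class TestPerformanceCurves:
    def test_random_policy_is_at_chance(self):
        """A zero-weight agent picks sides uniformly: accuracy 0.5 up to
        binomial error at every coherence."""
        task = TaskParams()
        params = AgentParams.zeros(make_grid())
        batches = {}
        from taubank.task import coherence_to_mu

        for c in (6.4, 25.6):
            mus = np.random.default_rng(int(c * 10)).choice([-1, 1], 3000) * (
                coherence_to_mu(c)
            )
            batches[c] = run_batch(params, task, mus, seed=int(c * 100))
        perf = metrics.performance_curves(batches)
        for c in (6.4, 25.6):
            acc = perf.loc[c, "accuracy"]
            assert acc == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 3000))

    def test_zero_coherence_has_nan_accuracy(self):
        task = TaskParams()
        params = AgentParams.zeros(make_grid())
        b = run_batch(params, task, np.zeros(500), seed=5, coherence=0.0)
        perf = metrics.performance_curves({0.0: b})
        assert np.isnan(perf.loc[0.0, "accuracy"])
        assert perf.loc[0.0, "n_decided"] > 0


class TestBoundaryStrip:
    def test_no_clock_threshold_constant(self):
        g = make_grid()
        p = AgentParams.zeros(g, b_wait=2.0)
        rng = np.random.default_rng(0)
        p.theta_s[2] = rng.normal(size=10)
        n_ep, n_steps = 400, 100
        dsr = rng.normal(size=(n_ep, n_steps))
        steps = rng.integers(10, n_steps, n_ep)
        b = make_batch(dsr, steps, np.ones(n_ep, int), dt=0.01)
        strip = metrics.boundary_strip({12.8: b}, p, bin_width=0.1)
        assert np.allclose(strip.ds_c, 2.0)  # b_wait - b_right, flat in time

    def test_sparse_bins_flagged(self):
        g = make_grid(3, 0.1, 1.0)
        p = AgentParams.zeros(g)
        n_ep, n_steps = 30, 50
        dsr = np.random.default_rng(2).normal(size=(n_ep, n_steps))
        steps = np.full(n_ep, 25)  # all decisions in one bin
        b = make_batch(dsr, steps, np.ones(n_ep, int))
        strip = metrics.boundary_strip({12.8: b}, p, bin_width=0.05, min_decisions=20)
        assert np.isnan(strip.lo).sum() == strip.lo.size - 1
        filled = ~np.isnan(strip.lo)
        assert strip.counts[filled][0] == 30
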