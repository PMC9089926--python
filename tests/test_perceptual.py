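"""RBM units, Contrastive Divergence, the mixed CD/REINFORCE rule, DBN passes."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.special import expit

from catperc import perceptual as pc


def _layer(W, use_bias=False):
    W = np.asarray(W, dtype=float)
    return pc.RbmLayer(
        W=W, b_vis=np.zeros(W.shape[1]), b_hid=np.zeros(W.shape[0]), use_bias=use_bias
    )


class TestUnitPotentials:
    def test_zero_weights_give_zero_potentials(self):
        layer = _layer(np.zeros((3, 4)))
        assert np.array_equal(pc.unit_potentials(layer, np.ones(4), "up"), np.zeros(3))

    def test_matches_hand_matrix_product(self):
        W = np.arange(6, dtype=float).reshape(3, 2)
        layer = _layer(W)
        p = pc.unit_potentials(layer, np.array([1.0, 0.0]), "up")
        assert np.array_equal(p, W[:, 0])
        down = pc.unit_potentials(layer, np.array([0.0, 1.0, 0.0]), "down")
        assert np.array_equal(down, W[1])

    def test_bias_added_when_enabled(self):
        layer = _layer(np.zeros((2, 2)), use_bias=True)
        layer.b_hid[:] = [1.0, -1.0]
        assert np.array_equal(pc.unit_potentials(layer, np.zeros(2), "up"), [1.0, -1.0])

    def test_dimension_mismatch_rejected(self):
        layer = _layer(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            pc.unit_potentials(layer, np.zeros(3), "up")
        with pytest.raises(ValueError):
            pc.unit_potentials(layer, np.zeros(4), "down")


class TestSampleBernoulli:
    def test_zero_potential_fires_half_the_time(self, rng):
        draws = np.array([pc.sample_bernoulli(np.zeros(1), rng)[0] for _ in range(10000)])
        # binomial 99% CI around 0.5 for n=10,000 is roughly +/- 0.013
        assert abs(draws.mean() - 0.5) < 0.02

    def test_saturated_potential_always_fires(self, rng):
        draws = [pc.sample_bernoulli(np.array([20.0]), rng)[0] for _ in range(1000)]
        assert all(d == 1.0 for d in draws)

    def test_frequencies_track_sigmoid(self, rng):
        pot = np.array([0.0, 2.0, -2.0])
        freq = np.mean([pc.sample_bernoulli(pot, rng) for _ in range(20000)], axis=0)
        assert np.allclose(freq, expit(pot), atol=0.02)

    def test_uniform_vector_replay(self):
        u = np.random.default_rng(3).random(5)
        a = pc.sample_bernoulli(np.linspace(-1, 1, 5), u)
        b = pc.sample_bernoulli(np.linspace(-1, 1, 5), u)
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0.0, 1.0}


class TestContrastiveDivergence:
    def test_seeded_statistics_replay(self):
        layer = _layer(np.random.default_rng(0).normal(size=(3, 4)))
        v = np.array([1.0, 0, 1, 0])
        s1 = pc.cd1_statistics(layer, v, np.random.default_rng(1))
        s2 = pc.cd1_statistics(layer, v, np.random.default_rng(1))
        assert np.array_equal(s1.pos, s2.pos) and np.array_equal(s1.neg, s2.neg)

    def test_perfect_reconstruction_is_a_fixed_point(self, rng):
        # saturated symmetric weights reproduce v=(1,0) deterministically
        layer = _layer([[40.0, -40.0], [-40.0, 40.0]])
        v = np.array([1.0, 0.0])
        stats = pc.cd1_statistics(layer, v, rng)
        assert np.array_equal(stats.pos, stats.neg)
        delta = pc.cd_update(layer, v, eps=0.5, rng=rng)
        assert np.all(delta.dW == 0)

    def test_update_linear_in_eps(self):
        layer = _layer(np.random.default_rng(2).normal(size=(2, 3)))
        v = np.array([1.0, 1, 0])
        u = np.random.default_rng(5).random(2 + 3 + 2)
        d1 = pc.cd_update(layer, v, eps=0.01, rng=u)
        d2 = pc.cd_update(layer, v, eps=0.02, rng=u)
        assert np.allclose(d2.dW, 2 * d1.dW)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """CD-1 expected update on a 3-visible/2-hidden RBM vs brute force.

        The oracle enumerates all hidden and reconstructed-visible
        configurations; the Monte-Carlo mean over 50,000 seeded draws
        must agree within 3 standard errors elementwise.
        """
        W = np.array([[0.5, -0.3, 0.8], [-0.6, 0.4, 0.2]])
        layer = _layer(W)
        v = np.array([1.0, 0.0, 1.0])

        # oracle: E[pos] and E[neg] by exhaustive enumeration
        p_h = expit(W @ v)
        e_pos = np.outer(p_h, v)
        e_neg = np.zeros_like(W)
        for h in itertools.product([0, 1], repeat=2):
            h = np.array(h, dtype=float)
            ph = np.prod(np.where(h == 1, p_h, 1 - p_h))
            p_v = expit(W.T @ h)
            for vm in itertools.product([0, 1], repeat=3):
                vm = np.array(vm, dtype=float)
                pv = np.prod(np.where(vm == 1, p_v, 1 - p_v))
                e_neg += ph * pv * np.outer(expit(W @ vm), vm)

        n = 50000
        rng = np.random.default_rng(99)
        pos = np.zeros_like(W)
        negs = np.zeros((n,) + W.shape)
        for k in range(n):
            stats = pc.cd1_statistics(layer, v, rng)
            pos += stats.pos
            negs[k] = stats.neg
        pos /= n
        neg_mean = negs.mean(axis=0)
        neg_se = negs.std(axis=0) / np.sqrt(n)
        pos_se = np.sqrt(e_pos * (1 - e_pos) / n)
        assert np.all(np.abs(pos - e_pos) <= 3 * pos_se + 1e-12)
        assert np.all(np.abs(neg_mean - e_neg) <= 3 * neg_se + 1e-12)


class TestMixedUpdate:
    def _setup(self, seed=0, use_bias=False):
        gen = np.random.default_rng(seed)
        layer = _layer(gen.normal(scale=0.5, size=(2, 3)), use_bias=use_bias)
        v = np.array([1.0, 0, 1])
        pot = pc.unit_potentials(layer, v, "up")
        y = pc.sample_bernoulli(pot, gen)
        u = gen.random(3 + 2)
        return layer, v, y, pot, u

    def test_lambda_one_reproduces_pure_cd_and_ignores_reward(self):
        layer, v, y, pot, u = self._setup()
        cfg = pc.LearnConfig(lambda_mix=1.0, eps=0.05)
        d_a = pc.mixed_update(layer, v, e=0.7, y=y, potentials=pot, cfg=cfg, rng=u)
        d_b = pc.mixed_update(layer, v, e=-0.3, y=y, potentials=pot, cfg=cfg, rng=u)
        assert np.array_equal(d_a.dW, d_b.dW)
        # manual CD delta reusing y as the data-phase hidden sample
        p_v = expit(layer.W.T @ y)
        vm = (u[:3] < p_v).astype(float)
        hm = (u[3:] < expit(layer.W @ vm)).astype(float)
        expected = 0.05 * (np.outer(y, v) - np.outer(hm, vm))
        assert np.allclose(d_a.dW, expected)

    def test_lambda_zero_with_zero_surprise_is_inert(self):
        layer, v, y, pot, u = self._setup()
        cfg = pc.LearnConfig(lambda_mix=0.0)
        delta = pc.mixed_update(layer, v, e=0.0, y=y, potentials=pot, cfg=cfg, rng=u)
        assert np.all(delta.dW == 0)

    @pytest.mark.parametrize("lam", [0.0, 0.001, 0.01, 0.1, 0.5, 0.9, 1.0])
    def test_exact_convex_combination(self, lam):
        layer, v, y, pot, u = self._setup(seed=4)
        kw = dict(v_data=v, e=0.4, y=y, potentials=pot, rng=u)
        d_cd = pc.mixed_update(layer, cfg=pc.LearnConfig(1.0), **kw)
        d_rl = pc.mixed_update(layer, cfg=pc.LearnConfig(0.0), **kw)
        d_mix = pc.mixed_update(layer, cfg=pc.LearnConfig(lam), **kw)
        assert np.allclose(d_mix.dW, lam * d_cd.dW + (1 - lam) * d_rl.dW, rtol=0, atol=1e-15)

    def test_sigmoid_and_potential_eligibility_factors(self):
        layer, v, y, pot, u = self._setup(seed=7)
        d_sig = pc.mixed_update(
            layer, v, 0.5, y, pot, pc.LearnConfig(0.0, alpha=0.1, rl_factor="sigmoid"), u
        )
        d_pot = pc.mixed_update(
            layer, v, 0.5, y, pot, pc.LearnConfig(0.0, alpha=0.1, rl_factor="potential"), u
        )
        assert np.allclose(d_sig.dW, 0.1 * 0.5 * np.outer(y - expit(pot), v))
        assert np.allclose(d_pot.dW, 0.1 * 0.5 * np.outer(y - pot, v))

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            pc.LearnConfig(lambda_mix=1.5)
        with pytest.raises(ValueError):
            pc.LearnConfig(lambda_mix=-0.1)


@given(hst.floats(min_value=0.0, max_value=1.0))
def test_convex_combination_property(lam):
    gen = np.random.default_rng(11)
    layer = _layer(gen.normal(scale=0.3, size=(3, 4)))
    v = np.array([1.0, 0, 1, 1])
    pot = pc.unit_potentials(layer, v, "up")
    y = pc.sample_bernoulli(pot, gen)
    u = gen.random(4 + 3)
    kw = dict(v_data=v, e=-0.25, y=y, potentials=pot, rng=u)
    d_cd = pc.mixed_update(layer, cfg=pc.LearnConfig(1.0), **kw)
    d_rl = pc.mixed_update(layer, cfg=pc.LearnConfig(0.0), **kw)
    d_mix = pc.mixed_update(layer, cfg=pc.LearnConfig(lam), **kw)
    assert np.allclose(d_mix.dW, lam * d_cd.dW + (1 - lam) * d_rl.dW, rtol=0, atol=1e-15)


class TestDbnPasses:
    def _dbn(self, h1=4, h2=3, seed=0, scale=0.5):
        gen = np.random.default_rng(seed)
        rbm1 = pc.RbmLayer.init(6, h1, gen, scale=scale, use_bias=False)
        rbm2 = pc.RbmLayer.init(h1, h2, gen, scale=scale, use_bias=False)
        return pc.Dbn(rbm1, rbm2)

    def test_stack_size_mismatch_rejected(self):
        gen = np.random.default_rng(0)
        rbm1 = pc.RbmLayer.init(6, 4, gen)
        rbm2 = pc.RbmLayer.init(5, 3, gen)
        with pytest.raises(ValueError):
            pc.Dbn(rbm1, rbm2)

    def test_meanfield_encode_deterministic_and_sample_replayable(self):
        dbn = self._dbn()
        v = np.array([1.0, 0, 1, 0, 1, 1])
        a = pc.dbn_encode(dbn, v, "meanfield")
        b = pc.dbn_encode(dbn, v, "meanfield")
        assert np.array_equal(a, b)
        s1 = pc.dbn_encode(dbn, v, "sample", np.random.default_rng(5))
        s2 = pc.dbn_encode(dbn, v, "sample", np.random.default_rng(5))
        assert np.array_equal(s1, s2)
        assert set(np.unique(s1)) <= {0.0, 1.0}

    def test_zero_weights_give_half_activations(self):
        dbn = self._dbn(scale=1e-30)
        v = np.ones(6)
        top = pc.dbn_encode(dbn, v, "meanfield")
        recon = pc.dbn_reconstruct(dbn, v)
        assert np.allclose(top, 0.5)
        assert np.allclose(recon, 0.5)

    def test_reconstruct_batch_matches_single(self, dataset, retinas, fast_rbm1):
        gen = np.random.default_rng(1)
        rbm2 = pc.RbmLayer.init(fast_rbm1.hidden_size, 5, gen, use_bias=False)
        dbn = pc.Dbn(fast_rbm1.copy(), rbm2, rbm1_pretrained=True)
        batch = pc.reconstruct_batch(dbn, retinas[:3])
        for i in range(3):
            assert np.allclose(batch[i], pc.dbn_reconstruct(dbn, retinas[i]))
        assert np.all(batch >= 0) and np.all(batch <= 1)


class TestPretraining:
    def test_zero_epochs_leave_weights_unchanged(self, retinas):
        rbm = pc.RbmLayer.init(retinas.shape[1], 8, np.random.default_rng(0))
        before = rbm.W.copy()
        trace = pc.pretrain_rbm1(rbm, retinas, 0, 0.01, np.random.default_rng(1))
        assert trace == [] and np.array_equal(rbm.W, before)

    def test_error_drops_and_same_seed_is_identical(self, retinas):
        def train():
            rbm = pc.RbmLayer.init(retinas.shape[1], 32, np.random.default_rng(0))
            trace = pc.pretrain_rbm1(rbm, retinas, 30, 0.01, np.random.default_rng(1))
            return rbm, trace

        rbm_a, trace_a = train()
        rbm_b, trace_b = train()
        assert np.array_equal(rbm_a.W, rbm_b.W)
        assert trace_a[-1] < trace_a[0]

    def test_engines_agree(self, retinas):
        rbm_nb = pc.RbmLayer.init(retinas.shape[1], 6, np.random.default_rng(2))
        rbm_np = pc.RbmLayer.init(retinas.shape[1], 6, np.random.default_rng(2))
        t_nb = pc.pretrain_rbm1(rbm_nb, retinas, 2, 0.02, np.random.default_rng(3), engine="numba")
        t_np = pc.pretrain_rbm1(rbm_np, retinas, 2, 0.02, np.random.default_rng(3), engine="numpy")
        assert np.allclose(rbm_nb.W, rbm_np.W, atol=1e-12)
        assert np.allclose(t_nb, t_np)
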