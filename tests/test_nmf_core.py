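"""Unit and property tests for the factorization lineage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ocnmf import (
    ConvolutiveBasis,
    FactorizationConfig,
    beta_divergence,
    cnmf_train,
    conv_model,
    nmf_fit,
    normalize_columns,
    ocnmf_fit,
    onmf_update_noise_basis,
    orthogonality_penalty,
    phi,
    scnmf_fit,
    shift_left,
    shift_right,
    snmf_fit,
)
from ocnmf.nmf_core import _normalize_cols, cnmf_train_result


def brute_force_conv(basis: np.ndarray, act: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the convolutive model (independent oracle)."""
    k, f, r = basis.shape
    _, t = act.shape
    z = np.zeros((f, t))
    for tau in range(k):
        for j in range(r):
            for tt in range(t):
                if tt - tau >= 0:
                    z[:, tt] += basis[tau, :, j] * act[j, tt - tau]
    return z


class TestBetaDivergence:
    def test_identity_is_zero(self, rng):
        y = rng.random((6, 7)) + 0.1
        for beta in (0.0, 1.0, 2.0, 0.5, 3.0):
            assert beta_divergence(y, y, beta) == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_hand_value(self):
        # (3 - 1)^2 / 2
        assert beta_divergence([[3.0]], [[1.0]], 2.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0, 1.5])
    def test_nonnegative(self, rng, beta):
        y = rng.random((5, 5)) + 0.05
        x = rng.random((5, 5)) + 0.05
        assert beta_divergence(y, x, beta) >= 0.0

    def test_limit_forms_match_generic_nearby(self, rng):
        """The beta=0,1 limit forms agree with the generic formula at
        neighbouring beta values (continuity of the divergence family)."""
        y = rng.random((4, 4)) + 0.5
        x = rng.random((4, 4)) + 0.5
        for b0, eps in ((1.0, 1e-6), (0.0, 1e-6)):
            exact = beta_divergence(y, x, b0)
            near = beta_divergence(y, x, b0 + eps)
            assert near == pytest.approx(exact, rel=1e-4)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            beta_divergence(np.ones((2, 2)), np.ones((2, 3)), 2.0)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            beta_divergence(np.array([[np.inf]]), np.ones((1, 1)), 2.0)


def test_phi_piecewise():
    assert phi(2.0) == 1.0
    assert phi(0.0) == 0.5
    assert phi(3.0) == 0.5
    assert phi(1.0) == 1.0
    assert phi(-1.0) == pytest.approx(1.0 / 3.0)


class TestShifts:
    def test_shift_right_example(self):
        m = np.array([[1.0, 2, 3], [4, 5, 6]])
        out = shift_right(m, 1)
        assert np.array_equal(out, [[0, 1, 2], [0, 4, 5]])

    def test_shift_left_example(self):
        assert np.array_equal(shift_left(np.array([[1.0, 2, 3]]), 1), [[2, 3, 0]])

    def test_negative_tau_raises(self):
        with pytest.raises(ValueError):
            shift_right(np.ones((2, 2)), -1)
        with pytest.raises(ValueError):
            shift_left(np.ones((2, 2)), -1)

    @settings(deadline=None, max_examples=40)
    @given(
        m=arrays(np.float64, (3, 6), elements=st.floats(0, 10)),
        tau=st.integers(0, 8),
    )
    def test_composition_and_shape(self, m, tau):
        """shift_left(shift_right(m, tau), tau) zeroes the last tau columns
        and leaves the rest intact; shapes are always preserved."""
        back = shift_left(shift_right(m, tau), tau)
        assert back.shape == m.shape
        expect = m.copy()
        expect[:, max(m.shape[1] - tau, 0) :] = 0.0
        assert np.array_equal(back, expect)

    def test_tau_beyond_width_gives_zero(self):
        assert not shift_right(np.ones((2, 3)), 5).any()


class TestConvModel:
    def test_k1_is_plain_product(self, rng):
        b = rng.random((1, 5, 3))
        a = rng.random((3, 7))
        assert np.allclose(conv_model(b, a), b[0] @ a)

    def test_hand_example(self):
        basis = np.array([[[1.0], [0.0]], [[0.0], [1.0]]])  # K=2, F=2, R=1
        act = np.array([[1.0, 0.0, 0.0]])
        assert np.array_equal(conv_model(basis, act), [[1, 0, 0], [0, 1, 0]])

    def test_zero_activation(self, rng):
        assert not conv_model(rng.random((2, 4, 3)), np.zeros((3, 6))).any()

    def test_matches_brute_force(self):
        """Stacked-matmul evaluation agrees with the triple-loop oracle."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            k, f, rr, t = (int(r.integers(1, 7)) for _ in range(4))
            b = r.random((k, f, rr))
            a = r.random((rr, t))
            assert np.allclose(conv_model(b, a), brute_force_conv(b, a), rtol=1e-12)


class TestNormalizeColumns:
    def test_direct_value(self):
        b = normalize_columns(np.array([[[3.0], [4.0]]]))
        assert np.allclose(b.values[0, :, 0], [0.6, 0.8])
        assert b.normalized

    def test_idempotent(self, rng):
        b = normalize_columns(rng.random((2, 6, 4)))
        again = normalize_columns(b)
        assert np.allclose(b.values, again.values)

    def test_zero_column_stays_zero(self):
        b = normalize_columns(np.zeros((1, 4, 2)))
        assert not b.values.any()
        assert np.all(np.isfinite(b.values))


class TestNmfFit:
    def test_rank_one_input_recovered(self):
        """A rank-1 spectrogram is exactly representable at R=1, so the
        objective collapses by many orders of magnitude."""
        r = np.random.default_rng(5)
        y = np.outer(r.random(12) + 0.5, r.random(20) + 0.5)
        cfg = FactorizationConfig(R=1, K=1, beta=2.0, iters_train=300, seed=2)
        res = nmf_fit(y, cfg)
        # reference scale: divergence of the best constant model
        baseline = beta_divergence(y, np.full_like(y, y.mean()), 2.0)
        assert res.objective_trace[-1] < 1e-6 * baseline

    def test_zero_input(self):
        cfg = FactorizationConfig(R=2, iters_train=10, seed=0)
        res = nmf_fit(np.zeros((6, 8)), cfg)
        assert np.all(res.signal_basis.values >= 0)
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0])
    def test_factors_stay_nonnegative(self, small_spectrogram, beta):
        cfg = FactorizationConfig(R=4, beta=beta, iters_train=25, seed=3)
        res = nmf_fit(small_spectrogram, cfg)
        assert np.all(res.signal_basis.values >= 0)
        assert np.all(res.signal_activation.values >= 0)
        assert np.all(np.isfinite(res.objective_trace))

    def test_monotone_objective_beta2(self, small_spectrogram):
        cfg = FactorizationConfig(R=4, beta=2.0, iters_train=150, seed=11)
        tr = nmf_fit(small_spectrogram, cfg).objective_trace
        rel = np.diff(tr) / np.maximum(tr[:-1], 1e-300)
        assert rel.max() <= 1e-10

    def test_deterministic(self, small_spectrogram):
        cfg = FactorizationConfig(R=4, iters_train=15, seed=9)
        a = nmf_fit(small_spectrogram, cfg)
        b = nmf_fit(small_spectrogram, cfg)
        assert np.array_equal(a.signal_basis.values, b.signal_basis.values)
        assert np.array_equal(a.objective_trace, b.objective_trace)


class TestCnmfTrain:
    def test_columns_unit_norm(self, small_spectrogram, tiny_cfg):
        basis = cnmf_train(small_spectrogram, tiny_cfg)
        norms = np.linalg.norm(basis.values, axis=1)
        assert np.allclose(norms, 1.0)

    def test_shifting_template_reconstructed(self):
        """A spectrogram built from one time-shifting spectral template lies
        in the convolutive model class, so training recovers it almost
        exactly (divergence below 1% of the spectrogram mass)."""
        r = np.random.default_rng(3)
        k, f, t = 3, 16, 60
        true_basis = r.random((k, f, 1)) * 0.5 + 0.1
        true_act = (r.random((1, t)) > 0.5) * (r.random((1, t)) + 0.2)
        y = conv_model(true_basis, true_act) + 1e-6
        cfg = FactorizationConfig(R=1, K=k, beta=2.0, iters_train=500, seed=4)
        res = cnmf_train_result(y, cfg)
        z = conv_model(res.signal_basis, res.signal_activation)
        assert beta_divergence(y, z, 2.0) < 0.01 * y.sum()

    def test_k1_equals_flat_pretraining(self, small_spectrogram):
        """With one shift the convolutive trainer must reproduce the flat
        NMF pre-training run exactly (shared seed, element-wise)."""
        cfg = FactorizationConfig(R=4, K=1, beta=2.0, iters_train=30, seed=6)
        conv = cnmf_train_result(small_spectrogram, cfg)
        flat = nmf_fit(small_spectrogram, cfg, normalize_basis=True)
        assert np.array_equal(conv.signal_basis.values, flat.signal_basis.values)
        assert np.array_equal(
            conv.signal_activation.values, flat.signal_activation.values
        )
        assert np.array_equal(conv.objective_trace, flat.objective_trace)


def _random_unit_basis(rng, k, f, r):
    return ConvolutiveBasis(
        np.stack([_normalize_cols(rng.random((f, r)) + 0.05, 1e-12) for _ in range(k)]),
        normalized=True,
    )


class TestSemiSupervised:
    def test_noiseless_input_mostly_signal(self):
        """On input generated exactly by the signal model, the noise term
        should end up carrying a small share of the reconstruction."""
        r = np.random.default_rng(11)
        basis = _random_unit_basis(r, 3, 20, 4)
        u_true = r.random((4, 50)) * (r.random((4, 50)) > 0.5)
        y = conv_model(basis, u_true) + 1e-8
        cfg = FactorizationConfig(R=4, J=3, K=3, beta=2.0, iters_analysis=300, seed=0)
        res = scnmf_fit(y, basis, cfg)
        z_sig = conv_model(res.signal_basis, res.signal_activation)
        z_noise = conv_model(res.noise_basis, res.noise_activation)
        frac = np.linalg.norm(z_noise) / np.linalg.norm(z_sig + z_noise)
        assert frac < 0.1

    def test_factors_nonnegative_and_unit_norm(self, small_spectrogram, tiny_cfg, rng):
        basis = _random_unit_basis(rng, tiny_cfg.K, 24, tiny_cfg.R)
        res = ocnmf_fit(small_spectrogram, basis, tiny_cfg)
        assert np.all(res.noise_basis.values >= 0)
        assert np.all(res.noise_activation.values >= 0)
        assert np.all(res.signal_activation.values >= 0)
        norms = np.linalg.norm(res.noise_basis.values, axis=1)
        assert np.allclose(norms, 1.0)

    def test_scnmf_k1_equals_flat_snmf(self, small_spectrogram, rng):
        cfg = FactorizationConfig(R=4, J=3, K=1, beta=2.0, iters_analysis=30, seed=5)
        basis = _random_unit_basis(rng, 1, 24, 4)
        conv = scnmf_fit(small_spectrogram, basis, cfg)
        flat = snmf_fit(small_spectrogram, basis.values[0], cfg)
        assert np.array_equal(conv.noise_basis.values, flat.noise_basis.values)
        assert np.array_equal(conv.objective_trace, flat.objective_trace)

    def test_ocnmf_mu0_equals_scnmf(self, small_spectrogram, rng):
        cfg = FactorizationConfig(
            R=4, J=3, K=3, beta=2.0, mu=0.0, iters_analysis=30, seed=5
        )
        basis = _random_unit_basis(rng, 3, 24, 4)
        a = ocnmf_fit(small_spectrogram, basis, cfg)
        b = scnmf_fit(small_spectrogram, basis, cfg)
        assert np.array_equal(a.noise_basis.values, b.noise_basis.values)
        assert np.array_equal(a.objective_trace, b.objective_trace)

    def test_ocnmf_k1_equals_flat_onmf(self, small_spectrogram, rng):
        cfg = FactorizationConfig(
            R=4, J=3, K=1, beta=2.0, mu=1e4, iters_analysis=30, seed=5
        )
        basis = _random_unit_basis(rng, 1, 24, 4)
        conv = ocnmf_fit(small_spectrogram, basis, cfg)
        flat = snmf_fit(small_spectrogram, basis.values[0], cfg, mu=1e4)
        assert np.array_equal(conv.noise_basis.values, flat.noise_basis.values)
        assert np.array_equal(conv.objective_trace, flat.objective_trace)

    def test_k_mismatch_raises(self, small_spectrogram, rng, tiny_cfg):
        basis = _random_unit_basis(rng, tiny_cfg.K + 1, 24, tiny_cfg.R)
        with pytest.raises(ValueError):
            scnmf_fit(small_spectrogram, basis, tiny_cfg)

    def test_deterministic(self, small_spectrogram, rng, tiny_cfg):
        basis = _random_unit_basis(rng, tiny_cfg.K, 24, tiny_cfg.R)
        a = ocnmf_fit(small_spectrogram, basis, tiny_cfg)
        b = ocnmf_fit(small_spectrogram, basis, tiny_cfg)
        assert np.array_equal(a.noise_basis.values, b.noise_basis.values)
        assert np.array_equal(a.signal_activation.values, b.signal_activation.values)
        assert np.array_equal(a.objective_trace, b.objective_trace)


class TestOnmfStep:
    def _setup(self, seed=0):
        r = np.random.default_rng(seed)
        f = r.random((10, 3))
        h = _normalize_cols(r.random((10, 4)), 1e-12)
        g = r.random((3, 12))
        u = r.random((4, 12))
        y = r.random((10, 12)) + 0.1
        return f, h, g, u, y

    def test_mu_zero_equals_plain_step(self):
        f, h, g, u, y = self._setup()
        constrained = onmf_update_noise_basis(f, h, g, u, y, 2.0, 0.0)
        plain = onmf_update_noise_basis(f, np.zeros_like(h), g, u, y, 2.0, 1e6)
        # with mu=0 and with a zero signal basis the penalty vanishes alike
        z = h @ u + f @ g
        expected = f * ((y @ g.T) / np.maximum(z @ g.T, 1e-12))
        assert np.allclose(constrained, expected)
        z0 = np.zeros_like(h) @ u + f @ g
        expected0 = f * ((y @ g.T) / np.maximum(z0 @ g.T, 1e-12))
        assert np.allclose(plain, expected0)

    def test_large_mu_shrinks_f(self):
        f, h, g, u, y = self._setup(1)
        out = onmf_update_noise_basis(f, h, g, u, y, 2.0, 1e12)
        assert np.all(out < f * 1e-3)

    def test_shape_mismatch_raises(self):
        f, h, g, u, y = self._setup(2)
        with pytest.raises(ValueError):
            onmf_update_noise_basis(f[:5], h, g, u, y, 2.0, 0.0)


class TestOrthogonalityEffect:
    def test_penalty_reduced_by_constraint(self, rng):
        """The alignment penalty after a constrained fit is no larger than
        after the unconstrained fit from the same initialisation."""
        y = rng.random((24, 40)) * 2.0
        basis = _random_unit_basis(rng, 2, 24, 4)
        for seed in range(3):
            cfg = FactorizationConfig(
                R=4, J=3, K=2, beta=2.0, mu=1e6, iters_analysis=60, seed=seed
            )
            con = ocnmf_fit(y, basis, cfg)
            unc = scnmf_fit(y, basis, cfg)
            p_con = orthogonality_penalty(basis, con.noise_basis)
            p_unc = orthogonality_penalty(basis, unc.noise_basis)
            assert p_con <= p_unc
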