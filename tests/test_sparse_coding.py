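"""Shrinkage, weights, the three coefficient rules, and the auxiliary /
multiplier updates, each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtbmdu.dictionary import gram_spectral_radius, init_dct_dictionary
from wtbmdu.sparse_coding import (
    code_patches,
    code_step_tbmdu,
    code_step_wl1,
    code_step_wl2,
    compute_weights,
    epsilon_schedule,
    intermediate_y,
    shrink,
    update_multiplier,
    update_z,
)


def shrink_oracle(g, tau):
    mag = np.abs(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(mag > 0, g / np.where(mag > 0, mag, 1.0), 0.0)
    return phase * np.maximum(mag - tau, 0.0)


class TestShrink:
    def test_real_soft_threshold(self):
        assert shrink(2.0, 0.5) == pytest.approx(1.5)
        assert shrink(-2.0, 0.5) == pytest.approx(-1.5)

    def test_dead_zone_is_exact_zero(self, rng):
        g = 0.3 * (rng.standard_normal(100) + 1j * rng.standard_normal(100))
        assert np.all(shrink(g, np.abs(g).max()) == 0)

    def test_complex_phase_preserved(self):
        assert shrink(3.0j, 1.0) == pytest.approx(2.0j)

    def test_matches_closed_form_oracle_on_1000_random_inputs(self, rng):
        g = rng.standard_normal(1000) + 1j * rng.standard_normal(1000)
        tau = np.abs(rng.standard_normal(1000))
        assert np.abs(shrink(g, tau) - shrink_oracle(g, tau)).max() < 1e-12

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            shrink(1.0, -0.1)

    @settings(deadline=None, derandomize=True)
    @given(
        re=st.floats(-1e6, 1e6), im=st.floats(-1e6, 1e6),
        tau=st.floats(0, 1e6),
    )
    def test_magnitude_never_exceeds_input(self, re, im, tau):
        g = complex(re, im)
        out = shrink(g, tau)
        assert abs(out) <= abs(g) + 1e-9
        assert abs(out) <= max(abs(g) - tau, 0.0) + 1e-6 * max(abs(g), 1.0)


class TestWeights:
    def test_p_equal_one_gives_constant_weights(self, rng):
        G = rng.standard_normal((5, 7))
        W = compute_weights(G, 1.0, 0.3, "L1")
        assert np.abs(W - 1.0 / 1.3).max() < 1e-14

    def test_dead_coefficient_gets_maximum_weight(self):
        for variant in ("L1", "L2"):
            W = compute_weights(np.zeros((2, 2)), 0.5, 0.25, variant)
            assert np.abs(W - 4.0).max() < 1e-14

    def test_hand_value_l2(self):
        W = compute_weights(np.array([[2.0]]), 0.7, 0.1, "L2")
        assert W[0, 0] == pytest.approx(1.0 / (2.0**1.3 + 0.1), rel=1e-10)

    def test_monotone_nonincreasing_in_magnitude(self):
        mags = np.linspace(0, 50, 200)[None, :]
        for variant in ("L1", "L2"):
            W = compute_weights(mags, 0.6, 0.05, variant)
            assert np.all(np.diff(W[0]) <= 0)

    def test_bounds(self, rng):
        G = rng.standard_normal((6, 6)) * 10
        W = compute_weights(G, 0.5, 0.2, "L1")
        assert np.all(W > 0) and np.all(W <= 1 / 0.2 + 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="p must be"):
            compute_weights(np.ones((1, 1)), 1.5, 0.1, "L1")
        with pytest.raises(ValueError, match="p must be"):
            compute_weights(np.ones((1, 1)), 0.0, 0.1, "L2")


class TestEpsilonSchedule:
    def test_initial_and_first_decay(self):
        assert epsilon_schedule(0) == pytest.approx(5.0)
        assert epsilon_schedule(1) == pytest.approx(4.9)

    def test_strictly_decreasing_positive(self):
        vals = [epsilon_schedule(t) for t in range(200)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0


class TestIntermediateY:
    def test_zero_coefficients(self, rng):
        D = init_dct_dictionary(9, 1)
        B = rng.standard_normal((9, 4))
        out = intermediate_y(D, np.zeros((9, 4)), B, np.zeros((9, 4)), 12.0, 0.005)
        t0 = 12.0 * 0.005 / 12.005
        assert np.abs(out - t0 * B).max() < 1e-14

    def test_exact_fit_with_zero_multiplier_gives_zero(self, rng):
        D = init_dct_dictionary(9, 1)
        G = rng.standard_normal((9, 4))
        B = D @ G
        out = intermediate_y(D, G, B, np.zeros_like(B), 12.0, 0.005)
        assert np.abs(out).max() < 1e-12

    def test_scalar_hand_arithmetic(self):
        # D=1, alpha=1, b=2, y=0.1, lambda=12, beta=0.005
        lam, beta = 12.0, 0.005
        t0 = lam * beta / (lam + beta)
        out = intermediate_y(np.array([[1.0]]), np.array([[1.0]]),
                             np.array([[2.0]]), np.array([[0.1]]), lam, beta)
        assert out[0, 0] == pytest.approx(t0 * 21.0, rel=1e-12)
        assert t0 == pytest.approx(0.00499792, abs=1e-8)


class TestCodeSteps:
    lam, beta = 12.0, 0.0056

    def _setup(self, rng, M=9, J=9, L=12):
        D = init_dct_dictionary(M, 1)
        gamma = 1.05 * gram_spectral_radius(D)
        G = rng.standard_normal((J, L))
        B = rng.standard_normal((M, L))
        Y = 0.01 * rng.standard_normal((M, L))
        return D, gamma, G, B, Y

    def test_dead_zone_maps_small_state_to_zero(self, rng):
        D, gamma, G, B, Y = self._setup(rng)
        thresh = (self.lam + self.beta) / (gamma * self.lam * self.beta)
        Gs = 0.4 * thresh * rng.uniform(-1, 1, G.shape)
        out = code_step_tbmdu(Gs, D, np.zeros_like(B), self.lam, self.beta, gamma)
        assert np.all(out == 0)

    def test_scalar_reduction_matches_shrink(self, rng):
        lam, beta, gamma = self.lam, self.beta, 1.0
        a, yv = 0.7, 0.2
        out = code_step_tbmdu(np.array([[a]]), np.array([[1.0]]),
                              np.array([[yv]]), lam, beta, gamma)
        c = (lam + beta) / (gamma * lam * beta)
        assert out[0, 0] == pytest.approx(float(shrink(a + c * yv, c)), rel=1e-12)

    def test_unit_weights_reduce_wl1_to_plain(self, rng):
        D, gamma, G, B, Y = self._setup(rng)
        y_imm = intermediate_y(D, G, B, Y, self.lam, self.beta)
        a = code_step_tbmdu(G, D, y_imm, self.lam, self.beta, gamma)
        b = code_step_wl1(G, D, y_imm, self.lam, self.beta, gamma, np.ones_like(G))
        assert np.abs(a - b).max() < 1e-14

    def test_larger_magnitude_gets_smaller_threshold(self):
        W = compute_weights(np.array([[10.0, 0.0]]), 0.5, 0.1, "L1")
        assert W[0, 0] < W[0, 1]

    def test_wl2_scalar_matches_numeric_minimizer(self):
        from scipy.optimize import minimize_scalar

        gamma, lam, beta, Wv, a, dy = 2.0, 12.0, 0.005, 0.5, 1.0, 0.3
        ratio = (lam + beta) / (lam * beta)
        out = code_step_wl2(np.array([[a]]), np.array([[1.0]]), np.array([[dy]]),
                            lam, beta, gamma, np.array([[Wv]]))
        # independent oracle: 1-D minimization of the ridge surrogate
        c = a + ratio * dy / gamma
        res = minimize_scalar(lambda x: gamma * (x - c) ** 2 + ratio * Wv * x**2,
                              bounds=(-10, 10), method="bounded")
        assert out[0, 0] == pytest.approx(res.x, abs=1e-6)

    def test_wl2_vanishing_weights_give_pure_gradient_step(self, rng):
        D, gamma, G, B, Y = self._setup(rng)
        y_imm = intermediate_y(D, G, B, Y, self.lam, self.beta)
        out = code_step_wl2(G, D, y_imm, self.lam, self.beta, gamma,
                            np.zeros_like(G))
        c = (self.lam + self.beta) / (gamma * self.lam * self.beta)
        expect = G + c * (D.T @ y_imm)
        assert np.abs(out - expect).max() < 1e-10

    def test_wl2_ridge_shrinks_toward_zero(self, rng):
        D, gamma, G, B, Y = self._setup(rng)
        out = code_step_wl2(G, D, np.zeros_like(B), self.lam, self.beta, gamma,
                            1e3 * np.ones_like(G))
        assert np.all(np.abs(out) < np.abs(G) + 1e-15)

    @pytest.mark.parametrize("rule", ["tbmdu", "wl1", "wl2"])
    def test_surrogate_descent_on_random_instances(self, rng, rule):
        """One step never increases its own majorized objective when gamma
        dominates the dictionary Gram spectrum (checked on 100 draws)."""
        lam, beta = self.lam, self.beta
        tau = (lam + beta) / (lam * beta)
        for _ in range(100):
            M = 9
            D = rng.standard_normal((M, M))
            D /= np.linalg.norm(D, axis=0)
            gamma = 1.05 * gram_spectral_radius(D)
            G = rng.standard_normal((M, 6))
            C = rng.standard_normal((M, 6))  # coding target b + y/beta
            W = np.abs(rng.standard_normal((M, 6))) + 0.05
            # y' repackages the residual: T0 * (C - D G)
            t0 = lam * beta / (lam + beta)
            y_imm = t0 * (C - D @ G)
            if rule == "tbmdu":
                new = code_step_tbmdu(G, D, y_imm, lam, beta, gamma)
                before = 0.5 * np.linalg.norm(D @ G - C) ** 2 + tau * np.abs(G).sum()
                after = 0.5 * np.linalg.norm(D @ new - C) ** 2 + tau * np.abs(new).sum()
            elif rule == "wl1":
                new = code_step_wl1(G, D, y_imm, lam, beta, gamma, W)
                before = 0.5 * np.linalg.norm(D @ G - C) ** 2 + tau * (W * np.abs(G)).sum()
                after = 0.5 * np.linalg.norm(D @ new - C) ** 2 + tau * (W * np.abs(new)).sum()
            else:
                new = code_step_wl2(G, D, y_imm, lam, beta, gamma, W)
                before = 0.5 * np.linalg.norm(D @ G - C) ** 2 + 0.5 * tau * (W * G**2).sum()
                after = 0.5 * np.linalg.norm(D @ new - C) ** 2 + 0.5 * tau * (W * new**2).sum()
            assert after <= before + 1e-9 * max(1.0, abs(before))

    def test_mm_property_frozen_weights_l2(self, rng):
        """With weights frozen at the current iterate, the weighted ridge
        surrogate does not increase across an update (MM property)."""
        lam, beta = self.lam, self.beta
        tau = (lam + beta) / (lam * beta)
        D = init_dct_dictionary(9, 1)
        gamma = 1.1 * gram_spectral_radius(D)
        G = rng.standard_normal((9, 8))
        C = rng.standard_normal((9, 8))
        W = compute_weights(G, 0.5, 0.1, "L2")
        t0 = lam * beta / (lam + beta)
        new = code_step_wl2(G, D, t0 * (C - D @ G), lam, beta, gamma, W)
        surr = lambda x: 0.5 * np.linalg.norm(D @ x - C) ** 2 + 0.5 * tau * (W * x**2).sum()
        assert surr(new) <= surr(G) + 1e-10


class TestAuxiliaryUpdates:
    def test_update_z_heavy_penalty_limit(self, rng):
        Ru = rng.standard_normal((4, 5))
        D = np.eye(4)
        G = rng.standard_normal((4, 5))
        Z = update_z(Ru, D, G, np.zeros_like(Ru), 1e12, 0.01)
        assert np.abs(Z).max() < 1e-10

    def test_update_z_exact_fit_zero_multiplier(self, rng):
        D = init_dct_dictionary(9, 1)
        G = rng.standard_normal((9, 5))
        Ru = D @ G
        Z = update_z(Ru, D, G, np.zeros_like(Ru), 12.0, 0.005)
        assert np.abs(Z).max() < 1e-12

    def test_update_z_beats_random_perturbations(self, rng):
        lam, beta = 12.0, 0.0056
        D = init_dct_dictionary(9, 1)
        G = rng.standard_normal((9, 6))
        Ru = rng.standard_normal((9, 6))
        Y = 0.1 * rng.standard_normal((9, 6))
        Z = update_z(Ru, D, G, Y, lam, beta)

        def objective(Zc):
            r = Ru - D @ G - Zc + Y / beta
            return 0.5 * lam * np.linalg.norm(Zc) ** 2 + 0.5 * beta * np.linalg.norm(r) ** 2

        base = objective(Z)
        for _ in range(100):
            assert base <= objective(Z + 0.01 * rng.standard_normal(Z.shape)) + 1e-12

    def test_multiplier_fixed_point_and_linearity(self, rng):
        D = init_dct_dictionary(9, 1)
        G = rng.standard_normal((9, 5))
        Z = rng.standard_normal((9, 5))
        Ru = Z + D @ G
        Y = rng.standard_normal((9, 5))
        assert np.abs(update_multiplier(Y, Ru, Z, D, G, 0.1) - Y).max() < 1e-12
        assert np.abs(update_multiplier(Y, Ru + 1, Z, D, G, 0.0) - Y).max() < 1e-12
        r = rng.standard_normal((9, 5))
        two = update_multiplier(update_multiplier(Y, Ru + r, Z, D, G, 0.2),
                                Ru + r, Z, D, G, 0.2)
        assert np.abs(two - (Y + 0.4 * r)).max() < 1e-12


def test_code_patches_recovers_sparse_supports(rng):
    """Patch coding on exactly k-sparse data recovers the true supports."""
    from wtbmdu.operators import extract_patches
    from wtbmdu.synthetic import dict_sparse_phantom

    D = init_dct_dictionary(36, 1)
    img, G_true = dict_sparse_phantom(60, D, k=3, seed=3)
    P = extract_patches(img, 6, 6)
    Gam = code_patches(P, D, lam=100.0, beta=1.0, n_iter=80)
    hits = 0
    for l in range(G_true.shape[1]):
        true_support = set(np.flatnonzero(np.abs(G_true[:, l]) > 0))
        top = set(np.argsort(np.abs(Gam[:, l]))[-3:])
        hits += top == true_support
    assert hits / G_true.shape[1] >= 0.9
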