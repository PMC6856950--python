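"""Unit and property tests for the energy terms and their gradients."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from chromstruct import (
    ContactMatrix,
    EffectiveData,
    ModelParams,
    effective_data,
    energy,
    energy_gradient,
    neg_loglik,
    penalty_smoothness,
    penalty_spacing,
)
from chromstruct.energy import (
    DegenerateCurveError,
    neg_loglik_gradient,
    penalty_smoothness_gradient,
    penalty_spacing_gradient,
)

from helpers import random_rotation


class TestContactMatrix:
    def test_diagonal_zeroed_and_M(self):
        C = ContactMatrix(np.array([[5.0, 2.0], [2.0, 7.0]]))
        assert np.all(np.diag(C.counts) == 0)
        assert C.M == 2.0

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ContactMatrix(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNegLoglik:
    def test_hand_computed_value(self, small_symmetric_counts):
        # three collinear unit-spaced points, c12=2, c13=1, c23=0, a=-1, b=1
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        g = neg_loglik(X, small_symmetric_counts, a=-1.0, b=1.0)
        assert g == pytest.approx(2.5 + np.log(2), rel=1e-12)

    def test_zero_counts_pure_repulsion(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        C = ContactMatrix(np.zeros((4, 4)))
        d = np.array([1.0, 2, 3, 1, 2, 1])
        assert neg_loglik(X, C, a=-3.0, b=1.0) == pytest.approx(np.sum(d**-3.0))

    @pytest.mark.parametrize("gamma", [0.5, 2.0, 3.7])
    def test_scale_nonidentifiability(self, rng, random_contacts, gamma):
        """g(gamma X | C, a, b) = g(X | C, a, gamma^a b) - a M log(gamma)."""
        a = -3.0
        for _ in range(5):
            X = rng.standard_normal((30, 3))
            lhs = neg_loglik(gamma * X, random_contacts, a, b=1.0)
            rhs = neg_loglik(X, random_contacts, a, b=gamma**a * 1.0)
            assert lhs - rhs == pytest.approx(
                -a * random_contacts.M * np.log(gamma), rel=1e-10
            )

    def test_dimension_mismatch(self, random_contacts):
        with pytest.raises(ValueError, match="nodes"):
            neg_loglik(np.zeros((5, 3)), random_contacts, -3.0, 1.0)

    def test_coincident_points_clamped_with_warning(self, small_symmetric_counts):
        X = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.warns(RuntimeWarning, match="clamped"):
            g = neg_loglik(X, small_symmetric_counts, a=-1.0, b=1.0)
        assert np.isfinite(g)


class TestPenaltySpacing:
    @pytest.mark.parametrize("n", [3, 10, 101])
    def test_zero_on_equally_spaced(self, rng, n):
        """h1 attains its minimum 0 on any equal-gap curve, any n."""
        steps = rng.standard_normal((n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        X = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        assert penalty_spacing(X) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [3, 0, 0]])
        # u = (2/3, 4/3); variance over the 2 gaps = 1/9
        assert penalty_spacing(X) == pytest.approx(1.0 / 9.0, rel=1e-12)

    def test_similarity_invariance(self, rng, random_curve):
        base = penalty_spacing(random_curve)
        R = random_rotation(rng, reflect=True)
        X2 = 3.7 * random_curve @ R.T + rng.standard_normal(3)
        assert penalty_spacing(X2) == pytest.approx(base, rel=1e-10)

    def test_collapsed_curve_errors(self):
        with pytest.raises(DegenerateCurveError):
            penalty_spacing(np.zeros((4, 3)))


class TestPenaltySmoothness:
    @pytest.mark.parametrize("n", [3, 10, 101])
    def test_minus_one_on_collinear(self, rng, n):
        """h2 attains its minimum -1 on monotone collinear curves, any gaps."""
        t = np.sort(rng.uniform(0, 10, size=n))
        v = rng.standard_normal(3)
        X = np.outer(t, v) + rng.standard_normal(3)
        assert penalty_smoothness(X) == pytest.approx(-1.0, abs=1e-12)

    def test_right_angle_is_zero(self):
        X = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert penalty_smoothness(X) == pytest.approx(0.0, abs=1e-14)

    def test_fold_back_is_plus_one(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [1e-9, 0, 0]])
        assert penalty_smoothness(X) == pytest.approx(1.0, abs=1e-6)

    def test_bounded(self, rng):
        for _ in range(20):
            X = rng.standard_normal((15, 3))
            assert -1.0 <= penalty_smoothness(X) <= 1.0

    def test_similarity_invariance(self, rng, random_curve):
        base = penalty_smoothness(random_curve)
        R = random_rotation(rng, reflect=False)
        X2 = 0.3 * random_curve @ R.T - 5.0
        assert penalty_smoothness(X2) == pytest.approx(base, rel=1e-10)


class TestEffectiveData:
    def test_zero_mixing_identity(self, random_contacts):
        eff = effective_data(random_contacts, None, 0.0, 2.0)
        assert eff.k == 0.0
        assert eff.b_tilde == 2.0
        assert eff.C_tilde is random_contacts

    def test_direct_substitution(self):
        C = ContactMatrix(np.array([[0, 10.0], [10.0, 0]]))  # M = 10
        Cb = ContactMatrix(np.array([[0, 100.0], [100.0, 0]]))  # M' = 100
        eff = effective_data(C, Cb, lambda3=0.1, b=1.0)
        assert eff.k == pytest.approx(0.01)
        assert eff.b_tilde == pytest.approx(1.01)
        assert np.allclose(eff.C_tilde.counts, C.counts + 0.01 * Cb.counts)

    def test_bulk_absorption_identity(self, rng):
        """g(X|C)/M + (lam3/M') g(X|C') == g(X|C~, b~)/M at random instances."""
        a, b = -3.0, 1.5
        for _ in range(100):
            n = int(rng.integers(5, 15))
            X = rng.standard_normal((n, 3))
            U = np.triu(rng.poisson(3.0, (n, n)), 1)
            C = ContactMatrix(U + U.T)
            Ub = np.triu(rng.poisson(20.0, (n, n)), 1)
            Cb = ContactMatrix(Ub + Ub.T)
            if C.M == 0 or Cb.M == 0:
                continue
            lam3 = float(rng.uniform(0.01, 2.0))
            eff = effective_data(C, Cb, lam3, b)
            lhs = neg_loglik(X, C, a, b) / C.M + lam3 / Cb.M * neg_loglik(X, Cb, a, b)
            rhs = neg_loglik(X, eff.C_tilde, a, eff.b_tilde) / C.M
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_empty_bulk_with_positive_lambda3_errors(self, random_contacts):
        empty = ContactMatrix(np.zeros((30, 30)))
        with pytest.raises(ValueError, match="zero total"):
            effective_data(random_contacts, empty, 0.5, 1.0)

    def test_dimension_mismatch_errors(self, random_contacts):
        other = ContactMatrix(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="bins"):
            effective_data(random_contacts, other, 0.5, 1.0)


class TestEnergy:
    def test_penalties_off_reduces_to_likelihood(self, random_curve, random_contacts):
        p = ModelParams(a=-3.0, b=50.0, lambda1=0.0, lambda2=0.0, lambda3=0.0)
        eff = effective_data(random_contacts, None, 0.0, 50.0)
        E = energy(random_curve, eff, random_contacts.M, p)
        g = neg_loglik(random_curve, random_contacts, -3.0, 50.0)
        assert E == pytest.approx(g / random_contacts.M, rel=1e-12)

    def test_monotone_in_weights(self, random_curve, random_contacts):
        eff = effective_data(random_contacts, None, 0.0, 50.0)
        M = random_contacts.M
        h1 = penalty_spacing(random_curve)
        assert h1 > 0
        E_lo = energy(random_curve, eff, M, ModelParams(-3, 50, 0.1, 0.0, 0.0))
        E_hi = energy(random_curve, eff, M, ModelParams(-3, 50, 1.0, 0.0, 0.0))
        assert E_hi > E_lo

    def test_zero_M_errors(self, random_curve):
        C = ContactMatrix(np.zeros((30, 30)))
        eff = EffectiveData(C_tilde=C, b_tilde=1.0, k=0.0)
        with pytest.raises(ValueError, match="M == 0"):
            energy(random_curve, eff, C.M, ModelParams())

    def test_default_weights_run_end_to_end(self, random_curve, random_contacts):
        p = ModelParams()  # documented defaults lambda = (0.5, 1, 0.1) need a bulk
        eff = effective_data(random_contacts, random_contacts, p.lambda3, p.b)
        E = energy(random_curve, eff, random_contacts.M, p)
        assert np.isfinite(E)


class TestGradients:
    def _fd(self, f, x, eps=1e-6):
        """Central finite differences."""
        g = np.zeros_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = eps
            g[i] = (f(x + e) - f(x - e)) / (2 * eps)
        return g

    @pytest.mark.parametrize(
        "value_fn, grad_fn",
        [
            (penalty_spacing, penalty_spacing_gradient),
            (penalty_smoothness, penalty_smoothness_gradient),
        ],
    )
    def test_penalty_gradients_match_finite_differences(self, rng, value_fn, grad_fn):
        X = rng.standard_normal((25, 3))
        num = self._fd(lambda x: value_fn(x.reshape(-1, 3)), X.ravel())
        ana = grad_fn(X).ravel()
        assert np.max(np.abs(num - ana)) < 1e-6 * max(1.0, np.abs(ana).max())

    def test_likelihood_gradient_matches_finite_differences(self, rng, random_contacts):
        X = rng.standard_normal((30, 3))
        num = self._fd(
            lambda x: neg_loglik(x.reshape(-1, 3), random_contacts, -3.0, 50.0),
            X.ravel(),
        )
        ana = neg_loglik_gradient(X, random_contacts, -3.0, 50.0).ravel()
        assert np.max(np.abs(num - ana)) / np.abs(ana).max() < 1e-5

    def test_full_energy_gradient_oracle_n50(self, rng):
        """Analytic grad(E) vs central differences at n=50, incl. bulk prior."""
        from chromstruct import simulate_contact_matrix

        X0 = rng.standard_normal((50, 3))
        C = simulate_contact_matrix(X0, a=-3.0, b=100.0, seed=3)
        Cb = simulate_contact_matrix(X0, a=-3.0, b=500.0, seed=4)
        p = ModelParams(a=-3.0, b=100.0, lambda1=0.5, lambda2=1.0, lambda3=0.3)
        eff = effective_data(C, Cb, p.lambda3, p.b)
        X = rng.standard_normal((50, 3))
        num = self._fd(
            lambda x: energy(x.reshape(-1, 3), eff, C.M, p), X.ravel(), eps=1e-6
        )
        ana = energy_gradient(X, eff, C.M, p).ravel()
        rel = np.max(np.abs(num - ana)) / np.abs(ana).max()
        assert rel < 1e-5

    def test_penalty_gradients_translation_invariant(self, rng, random_curve):
        """Columns of lam1*grad(h1) + lam2*grad(h2) sum to zero."""
        g = 0.5 * penalty_spacing_gradient(random_curve) + 1.0 * penalty_smoothness_gradient(random_curve)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-12)


class TestModelParams:
    @pytest.mark.parametrize("kw", [{"a": 0.5}, {"b": -1.0}, {"lambda1": -0.1}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)
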