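"""Penalized likelihood: algebraic identities, hand oracles, gradients."""

import numpy as np
import pytest
from scipy.integrate import quad

from smolsurv import autodiff as ad
from smolsurv.bspline import greville_abscissae, second_derivative_gram
from smolsurv.data import LongitudinalCohort, build_batch
from smolsurv.objective import (LossWeights, likelihood_constants, nll,
                                pairwise_constants, phi_tensor, ranking_penalty,
                                reconstruction_penalty, roughness_penalty,
                                total_loss)
from smolsurv.smol import SmolHead, log_density, smol_derivative, survival


def _random_cohort(rng, n=12, d_z=2, d_x=2, horizon=30.0, binary=None):
    times, x, xm = [], [], []
    for _ in range(n):
        J = rng.integers(1, 5)
        tt = np.concatenate([[0.0], np.sort(rng.uniform(0.5, horizon * 0.6, J - 1))])
        times.append(tt)
        xi = rng.standard_normal((J, d_x))
        if binary is not None:
            xi[:, binary] = rng.integers(0, 2, (J, int(np.sum(binary))))
        x.append(xi)
        xm.append((rng.random((J, d_x)) < 0.2).astype(float))
    last = np.array([t[-1] for t in times])
    T = last + rng.uniform(0.1, 5.0, n)
    delta = rng.integers(0, 2, n)
    return LongitudinalCohort(
        z=rng.standard_normal((n, d_z)), z_mask=np.zeros((n, d_z)),
        times=times, x=x, x_mask=xm, T=T, delta=delta,
        binary_x=np.zeros(d_x, dtype=bool) if binary is None else binary,
    )


class TestNll:
    def test_compositional_equals_expanded_form(self, head, rng):
        """The expanded suffix-sum likelihood must equal the compositional
        route (-delta*log density - (1-delta)*log survival) to 1e-10."""
        for _ in range(5):
            cohort = _random_cohort(rng)
            lc = likelihood_constants(cohort, head)
            # away from the positivity floor, where the log-density is
            # infinitely conditioned and float64 cannot hold 1e-10
            o = rng.standard_normal((cohort.n, head.n_basis))
            o[:, 1:] = np.abs(o[:, 1:]) + 0.05
            expanded = float(nll(o, lc, head).value)
            comp = 0.0
            for i in range(cohort.n):
                tau, T = lc.tau_last[i], lc.T_eff[i]
                if lc.delta[i] > 0:
                    comp -= float(log_density(T, tau, o[i], head))
                else:
                    comp -= float(np.log(survival(T, tau, o[i], head)))
            comp /= cohort.n
            assert expanded == pytest.approx(comp, abs=1e-10)

    def test_all_censored_nonnegative(self, head, rng):
        cohort = _random_cohort(rng)
        cohort.delta[:] = 0
        lc = likelihood_constants(cohort, head)
        o = rng.standard_normal((cohort.n, head.n_basis))
        assert float(nll(o, lc, head).value) >= 0.0

    def test_hand_computed_two_basis_event(self):
        """One event subject with the smallest basis (L=1, p=2): the value
        reduces to hand-evaluated spline arithmetic."""
        head = SmolHead.create(L=1, p=2, t_max=2.0)
        cohort = LongitudinalCohort(
            z=np.zeros((1, 1)), z_mask=np.zeros((1, 1)), times=[[0.0]],
            x=[np.zeros((1, 1))], x_mask=[np.zeros((1, 1))],
            T=np.array([1.0]), delta=np.array([1]),
        )
        o = np.array([[0.4, -0.3, 0.2]])
        ph = np.array([0.4, 1e-8, 0.2 + 1e-8])
        lc = likelihood_constants(cohort, head)
        # log S = sum_k phi_k * suffix_k[B(0) - B(1)]; log f adds log O'(1)
        log_s = float(np.dot(ph, lc.W[0]))
        dens = float(np.dot(ph, lc.D[0]))
        expected = -(log_s + np.log(dens))
        assert float(nll(o, lc, head).value) == pytest.approx(expected, rel=1e-12)
        # cross-check against the survival/derivative route
        alt = -(np.log(survival(1.0, 0.0, o[0], head))
                + np.log(smol_derivative(1.0, o[0], head)))
        assert float(nll(o, lc, head).value) == pytest.approx(float(alt), rel=1e-10)

    def test_truncation_beyond_horizon(self, head, rng):
        cohort = _random_cohort(rng)
        cohort.T[0] = head.ks.t_max + 5.0
        cohort.delta[0] = 1
        lc = likelihood_constants(cohort, head)
        assert lc.T_eff[0] == head.ks.t_max
        assert lc.delta[0] == 0  # administratively censored at the horizon


class TestRankingPenalty:
    def test_single_subject_is_zero(self, head, rng):
        cohort = _random_cohort(rng, n=1)
        cohort.delta[:] = 1
        lc = likelihood_constants(cohort, head)
        pc = pairwise_constants(lc, head)
        o = rng.standard_normal((1, head.n_basis))
        assert float(ranking_penalty(o, lc, pc, head).value) == 0.0

    def test_summands_within_exponential_bounds(self, head, rng):
        cohort = _random_cohort(rng, n=10)
        lc = likelihood_constants(cohort, head)
        pc = pairwise_constants(lc, head)
        o = rng.standard_normal((10, head.n_basis))
        val = float(ranking_penalty(o, lc, pc, head).value)
        n_pairs = pc["mask"].sum()
        if n_pairs:
            per_pair = val * 100 / n_pairs  # n^2 = 100
            assert np.exp(-1) < per_pair < np.exp(1)

    def test_matches_brute_force_enumeration(self, head, rng):
        cohort = _random_cohort(rng, n=6)
        lc = likelihood_constants(cohort, head)
        pc = pairwise_constants(lc, head)
        o = rng.standard_normal((6, head.n_basis))
        total = 0.0
        elapsed = lc.T_eff - lc.tau_last
        for i1 in range(6):
            if lc.delta[i1] != 1:
                continue
            S1 = float(survival(lc.T_eff[i1], lc.tau_last[i1], o[i1], head))
            for i2 in range(6):
                if i2 == i1 or not elapsed[i1] < elapsed[i2]:
                    continue
                s_at = min(elapsed[i1] + lc.tau_last[i2], head.ks.t_max)
                S2 = float(survival(s_at, lc.tau_last[i2], o[i2], head))
                total += np.exp(S1 - S2)
        assert float(ranking_penalty(o, lc, pc, head).value) == pytest.approx(
            total / 36, rel=1e-10)


class TestReconstructionPenalty:
    def test_perfect_continuous_predictions_zero(self, rng):
        cohort = _random_cohort(rng, n=5)
        batch = build_batch(cohort)
        x_hat = ad.constant(batch.x[:, 1:])
        val = reconstruction_penalty(x_hat, batch, cohort.binary_x, d_z=cohort.d_z)
        assert float(val.value) == 0.0

    def test_fully_masked_entries_contribute_zero(self, rng):
        cohort = _random_cohort(rng, n=5)
        for m in cohort.x_mask:
            m[:] = 1.0
        batch = build_batch(cohort)
        x_hat = ad.constant(rng.standard_normal(batch.x[:, 1:].shape))
        val = reconstruction_penalty(x_hat, batch, cohort.binary_x, d_z=cohort.d_z)
        assert float(val.value) == 0.0

    def test_hand_computed_mixed_types(self):
        """One subject, two visits, one continuous and one binary covariate."""
        eps = 1e-8
        cohort = LongitudinalCohort(
            z=np.zeros((1, 1)), z_mask=np.zeros((1, 1)),
            times=[[0.0, 2.0]], x=[np.array([[0.5, 1.0], [1.5, 1.0]])],
            x_mask=[np.zeros((2, 2))], T=np.array([3.0]), delta=np.array([1]),
            binary_x=np.array([False, True]),
        )
        batch = build_batch(cohort)
        raw = np.array([[[2.0, 0.3]]])  # predicts visit 2
        prob = 1 / (1 + np.exp(-0.3))
        expected = (1.5 - 2.0) ** 2 + (-np.log(prob + eps))
        val = reconstruction_penalty(ad.constant(raw), batch, cohort.binary_x,
                                     eps_zeta=eps, d_z=1)
        assert float(val.value) == pytest.approx(expected, rel=1e-9)

    def test_nonbinary_value_in_binary_column_rejected(self):
        cohort = LongitudinalCohort(
            z=np.zeros((1, 1)), z_mask=np.zeros((1, 1)),
            times=[[0.0, 2.0]], x=[np.array([[0.0, 1.0], [0.5, 0.37]])],
            x_mask=[np.zeros((2, 2))], T=np.array([3.0]), delta=np.array([1]),
            binary_x=np.array([False, True]),
        )
        batch = build_batch(cohort)
        x_hat = ad.constant(np.zeros(batch.x[:, 1:].shape))
        with pytest.raises(ValueError):
            reconstruction_penalty(x_hat, batch, cohort.binary_x, d_z=1)


class TestRoughnessPenalty:
    def test_linear_coefficients_give_zero(self, head):
        gr = greville_abscissae(head.ks)
        c = 1.0 + 0.2 * gr
        o = np.concatenate([[c[0]], np.diff(c) - head.eps_phi])[None, :]
        assert float(roughness_penalty(o, head).value) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative(self, head, rng):
        o = rng.standard_normal((8, head.n_basis))
        assert float(roughness_penalty(o, head).value) >= 0.0

    def test_matches_adaptive_quadrature(self, head, rng):
        o = rng.standard_normal((1, head.n_basis))
        val = float(roughness_penalty(o, head).value)

        def integrand(u):
            return smol_derivative(u, o[0], head, order=2) ** 2

        ref = sum(quad(integrand, a, b, limit=100)[0]
                  for a, b in zip(np.linspace(0, 30, 11)[:-1],
                                  np.linspace(0, 30, 11)[1:]))
        assert val == pytest.approx(ref, abs=1e-8)


class TestTotalLoss:
    @staticmethod
    def _setup(rng, head):
        cohort = _random_cohort(rng, n=8)
        batch = build_batch(cohort)
        lc = likelihood_constants(cohort, head, index=batch.index)
        pc = pairwise_constants(lc, head)
        gram = second_derivative_gram(head.ks)
        return cohort, batch, lc, pc, gram

    def test_zero_weights_reduce_to_nll(self, head, rng):
        cohort, batch, lc, pc, gram = self._setup(rng, head)
        o = rng.standard_normal((batch.n, head.n_basis))
        x_hat = ad.constant(rng.standard_normal(batch.x[:, 1:].shape))
        total, parts = total_loss(o, x_hat, lc, pc, batch, head,
                                  LossWeights(0, 0, 0), cohort.binary_x,
                                  gram=gram, d_z=cohort.d_z)
        assert float(total.value) == float(nll(o, lc, head).value)

    def test_weighted_sum_arithmetic(self, head, rng):
        cohort, batch, lc, pc, gram = self._setup(rng, head)
        o = rng.standard_normal((batch.n, head.n_basis))
        x_hat = ad.constant(rng.standard_normal(batch.x[:, 1:].shape))
        w = LossWeights(0.1, 0.01, 10.0)
        total, parts = total_loss(o, x_hat, lc, pc, batch, head, w,
                                  cohort.binary_x, gram=gram, d_z=cohort.d_z)
        expected = (parts["nll"] + 0.1 * parts["P1"] + 0.01 * parts["P2"]
                    + 10.0 * parts["P3"])
        assert parts["total"] == pytest.approx(expected, rel=1e-12)

    def test_ablating_one_weight_changes_only_that_component(self, head, rng):
        cohort, batch, lc, pc, gram = self._setup(rng, head)
        o = rng.standard_normal((batch.n, head.n_basis))
        x_hat = ad.constant(rng.standard_normal(batch.x[:, 1:].shape))
        w_full = LossWeights(1.0, 1.0, 1.0)
        _, full = total_loss(o, x_hat, lc, pc, batch, head, w_full,
                             cohort.binary_x, gram=gram, d_z=cohort.d_z)
        _, no_p1 = total_loss(o, x_hat, lc, pc, batch, head,
                              LossWeights(0.0, 1.0, 1.0), cohort.binary_x,
                              gram=gram, d_z=cohort.d_z)
        assert no_p1["nll"] == full["nll"]
        assert no_p1["P2"] == full["P2"]
        assert no_p1["P3"] == full["P3"]
        assert no_p1["total"] == pytest.approx(full["total"] - full["P1"])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.0, 0.0)


def test_total_loss_gradient_matches_finite_differences(head, rng):
    """Autodiff gradient of the full objective w.r.t. the encodings."""
    cohort = _random_cohort(rng, n=5)
    batch = build_batch(cohort)
    lc = likelihood_constants(cohort, head, index=batch.index)
    pc = pairwise_constants(lc, head)
    gram = second_derivative_gram(head.ks)
    w = LossWeights(1.0, 0.5, 2.0)
    o = ad.parameter(rng.standard_normal((batch.n, head.n_basis)))
    x_hat = ad.parameter(rng.standard_normal(batch.x[:, 1:].shape))
    total, _ = total_loss(o, x_hat, lc, pc, batch, head, w, cohort.binary_x,
                          gram=gram, d_z=cohort.d_z)
    total.backward()
    for leaf in (o, x_hat):
        flat, grad = leaf.value.ravel(), leaf.grad.ravel()
        for k in rng.choice(flat.size, 8, replace=False):
            if abs(flat[k]) < 1e-4:
                continue  # avoid the positivity-map kink at zero
            old = flat[k]
            eps = 1e-6
            flat[k] = old + eps
            up = float(total_loss(o, x_hat, lc, pc, batch, head, w,
                                  cohort.binary_x, gram=gram,
                                  d_z=cohort.d_z)[0].value)
            flat[k] = old - eps
            dn = float(total_loss(o, x_hat, lc, pc, batch, head, w,
                                  cohort.binary_x, gram=gram,
                                  d_z=cohort.d_z)[0].value)
            flat[k] = old
            fd = (up - dn) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)
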