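import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from copulagc import (
    FitResult,
    JointModel,
    SimConfig,
    aic,
    cond_means,
    fit,
    joint_loglik,
    mixed_pair_loglik,
    select_order,
    simulate_mixed,
)
from copulagc.copula_model import (
    continuous_loglik,
    discrete_loglik,
    load_fit,
    save_fit,
    select_order as _select_order,
)
from conftest import random_valid_model


def brute_force_loglik(model, ts):
    """Independent likelihood implementation: plain loops and textbook
    formulas (norm.pdf / norm.cdf, no shared code with the package path)."""
    total = 0.0
    p = model.p
    for tr in range(ts.n_trials):
        y_row = ts.lfp[tr]
        x_row = ts.spikes[tr]
        for t in range(p, ts.n_bins):
            mu = model.c_y
            eta = model.c_x
            for i in range(1, p + 1):
                mu += model.a[i - 1] * y_row[t - i] + model.b[i - 1] * x_row[t - i]
                eta += model.d[i - 1] * x_row[t - i] + model.e[i - 1] * y_row[t - i]
            z = (y_row[t] - mu) / model.sigma
            f_y = norm.pdf(y_row[t], loc=mu, scale=model.sigma)
            p1 = norm.cdf((eta + model.rho * z) / math.sqrt(1 - model.rho**2))
            p_x = p1 if x_row[t] == 1 else 1.0 - p1
            total += math.log(f_y) + math.log(p_x)
    return total


class TestCondMeans:
    def test_all_zero_gives_half_probability(self):
        m = JointModel(p=1, c_y=0.0, a=[0.0], b=[0.0], sigma=1.0,
                       c_x=0.0, d=[0.0], e=[0.0], rho=0.0)
        mu, eta = cond_means(m, [1.0], [1])
        assert mu == 0.0
        assert norm.cdf(eta) == 0.5

    def test_linear_form(self):
        m = JointModel(p=1, c_y=0.0, a=[0.5], b=[0.0], sigma=1.0,
                       c_x=0.0, d=[0.0], e=[0.0], rho=0.0)
        mu, _ = cond_means(m, [2.0], [0])
        assert mu == 1.0

    def test_matches_independent_dot_product(self, rng):
        m = random_valid_model(rng)
        yh = rng.standard_normal(2)
        xh = rng.integers(0, 2, 2)
        mu, eta = cond_means(m, yh, xh)
        mu_ref = m.c_y + sum(m.a[i] * yh[i] + m.b[i] * xh[i] for i in range(2))
        eta_ref = m.c_x + sum(m.d[i] * xh[i] + m.e[i] * yh[i] for i in range(2))
        assert mu == pytest.approx(mu_ref, abs=1e-12)
        assert eta == pytest.approx(eta_ref, abs=1e-12)

    def test_wrong_history_length_rejected(self, coupled_model_p2):
        with pytest.raises(ValueError, match="length p=2"):
            cond_means(coupled_model_p2, [1.0], [0, 1])


class TestMixedPairLoglik:
    def test_rho_zero_factorizes(self, rng):
        m = random_valid_model(rng)
        m.rho = 0.0
        yh, xh = rng.standard_normal(2), rng.integers(0, 2, 2)
        mu, eta = cond_means(m, yh, xh)
        for x_t, y_t in [(0, 0.3), (1, -1.2)]:
            ll = mixed_pair_loglik(m, x_t, y_t, yh, xh)
            ref = norm.logpdf(y_t, mu, m.sigma) + (
                norm.logcdf(eta) if x_t == 1 else norm.logcdf(-eta)
            )
            assert ll == pytest.approx(ref, abs=1e-12)

    def test_bivariate_normal_conditional_oracle(self):
        # rho=0.5, sigma=1, mu=0, eta=0, (x=1, y=1)
        m = JointModel(p=1, c_y=0.0, a=[0.0], b=[0.0], sigma=1.0,
                       c_x=0.0, d=[0.0], e=[0.0], rho=0.5)
        ll = mixed_pair_loglik(m, 1, 1.0, [0.0], [0])
        expected = math.log(norm.pdf(1.0) * norm.cdf(0.5 / math.sqrt(0.75)))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_density_normalizes(self, rng):
        m = random_valid_model(rng)
        yh, xh = rng.standard_normal(2), rng.integers(0, 2, 2)
        total = 0.0
        for x_t in (0, 1):
            val, _ = integrate.quad(
                lambda y: math.exp(mixed_pair_loglik(m, x_t, y, yh, xh)),
                -np.inf, np.inf,
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_x_rejected(self, coupled_model_p2):
        with pytest.raises(ValueError, match="0 or 1"):
            mixed_pair_loglik(coupled_model_p2, 2, 0.0, [0.0, 0.0], [0, 0])


class TestJointLoglik:
    def test_single_term(self, coupled_model_p2, tiny_trialset):
        sub = tiny_trialset.select_trials([0]).select_bins(0, 3)
        m = coupled_model_p2
        ll = joint_loglik(m, sub)
        ref = mixed_pair_loglik(
            m, int(sub.spikes[0, 2]), sub.lfp[0, 2],
            sub.lfp[0, [1, 0]], sub.spikes[0, [1, 0]],
        )
        assert ll == pytest.approx(ref, abs=1e-12)

    def test_duplicating_trials_doubles(self, coupled_model_p2, tiny_trialset):
        ll1 = joint_loglik(coupled_model_p2, tiny_trialset)
        doubled = tiny_trialset.select_trials([0, 1, 0, 1])
        assert joint_loglik(coupled_model_p2, doubled) == pytest.approx(
            2 * ll1, rel=1e-12
        )

    def test_brute_force_oracle(self, coupled_model_p2, tiny_trialset):
        ll = joint_loglik(coupled_model_p2, tiny_trialset)
        ref = brute_force_loglik(coupled_model_p2, tiny_trialset)
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_rho_zero_exact_factorization(self, null_model_p2, small_trialset):
        # same floating-point expressions: equality is exact
        ll = joint_loglik(null_model_p2, small_trialset)
        parts = continuous_loglik(null_model_p2, small_trialset) + discrete_loglik(
            null_model_p2, small_trialset
        )
        assert ll == parts

    def test_nonbinary_spikes_rejected(self, coupled_model_p2, tiny_trialset):
        bad = tiny_trialset.select_trials([0, 1])
        bad.spikes[0, 4] = 2
        with pytest.raises(ValueError, match="binary"):
            joint_loglik(coupled_model_p2, bad)


class TestFit:
    def test_full_dominates_reduced(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=20,
                                      n_bins=120, seed=5))
        fr_full = fit(ts, 2, restriction="full")
        for restriction in ("no_spike_to_lfp", "no_lfp_to_spike"):
            fr_red = fit(ts, 2, restriction=restriction)
            assert fr_full.loglik >= fr_red.loglik - 1e-8
            assert fr_red.k == fr_full.k - 2

    def test_restriction_zeroes_block(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=15,
                                      n_bins=100, seed=6))
        fr = fit(ts, 2, restriction="no_spike_to_lfp")
        np.testing.assert_array_equal(fr.model.b, 0.0)
        fr = fit(ts, 2, restriction="no_lfp_to_spike")
        np.testing.assert_array_equal(fr.model.e, 0.0)

    def test_k_counts_free_parameters(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=20,
                                      n_bins=120, seed=8))
        fr = fit(ts, 2)
        assert fr.k == 4 * 2 + 4
        assert fr.aic == -2 * fr.loglik + 2 * fr.k

    def test_degenerate_spike_channel_rejected(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=5,
                                      n_bins=50, seed=9))
        ts.spikes[:] = 0
        with pytest.raises(ValueError, match="degenerate"):
            fit(ts, 2)

    def test_too_few_observations_warns(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=2,
                                      n_bins=30, seed=10))
        if np.all(ts.spikes[:, 2:] == 0):
            pytest.skip("no spikes drawn")
        with pytest.warns(UserWarning, match="observations"):
            fit(ts, 2)

    def test_null_cross_coefficients_within_3se(self, null_model_p2):
        """Data generated with b=e=0, rho=0: fitted cross coefficients stay
        within 3 standard errors of zero in nearly all replicates."""
        n_reps, hits = 20, 0
        for rep in range(n_reps):
            ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=50,
                                          n_bins=300, seed=100 + rep))
            fr = fit(ts, 2, compute_se=True)
            ok = np.all(np.abs(fr.model.b) <= 3 * fr.se["b"]) and np.all(
                np.abs(fr.model.e) <= 3 * fr.se["e"]
            )
            hits += ok
        assert hits >= 17  # ~99% per replicate jointly over 4 coefficients

    def test_parameter_recovery(self, coupled_model_p2):
        ts = simulate_mixed(SimConfig(model=coupled_model_p2, n_trials=100,
                                      n_bins=400, seed=42))
        fr = fit(ts, 2)
        assert fr.converged
        m, truth = fr.model, coupled_model_p2
        assert m.rho == pytest.approx(truth.rho, abs=0.05)
        est = np.concatenate([[m.c_y], m.a, m.b, [m.c_x], m.d, m.e])
        tru = np.concatenate([[truth.c_y], truth.a, truth.b,
                              [truth.c_x], truth.d, truth.e])
        assert np.sqrt(np.mean((est - tru) ** 2)) < 0.08


class TestAic:
    def test_definition(self):
        m = JointModel(p=1, c_y=0, a=[0.1], b=[0.0], sigma=1.0,
                       c_x=0, d=[0.0], e=[0.0], rho=0.0)
        fr = FitResult(model=m, loglik=-100.0, k=10, converged=True, n_obs=500)
        assert aic(fr) == 220.0

    def test_k_difference_of_one_changes_aic_by_two(self):
        m = JointModel(p=1, c_y=0, a=[0.1], b=[0.0], sigma=1.0,
                       c_x=0, d=[0.0], e=[0.0], rho=0.0)
        a1 = aic(FitResult(model=m, loglik=-50.0, k=5, converged=True, n_obs=100))
        a2 = aic(FitResult(model=m, loglik=-50.0, k=6, converged=True, n_obs=100))
        assert a2 - a1 == 2.0

    def test_matches_recomputed_loglik(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=20,
                                      n_bins=150, seed=12))
        fr = fit(ts, 2)
        recomputed = -2 * joint_loglik(fr.model, ts) + 2 * fr.k
        assert aic(fr) == pytest.approx(recomputed, rel=1e-10)

    def test_nonconverged_rejected(self, null_model_p2):
        m = null_model_p2
        fr = FitResult(model=m, loglik=-1.0, k=3, converged=False, n_obs=10)
        with pytest.raises(ValueError, match="non-converged"):
            aic(fr)


class TestSelectOrder:
    def test_single_candidate(self, null_model_p2):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=20,
                                      n_bins=150, seed=13))
        best, table = select_order(ts, [3])
        assert best == 3
        assert set(table) == {3}
        assert table[3] is not None

    def test_empty_candidates_rejected(self, small_trialset):
        with pytest.raises(ValueError, match="nonempty"):
            select_order(small_trialset, [])

    def test_ties_break_toward_smaller(self, monkeypatch, small_trialset):
        import copulagc.copula_model as cm

        m = small_trialset
        def fake_fit(ts, p, restriction="full", **kw):
            model = JointModel(p=p, c_y=0, a=np.zeros(p), b=np.zeros(p),
                               sigma=1.0, c_x=0, d=np.zeros(p),
                               e=np.zeros(p), rho=0.0)
            # arrange equal AIC for p=2 and p=3 (k grows by 4 per order)
            return FitResult(model=model, loglik=-100.0 + 4.0 * (p - 2),
                             k=4 * p + 4, converged=True, n_obs=100)
        monkeypatch.setattr(cm, "fit", fake_fit)
        best, table = cm.select_order(m, [2, 3])
        assert table[2] == table[3]
        assert best == 2


class TestSerialization:
    def test_fit_round_trip(self, null_model_p2, tmp_path):
        ts = simulate_mixed(SimConfig(model=null_model_p2, n_trials=15,
                                      n_bins=100, seed=14))
        fr = fit(ts, 2)
        path = tmp_path / "fit.txt"
        save_fit(fr, path)
        back = load_fit(path)
        assert back.model.p == fr.model.p
        np.testing.assert_allclose(back.model.a, fr.model.a, atol=1e-15)
        np.testing.assert_allclose(back.model.b, fr.model.b, atol=1e-15)
        assert back.model.rho == fr.model.rho
        assert back.loglik == fr.loglik
        assert back.k == fr.k
        assert back.converged == fr.converged


class TestModelValidation:
    def test_bad_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            JointModel(p=1, c_y=0, a=[0.1], b=[0.0], sigma=0.0,
                       c_x=0, d=[0.0], e=[0.0], rho=0.0)

    def test_bad_rho(self):
        with pytest.raises(ValueError, match="rho"):
            JointModel(p=1, c_y=0, a=[0.1], b=[0.0], sigma=1.0,
                       c_x=0, d=[0.0], e=[0.0], rho=1.0)

    def test_wrong_vector_length(self):
        with pytest.raises(ValueError, match="length"):
            JointModel(p=2, c_y=0, a=[0.1], b=[0.0, 0.0], sigma=1.0,
                       c_x=0, d=[0.0, 0.0], e=[0.0, 0.0], rho=0.0)
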