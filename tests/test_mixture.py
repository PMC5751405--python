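"""Collapsed Gibbs sampler for the DP Gaussian mixture."""

import numpy as np
import pytest
from scipy import stats

from duobin._gibbs import logpred_diag, logpred_full
from duobin.mixture import (
    DirichletProcessGMM,
    dpgmm_gibbs,
    posterior_predictive_logpdf,
    prior_predictive_logpdf,
)


def pairwise_agreement(labels, truth):
    """Fraction of point pairs on whose co-membership two labelings agree."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    same_l = labels[:, None] == labels[None, :]
    same_t = truth[:, None] == truth[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return float((same_l[iu] == same_t[iu]).mean())


class TestPredictiveClosedForm:
    """The numba kernels must match the scipy multivariate-t closed forms."""

    @pytest.mark.parametrize("d", [1, 2, 5])
    def test_prior_predictive(self, d, rng):
        x = rng.normal(size=d)
        mu0 = rng.normal(size=d)
        kappa0, nu0 = 0.3, d + 3.0
        A = rng.normal(size=(d, d))
        psi0 = A @ A.T + np.eye(d)
        got = logpred_full(x, 0, np.zeros(d), np.zeros((d, d)), mu0, kappa0, nu0, psi0)
        want = prior_predictive_logpdf(x, mu0, kappa0, nu0, psi0)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("m", [1, 3, 20])
    def test_posterior_predictive(self, m, rng):
        d = 3
        x = rng.normal(size=d)
        mu0 = rng.normal(size=d)
        kappa0, nu0 = 0.01, d + 2.0
        psi0 = np.diag(rng.uniform(0.5, 2.0, size=d))
        members = rng.normal(size=(m, d))
        s = members.sum(axis=0)
        S = members.T @ members
        got = logpred_full(x, m, s, S, mu0, kappa0, nu0, psi0)
        want = posterior_predictive_logpdf(x, members, mu0, kappa0, nu0, psi0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_diag_prior_predictive_is_product_of_ts(self, rng):
        d = 4
        x = rng.normal(size=d)
        mu0 = rng.normal(size=d)
        kappa0, nu0 = 0.5, 4.0
        psi0 = rng.uniform(0.5, 2.0, size=d)
        got = logpred_diag(x, 0, np.zeros(d), np.zeros(d), mu0, kappa0, nu0, psi0)
        want = sum(
            stats.t.logpdf(
                x[j],
                df=nu0,
                loc=mu0[j],
                scale=np.sqrt(psi0[j] * (kappa0 + 1) / (kappa0 * nu0)),
            )
            for j in range(d)
        )
        assert got == pytest.approx(want, abs=1e-10)


class TestDegenerateInputs:
    def test_single_point_single_component(self):
        model = DirichletProcessGMM(random_state=0).fit(np.array([[1.0, 2.0]]))
        assert model.n_components_ == 1
        assert list(model.labels_) == [0]
        assert model.posterior_mode_k_ == 1

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            DirichletProcessGMM().fit(np.array([[np.nan, 0.0], [1.0, 2.0]]))

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            DirichletProcessGMM(n_iterations=10, burn_in=10).fit(np.zeros((5, 2)))


class TestRecovery:
    def test_two_separated_gaussians(self, rng):
        truth = np.repeat([0, 1], 100)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = np.vstack(
                [
                    r.normal((0, 0), 1.0, size=(100, 2)),
                    r.normal((10, 0), 1.0, size=(100, 2)),
                ]
            )
            model = DirichletProcessGMM(random_state=seed).fit(X)
            if (
                model.posterior_mode_k_ == 2
                and pairwise_agreement(model.labels_, truth) >= 0.99
            ):
                hits += 1
        assert hits >= 8

    def test_single_gaussian_one_component(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.normal(size=(200, 2))
            model = DirichletProcessGMM(random_state=seed).fit(X)
            hits += model.posterior_mode_k_ == 1
        assert hits >= 8

    def test_diag_covariance_used_in_high_dim(self, rng):
        X = rng.normal(size=(50, 12))
        model = DirichletProcessGMM(
            n_iterations=60, burn_in=20, random_state=0
        ).fit(X)
        assert model.covariance_ == "diag"

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 2))
        a = DirichletProcessGMM(n_iterations=80, burn_in=20, random_state=3).fit(X)
        b = DirichletProcessGMM(n_iterations=80, burn_in=20, random_state=3).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        assert a.alpha_ == b.alpha_


class TestExchangeability:
    def test_k_distribution_invariant_under_row_permutation(self):
        """Post-burn-in distribution of k should not depend on row order
        (within Monte-Carlo error over 20 seeds)."""
        base = np.random.default_rng(42)
        X = np.vstack(
            [
                base.normal((0, 0), 1.0, size=(20, 2)),
                base.normal((8, 0), 1.0, size=(20, 2)),
            ]
        )
        perm = base.permutation(len(X))

        def mean_k(data, seed_offset):
            ks = []
            for s in range(20):
                m = DirichletProcessGMM(
                    n_iterations=120, burn_in=40, random_state=seed_offset + s
                ).fit(data)
                ks.append(m.k_samples_.mean())
            return np.mean(ks), np.std(ks, ddof=1) / np.sqrt(20)

    # the same seeds are reused on purpose: only the row order changes
        m1, se1 = mean_k(X, 0)
        m2, se2 = mean_k(X[perm], 0)
        assert abs(m1 - m2) < 4 * np.hypot(se1, se2) + 0.05


class TestFunctionalWrapper:
    def test_dpgmm_gibbs_returns_labels(self, rng):
        X = rng.normal(size=(30, 2))
        labels = dpgmm_gibbs(X, n_iterations=60, burn_in=20, seed=1)
        assert labels.shape == (30,)
        assert labels.min() == 0
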