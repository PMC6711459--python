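import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dcmfmri import (Dataset, FitOptions, GaussianDensity, NoiseModel,
                     Prediction, build_priors, fit, free_energy)
from dcmfmri.inversion import variational_laplace

from conftest import make_two_region_spec


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(3)
    n, V = 3, 40
    X = rng.standard_normal((V, n))
    prior = GaussianDensity(np.zeros(n), np.diag([0.5, 1.0, 2.0]))
    lam = 2.0
    theta_true = np.array([0.3, -0.5, 0.8])
    y = X @ theta_true + rng.standard_normal(V) * np.exp(-lam / 2)
    return X, prior, lam, y


def solve_linear(X, prior, lam, y, **overrides):
    noise = NoiseModel(n_volumes=y.size, n_regions=1)
    opts = FitOptions(fit_noise=False, lambdas0=[lam], tol=1e-10,
                      max_iter=200, damping_init=1e-8, **overrides)
    return variational_laplace(lambda Th: Th @ X.T, y, prior, noise, opts)


class TestLinearGaussianOracle:
    """With a fixed linear map the scheme must land on the conjugate posterior
    and F must equal the analytic log evidence."""

    def test_posterior_matches_conjugate_closed_form(self, linear_problem):
        X, prior, lam, y = linear_problem
        best = solve_linear(X, prior, lam, y)["best"]
        P = np.linalg.inv(prior.cov) + np.exp(lam) * X.T @ X
        Sigma = np.linalg.inv(P)
        mean = Sigma @ (np.exp(lam) * X.T @ y)
        assert np.abs(best["m"] - mean).max() < 1e-6
        assert np.abs(best["Sigma"] - Sigma).max() < 1e-6

    def test_free_energy_equals_log_evidence(self, linear_problem):
        X, prior, lam, y = linear_problem
        best = solve_linear(X, prior, lam, y)["best"]
        C = X @ prior.cov @ X.T + np.exp(-lam) * np.eye(y.size)
        log_ev = multivariate_normal(mean=np.zeros(y.size), cov=C).logpdf(y)
        assert abs(best["F"] - log_ev) < 1e-4

    def test_joint_rescaling_accounting(self, linear_problem):
        # scaling y and the predictor by c, with lambda shifted by -2 ln c,
        # changes F by exactly -N ln c (the Jacobian of the rescaling)
        X, prior, lam, y = linear_problem
        c = 3.0
        F1 = solve_linear(X, prior, lam, y)["best"]["F"]
        F2 = solve_linear(c * X, prior, lam - 2 * np.log(c), c * y)["best"]["F"]
        assert F2 - F1 == pytest.approx(-y.size * np.log(c), abs=1e-6)


class TestFreeEnergyFunction:
    def test_complexity_zero_when_posterior_equals_prior(self):
        spec = make_two_region_spec(False)
        priors = build_priors(spec)
        rng = np.random.default_rng(1)
        from conftest import two_region_inputs
        U = two_region_inputs(100)
        Y = rng.standard_normal((20, 2)) * 0.05
        data = Dataset(U=U, Y=Y, TR=2.0, slice_times=spec.slice_times)
        noise = NoiseModel(n_volumes=20, n_regions=2)
        F, acc, comp = free_energy(Prediction(y_hat=np.zeros((20, 2))), data,
                                   priors, priors, noise, [6.0, 6.0])
        assert comp == pytest.approx(0.0, abs=1e-9)
        assert F == pytest.approx(acc, abs=1e-9)

    def test_kl_matches_closed_form_two_parameters(self):
        # KL(N(m1,S1) || N(m0,S0)) for diagonal 2-d Gaussians, hand-derived
        spec = make_two_region_spec(False)
        from conftest import two_region_inputs
        U = two_region_inputs(100)
        data = Dataset(U=U, Y=np.ones((20, 2)), TR=2.0, slice_times=spec.slice_times)
        noise = NoiseModel(n_volumes=20, n_regions=2)
        m0, s0 = np.array([0.0, 0.0]), np.array([1.0, 4.0])
        m1, s1 = np.array([0.5, -1.0]), np.array([0.2, 1.0])
        prior = GaussianDensity(m0, np.diag(s0))
        post = GaussianDensity(m1, np.diag(s1))
        # pad predictions so the accuracy term is irrelevant to this check
        _, _, comp = free_energy(Prediction(y_hat=np.ones((20, 2))), data,
                                 post, prior, noise, [6.0, 6.0])
        want = 0.5 * np.sum(s1 / s0 + (m1 - m0) ** 2 / s0 - 1 + np.log(s0 / s1))
        assert comp == pytest.approx(want, abs=1e-12)

    def test_singular_prior_rejected(self):
        spec = make_two_region_spec(False)
        from conftest import two_region_inputs
        U = two_region_inputs(100)
        data = Dataset(U=U, Y=np.ones((20, 2)), TR=2.0, slice_times=spec.slice_times)
        noise = NoiseModel(n_volumes=20, n_regions=2)
        sing = GaussianDensity(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            free_energy(Prediction(y_hat=np.ones((20, 2))), data, sing, sing,
                        noise, [6.0, 6.0])


class TestFitBehaviour:
    def test_trajectory_monotone_and_bookkeeping(self, two_region_fit):
        _, _, _, result = two_region_fit
        assert np.all(np.diff(result.F_trajectory) >= 0)
        assert result.F == result.F_trajectory[-1]
        assert result.n_iterations == len(result.F_trajectory)
        assert result.F == pytest.approx(result.accuracy - result.complexity)

    def test_posterior_variances_shrink(self, two_region_fit):
        spec, _, _, result = two_region_fit
        prior = build_priors(spec)
        assert np.all(result.posterior.sd() <= prior.sd() * (1 + 1e-6))

    def test_fit_is_deterministic(self, two_region_fit):
        spec, data, _, result = two_region_fit
        again = fit(spec, data)
        assert again.F == result.F
        assert np.array_equal(again.posterior.mean, result.posterior.mean)
        assert np.array_equal(again.lambdas, result.lambdas)

    def test_posterior_pulled_toward_truth(self, two_region_fit):
        spec, _, truth, result = two_region_fit
        from dcmfmri import vectorise
        theta = vectorise(truth, spec)
        prior = build_priors(spec)
        # fitted means are closer to the truth than the prior means are
        assert np.linalg.norm(result.posterior.mean - theta) \
            < np.linalg.norm(prior.mean - theta)

    def test_prior_mismatch_rejected(self, two_region_fit):
        spec, data, _, _ = two_region_fit
        bad = GaussianDensity(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError, match="free parameters"):
            fit(spec, data, priors=bad)
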