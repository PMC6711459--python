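"""Variational Laplace model inversion.

Fits the generative model to data under Gaussian (Laplace) assumptions on
the parameter posterior, returning the posterior density, optimised noise
log precisions, and the negative variational free energy

    F = accuracy - complexity

where accuracy is the expected log likelihood of the residuals under the
observation precision (including its log-determinant and dimensionality
constants) and complexity is the Kullback-Leibler divergence from the
priors to the posteriors (parameters plus, when noise is estimated, the
log-precision hyperparameters).  F is a lower bound on the log model
evidence and becomes exact for linear models.

The scheme is a Gauss-Newton ascent on F:

1. sensitivities of the prediction to every free parameter by central
   finite differences (one batched integration);
2. Laplace update of the posterior mean and covariance, regularised by
   Levenberg-Marquardt damping — steps that increase F are accepted and
   the damping relaxed (x0.7), steps that do not are rejected and the
   damping tightened (x2);
3. Newton updates of each noise log precision at the fixed parameter
   posterior, clamped to the hyperprior mean +/- 8 prior sd;
4. stop when the F improvement stays below tolerance for a patience
   window, or at the iteration cap.

Initialisation is deterministic at the prior mean, in keeping with the
shrinkage logic of the priors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .integrate import Dataset, IntegrationError, Prediction, _integrate_batch
from .model import GaussianDensity, ModelSpec, build_index, build_priors
from .noise import NoiseModel, default_noise

__all__ = ["FitOptions", "FitResult", "fit", "variational_laplace", "free_energy"]

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitOptions:
    """Tunable settings of the inversion (defaults are the contract)."""

    max_iter: int = 128
    tol: float = 1e-2            # nats; convergence threshold on dF
    patience: int = 4            # consecutive small improvements required
    fd_step: float = 1e-4        # central finite-difference step
    n_substeps: int | None = None
    damping_init: float = 0.5
    damping_up: float = 2.0
    damping_down: float = 0.7
    max_rejects: int = 8         # consecutive rejected steps before giving up
    fit_noise: bool = True
    lambdas0: np.ndarray | None = None
    verbose: bool = False


@dataclass
class FitResult:
    """Posterior densities, free energy decomposition and fit diagnostics."""

    posterior: GaussianDensity
    lambdas: np.ndarray
    lambda_var: np.ndarray
    F: float
    F_trajectory: np.ndarray
    accuracy: float
    complexity: float
    prediction: Prediction
    residuals: np.ndarray
    converged: bool
    n_iterations: int

    def __post_init__(self):
        self.F_trajectory = np.asarray(self.F_trajectory, dtype=float)
        if len(self.F_trajectory) != self.n_iterations:
            raise ValueError("one trajectory entry per accepted iteration is required")
        if abs(self.F - (self.accuracy - self.complexity)) > 1e-6 * max(1.0, abs(self.F)):
            raise ValueError("free energy must equal accuracy minus complexity")


def _kl_gaussian(m_q, S_q, m_p, S_p_chol, logdet_Sp):
    """KL( N(m_q, S_q) || N(m_p, S_p) ) with S_p pre-factorised."""
    n = m_q.size
    dm = m_q - m_p
    tr = float(np.trace(cho_solve(S_p_chol, S_q)))
    quad = float(dm @ cho_solve(S_p_chol, dm))
    sign, logdet_Sq = np.linalg.slogdet(S_q)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance is not positive definite")
    return 0.5 * (tr + quad - n + logdet_Sp - logdet_Sq)


def _accuracy_terms(sse_tr, lambdas, n_volumes):
    """Expected log likelihood: -1/2 sum_r exp(l_r) SS_r + 1/2 sum_r V l_r - N/2 ln 2pi."""
    n_obs = n_volumes * len(lambdas)
    return float(-0.5 * np.sum(np.exp(lambdas) * sse_tr)
                 + 0.5 * n_volumes * np.sum(lambdas)
                 - 0.5 * n_obs * LOG2PI)


def _kl_lambdas(lambdas, lam_var, prior_mean, prior_var):
    d = lambdas - prior_mean
    r = lam_var / prior_var
    return float(0.5 * np.sum(d * d / prior_var + r - 1.0 - np.log(r)))


def variational_laplace(forward_batch, y: np.ndarray, prior: GaussianDensity,
                        noise: NoiseModel, options: FitOptions | None = None
                        ) -> dict:
    """Core fitting loop over an arbitrary batched forward map.

    ``forward_batch`` maps an (m, n_params) array of parameter vectors to an
    (m, N) array of predictions, with observations ordered region-major to
    match ``noise``.  Returns a dict of posterior quantities; :func:`fit`
    wraps it for the DCM forward model.
    """
    options = options or FitOptions()
    y = np.asarray(y, dtype=float).ravel()
    n_obs = noise.n_obs
    if y.size != n_obs:
        raise ValueError(f"data vector has length {y.size}, expected {n_obs}")
    n_p = prior.n
    mu0 = prior.mean
    S0 = prior.cov
    try:
        S0_chol = cho_factor(S0)
    except np.linalg.LinAlgError as err:
        raise ValueError("prior covariance must be positive definite") from err
    P0 = cho_solve(S0_chol, np.eye(n_p))
    sign, logdet_S0 = np.linalg.slogdet(S0)
    if sign <= 0:
        raise ValueError("prior covariance must be positive definite")

    lam_mean, lam_pvar = noise.lambda_prior()
    if options.lambdas0 is not None:
        lam_init = np.asarray(options.lambdas0, dtype=float).ravel()
        if lam_init.size != noise.n_components:
            raise ValueError("lambdas0 length does not match the noise components")
    else:
        lam_init = lam_mean.copy()
    lam_lo = lam_mean - 8.0 * np.sqrt(lam_pvar)
    lam_hi = lam_mean + 8.0 * np.sqrt(lam_pvar)
    V = noise.n_volumes
    R = noise.n_regions
    fd = options.fd_step

    def sensitivities(theta):
        eye = np.eye(n_p)
        thetas = np.vstack([theta[None, :], theta + fd * eye, theta - fd * eye])
        H = forward_batch(thetas)
        h0 = H[0]
        J = (H[1:n_p + 1] - H[n_p + 1:]).T / (2.0 * fd)
        return h0, J

    def evaluate(theta, lam_start):
        """Predict, update (Sigma, lambda) jointly, and score F at ``theta``."""
        h0, J = sensitivities(theta)
        if not (np.isfinite(h0).all() and np.isfinite(J).all()):
            return None
        e = y - h0
        G = np.empty((R, n_p, n_p))
        sse = np.empty(R)
        for r in range(R):
            Jr = J[r * V:(r + 1) * V]
            G[r] = Jr.T @ Jr
            sse[r] = float(e[r * V:(r + 1) * V] @ e[r * V:(r + 1) * V])
        lam = lam_start.copy()
        n_inner = 8 if options.fit_noise else 1
        for _ in range(n_inner):
            P = P0 + np.einsum("r,rij->ij", np.exp(lam), G)
            try:
                P_chol = cho_factor(P)
            except np.linalg.LinAlgError:
                return None
            Sigma = cho_solve(P_chol, np.eye(n_p))
            tr = np.einsum("rij,ij->r", G, Sigma)
            if not options.fit_noise:
                break
            w = np.exp(lam)
            grad = 0.5 * (V - w * (sse + tr)) - (lam - lam_mean) / lam_pvar
            hess = -0.5 * w * (sse + tr) - 1.0 / lam_pvar
            lam = np.clip(lam - grad / hess, lam_lo, lam_hi)
        sse_tr = sse + tr
        lam_var = 1.0 / (0.5 * np.exp(lam) * sse_tr + 1.0 / lam_pvar)
        acc = _accuracy_terms(sse_tr, lam, V)
        comp = _kl_gaussian(theta, Sigma, mu0, S0_chol, logdet_S0)
        if options.fit_noise:
            comp += _kl_lambdas(lam, lam_var, lam_mean, lam_pvar)
        F = acc - comp
        if not np.isfinite(F):
            return None
        return dict(m=theta, h=h0, J=J, e=e, G=G, sse=sse, tr=tr, lam=lam,
                    lam_var=lam_var, P=P, Sigma=Sigma, F=F, acc=acc, comp=comp)

    def propose(state, damping):
        w_obs = np.repeat(np.exp(state["lam"]), V)
        g = state["J"].T @ (w_obs * state["e"]) - P0 @ (state["m"] - mu0)
        P = state["P"]
        P_damped = P + damping * np.diag(np.diag(P))
        try:
            return state["m"] + cho_solve(cho_factor(P_damped), g)
        except np.linalg.LinAlgError:
            return state["m"]

    best = evaluate(mu0, lam_init)
    if best is None:
        raise IntegrationError("prediction is non-finite at the prior mean")
    trajectory = [best["F"]]
    damping = options.damping_init
    converged = False
    streak = 0
    rejects = 0
    theta = propose(best, damping)
    for it in range(1, options.max_iter):
        cand = evaluate(theta, best["lam"])
        if cand is not None and cand["F"] > best["F"]:
            dF = cand["F"] - best["F"]
            best = cand
            trajectory.append(best["F"])
            damping = max(damping * options.damping_down, 1e-8)
            rejects = 0
            if options.verbose:
                logger.info("iter %3d  F=%.4f  dF=%.4e  damping=%.3g",
                            it, best["F"], dF, damping)
            streak = streak + 1 if dF < options.tol else 0
            if streak >= options.patience:
                converged = True
                break
        else:
            damping *= options.damping_up
            rejects += 1
            if options.verbose:
                logger.info("iter %3d  rejected  damping=%.3g", it, damping)
            if rejects > options.max_rejects:
                # repeated failures with a tiny proposed improvement mean a
                # stationary point was reached rather than a numerical dead end
                if cand is not None and abs(cand["F"] - best["F"]) < options.tol:
                    converged = True
                break
        theta = propose(best, damping)

    sd_prior = np.sqrt(np.diag(S0))
    sd_post = np.sqrt(np.diag(best["Sigma"]))
    if (sd_post > sd_prior * (1.0 + 1e-6) + 1e-12).any():
        warnings.warn("some posterior variances exceed their prior variances",
                      RuntimeWarning, stacklevel=2)
    return dict(best=best, trajectory=np.asarray(trajectory), converged=converged)


def fit(spec: ModelSpec, data: Dataset, priors: GaussianDensity | None = None,
        noise: NoiseModel | None = None, options: FitOptions | None = None
        ) -> FitResult:
    """Invert the DCM for one dataset.

    ``priors`` and ``noise`` default to :func:`~dcmfmri.model.build_priors`
    and :func:`~dcmfmri.noise.default_noise` for the spec.  Fitting is
    deterministic given the data and options.
    """
    options = options or FitOptions()
    if data.n_regions != spec.n_regions:
        raise ValueError("data and spec disagree on the number of regions")
    if data.U.n_conditions != spec.n_conditions:
        raise ValueError("data and spec disagree on the number of conditions")
    if data.X0.shape[1] != spec.n_confounds:
        raise ValueError("X0 and spec disagree on the number of confounds")
    if priors is None:
        priors = build_priors(spec)
    n_free = len(build_index(spec))
    if priors.n != n_free:
        raise ValueError(f"priors cover {priors.n} parameters but the spec has "
                         f"{n_free} free parameters")
    if noise is None:
        noise = default_noise(spec, data.n_volumes)
    V, R = data.n_volumes, data.n_regions

    def forward_batch(thetas):
        yhat = _integrate_batch(thetas, spec, data.U, V, data.X0,
                                n_substeps=options.n_substeps)
        return np.swapaxes(yhat, 1, 2).reshape(thetas.shape[0], V * R)

    y = data.Y.ravel(order="F")
    out = variational_laplace(forward_batch, y, priors, noise, options)
    best = out["best"]
    posterior = GaussianDensity(best["m"], 0.5 * (best["Sigma"] + best["Sigma"].T),
                                priors.index)
    y_hat = best["h"].reshape(R, V).T
    return FitResult(
        posterior=posterior,
        lambdas=best["lam"],
        lambda_var=best["lam_var"],
        F=best["F"],
        F_trajectory=out["trajectory"],
        accuracy=best["acc"],
        complexity=best["comp"],
        prediction=Prediction(y_hat=y_hat),
        residuals=data.Y - y_hat,
        converged=out["converged"],
        n_iterations=len(out["trajectory"]),
    )


def free_energy(prediction: Prediction, data: Dataset, posterior: GaussianDensity,
                priors: GaussianDensity, noise: NoiseModel, lambdas,
                sensitivities: np.ndarray | None = None,
                lambda_var: np.ndarray | None = None):
    """Free energy and its accuracy/complexity decomposition.

    ``sensitivities`` (N x n_params, region-major rows) sharpens the
    accuracy term with the expected quadratic contribution of posterior
    parameter uncertainty; without it the expansion is taken at the
    posterior mean only.  ``lambda_var`` adds the hyperparameter KL term;
    omit both for a point assessment.  Returns ``(F, accuracy, complexity)``
    with ``F = accuracy - complexity``.
    """
    lambdas = np.asarray(lambdas, dtype=float).ravel()
    V, R = data.n_volumes, data.n_regions
    if lambdas.size != noise.n_components:
        raise ValueError("one log precision per noise component is required")
    e = (data.Y - prediction.y_hat).ravel(order="F")
    sse = np.array([float(e[r * V:(r + 1) * V] @ e[r * V:(r + 1) * V])
                    for r in range(R)])
    if sensitivities is not None:
        J = np.asarray(sensitivities, dtype=float)
        tr = np.array([float(np.einsum("ij,ik,jk->", J[r * V:(r + 1) * V],
                                       J[r * V:(r + 1) * V], posterior.cov))
                       for r in range(R)])
    else:
        tr = np.zeros(R)
    accuracy = _accuracy_terms(sse + tr, lambdas, V)
    try:
        S0_chol = cho_factor(priors.cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("prior covariance must be positive definite") from err
    sign, logdet_S0 = np.linalg.slogdet(priors.cov)
    complexity = _kl_gaussian(posterior.mean, posterior.cov, priors.mean,
                              S0_chol, logdet_S0)
    if lambda_var is not None:
        m, v = noise.lambda_prior()
        complexity += _kl_lambdas(lambdas, np.asarray(lambda_var, dtype=float), m, v)
    return accuracy - complexity, accuracy, complexity
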