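"""Gaussian maximum likelihood with a Kronecker-structured covariance.

The comparator model treats every response as continuous with an identity
link: ``y_i = X_i' beta + eps_i`` with ``eps_i ~ N(0, Sigma_B kron R(rho))``
in response-major stacking, i.e. a matrix-normal with Q x Q between-response
covariance ``Sigma_B`` (carrying all scale) and P x P within-response
*correlation* ``R(rho)`` (EX or AR(1); unit diagonal fixes the Kronecker
scale ambiguity).

Estimation is coordinate ascent ("flip-flop"): GLS for the means given the
covariance, the closed-form matrix-normal update for ``Sigma_B`` given
``R(rho)``, and a bounded one-dimensional likelihood maximization for
``rho``.  Each sub-step maximizes the exact likelihood in its own block, so
the log-likelihood is non-decreasing across iterations.

Group-specific means with a *common* covariance are supported directly:
the classical covariance-pattern formulation of normal-theory repeated
measures discriminant analysis estimates one structured covariance from the
pooled residuals of both groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .datamodel import DesignSet, ResponsePanel, linear_predictor
from .working_structure import AR1, EX, corr_within

_RHO_HI = 0.99


def gaussian_loglik(panel: ResponsePanel, design: DesignSet, beta,
                    Sigma: np.ndarray) -> float:
    """Sum of multivariate-normal log densities of y_i - X_i'beta under Sigma."""
    Q = panel.n_responses
    resid = panel.stacked() - linear_predictor(beta, design, Q)
    L = np.linalg.cholesky(Sigma)  # raises LinAlgError unless PD
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    half = solve_triangular(L, resid.T, lower=True)
    quad = float(np.sum(half * half))
    n, d = resid.shape
    return -0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad)


def _right_solve(E, R):
    """E_i R^{-1} for a stack of (Q, P) matrices."""
    return np.linalg.solve(R.T, E.transpose(0, 2, 1)).transpose(0, 2, 1)


def _gls_beta(Y, design: DesignSet, Q, Sigma_inv):
    """GLS estimate of the KQ coefficient vector for rows Y (n, PQ)."""
    P = design.n_occasions
    n = Y.shape[0]
    B = np.zeros((n, P * Q, 2 * Q))
    for q in range(Q):
        sl = slice(q * P, (q + 1) * P)
        B[:, sl, 2 * q] = design.x[:, None]
        B[:, sl, 2 * q + 1] = design.t[None, :]
    SB = np.matmul(Sigma_inv[None], B)
    info = np.einsum("npk,npl->kl", B, SB)
    score = np.einsum("npk,np->k", SB, Y)
    return np.linalg.solve(info, score)


@dataclass
class MLEFit:
    """Fitted Gaussian Kronecker-ML model (possibly with group-specific means)."""

    betas: dict                     # group label -> KQ coefficient vector
    Sigma_B: np.ndarray
    rho: float
    R_rho: np.ndarray
    within_kind: str
    loglik: float
    loglik_path: np.ndarray
    converged: bool
    n_iter: int
    Q: int
    P: int

    @property
    def Sigma(self) -> np.ndarray:
        """Assembled PQ x PQ covariance Sigma_B kron R(rho)."""
        return np.kron(self.Sigma_B, self.R_rho)

    def group_view(self, label) -> "MLEGroupView":
        return MLEGroupView(self, label)


@dataclass
class MLEGroupView:
    """One group's mean model plus the (shared) covariance, with the same
    surface :class:`rmda.mgee.GroupFit` offers to the discriminant rules."""

    fit: MLEFit
    label: object

    def fitted_means(self, design: DesignSet) -> np.ndarray:
        return linear_predictor(self.fit.betas[self.label], design, self.fit.Q)

    def omega_factors(self, design: DesignSet):
        mu = self.fitted_means(design)
        Sigma = self.fit.Sigma
        s = np.sqrt(np.diag(Sigma))
        C = Sigma / np.outer(s, s)
        return mu, np.broadcast_to(s, mu.shape), C


def fit_gaussian_kron_mle(panel: ResponsePanel, design: DesignSet,
                          within_kind: str = AR1, tol: float = 1e-6,
                          max_iter: int = 200, groups=None,
                          ridge: float = 1e-8) -> MLEFit:
    """Flip-flop ML fit of group means and a common Kronecker covariance.

    Parameters
    ----------
    groups : array-like of shape (N,), optional
        Group labels; when given, each group gets its own coefficient vector
        while a single covariance is estimated from the pooled residuals.
        ``None`` fits one mean model to the whole sample.
    """
    Q, P, N = panel.n_responses, panel.n_occasions, panel.n_individuals
    if N <= 2:
        raise ValueError("need more individuals than covariates")
    Y = panel.stacked()
    if groups is None:
        groups = np.zeros(N, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())

    rho = 0.0
    R_rho = corr_within(within_kind, P, rho)
    Sigma_B = np.eye(Q)
    lo = -_RHO_HI if within_kind == AR1 else max(-1.0 / (P - 1) + 1e-3, -_RHO_HI)

    path = []
    converged = False
    betas = {}
    it = 0
    for it in range(1, max_iter + 1):
        Sigma = np.kron(Sigma_B, R_rho)
        Sigma_inv = np.linalg.inv(Sigma)
        resid = np.empty_like(Y)
        for g in labels:
            m = groups == g
            sub = DesignSet(design.x[m], design.t)
            betas[g] = _gls_beta(Y[m], sub, Q, Sigma_inv)
            resid[m] = Y[m] - linear_predictor(betas[g], sub, Q)
        E = resid.reshape(N, Q, P)

        # exact conditional maximizer for Sigma_B given R_rho
        ER = _right_solve(E, R_rho)
        Sigma_B = np.einsum("nqp,nrp->qr", E, ER) / (N * P)
        Sigma_B = 0.5 * (Sigma_B + Sigma_B.T)
        if np.linalg.eigvalsh(Sigma_B)[0] <= ridge:
            Sigma_B = Sigma_B + ridge * np.trace(Sigma_B) / Q * np.eye(Q)

        if P > 1:
            SinvE = np.linalg.solve(Sigma_B, E.transpose(1, 0, 2).reshape(Q, -1))
            SinvE = SinvE.reshape(Q, N, P).transpose(1, 0, 2)

            def nll(r):
                Rr = corr_within(within_kind, P, r)
                sR, ldR = np.linalg.slogdet(Rr)
                if sR <= 0:
                    return np.inf
                quad = float(np.einsum("nqp,nqp->", SinvE, _right_solve(E, Rr)))
                return N * Q * ldR + quad

            res = minimize_scalar(nll, bounds=(lo, _RHO_HI), method="bounded",
                                  options={"xatol": 1e-6})
            rho = float(res.x)
        R_rho = corr_within(within_kind, P, rho)

        ll = _loglik_from_parts(E, Sigma_B, R_rho)
        path.append(ll)
        if len(path) > 1 and path[-1] - path[-2] < tol:
            converged = True
            break

    return MLEFit(betas=betas, Sigma_B=Sigma_B, rho=rho, R_rho=R_rho,
                  within_kind=within_kind, loglik=path[-1],
                  loglik_path=np.asarray(path), converged=converged,
                  n_iter=it, Q=Q, P=P)


def _loglik_from_parts(E, Sigma_B, R_rho):
    N, Q, P = E.shape
    _, ldB = np.linalg.slogdet(Sigma_B)
    _, ldR = np.linalg.slogdet(R_rho)
    SinvE = np.linalg.solve(Sigma_B, E.transpose(1, 0, 2).reshape(Q, -1))
    SinvE = SinvE.reshape(Q, N, P).transpose(1, 0, 2)
    quad = float(np.einsum("nqp,nqp->", SinvE, _right_solve(E, R_rho)))
    return -0.5 * (N * P * Q * np.log(2 * np.pi) + N * (P * ldB + Q * ldR) + quad)


class KroneckerMLE(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_gaussian_kron_mle`.

    Attributes after fit: ``coef_`` (single-group) or ``coefs_`` (dict),
    ``sigma_between_``, ``rho_``, ``covariance_``, ``loglik_``,
    ``converged_``, ``n_iter_``.
    """

    def __init__(self, within: str = AR1, tol: float = 1e-6, max_iter: int = 200):
        self.within = within
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, panel: ResponsePanel, design: DesignSet, groups=None):
        fit = fit_gaussian_kron_mle(panel, design, within_kind=self.within,
                                    tol=self.tol, max_iter=self.max_iter,
                                    groups=groups)
        self.result_ = fit
        self.coefs_ = fit.betas
        if len(fit.betas) == 1:
            self.coef_ = next(iter(fit.betas.values()))
        self.sigma_between_ = fit.Sigma_B
        self.rho_ = fit.rho
        self.covariance_ = fit.Sigma
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self
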