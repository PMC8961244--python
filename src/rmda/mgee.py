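"""Multivariate GEE for one population: Fisher scoring with a Kronecker
working covariance and moment updates for the nuisance parameters.

The marginal mean model is ``mu_ipq = f_q(beta_q1 x_i + beta_q2 t_p)`` with a
response-specific inverse link ``f_q``, and the estimating equations are

    U(beta) = sum_i D_i' Omega_i^{-1} (y_i - mu_i) = 0,

solved by Fisher scoring.  ``Omega_i`` is the Kronecker working covariance of
:mod:`rmda.working_structure`; after every scoring step the dispersion(s) and
the correlation parameters (alpha, rho) are refreshed from Pearson residuals.

Dispersion convention: a free per-response dispersion ``phi_q`` is estimated
for gaussian responses and fixed at 1 for Poisson/Bernoulli responses, so the
working variance of coordinate (q, p) is ``phi_q * v_q(mu_ipq)``.  Residuals
are standardized per response before the correlation moments are formed,
which keeps mixed-family panels on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .datamodel import (
    GAUSSIAN,
    DesignSet,
    ResponsePanel,
    family_spec,
    linear_predictor,
)
from .working_structure import (
    AR1,
    EX,
    assemble_omega,
    corr_between_un,
    corr_within,
    estimate_phi,
    moment_estimate_alpha,
    moment_estimate_rho,
    shrink_to_pd,
)

#: within-response structure tag that fixes both correlation factors at I
INDEPENDENCE = "ind"


@dataclass
class WorkingState:
    """Current working-covariance parameters during/after a fit."""

    R_alpha: np.ndarray
    R_rho: np.ndarray
    phi_q: np.ndarray  # per-response dispersion
    within_kind: str

    def kron_correlation(self) -> np.ndarray:
        return np.kron(self.R_alpha, self.R_rho)


def _family_list(families, Q):
    fams = [family_spec(f) for f in families]
    if len(fams) != Q:
        raise ValueError("one family per response required")
    return fams


def _moments(beta, design: DesignSet, families, Q):
    """Linear predictor, mean, d mu/d eta and variance function, all (N, PQ)."""
    eta = linear_predictor(beta, design, Q)
    P = design.n_occasions
    mu = np.empty_like(eta)
    dmu = np.empty_like(eta)
    var = np.empty_like(eta)
    for q, fam in enumerate(families):
        sl = slice(q * P, (q + 1) * P)
        mu[:, sl] = fam.inverse_link(eta[:, sl])
        dmu[:, sl] = fam.dmu_deta(eta[:, sl])
        var[:, sl] = fam.variance(mu[:, sl])
    return eta, mu, dmu, var


def _scaled_design(design: DesignSet, Q, g):
    """Batched B_i = diag(g_i) X_i' of shape (N, PQ, KQ) for g of shape (N, PQ).

    X_i = I_Q kron X_i* with X_i* = [x_i...x_i; t_1...t_P], so column 2q of
    B_i is g on block q times x_i and column 2q+1 is g on block q times t.
    """
    N = design.n_individuals
    P = design.n_occasions
    B = np.zeros((N, P * Q, 2 * Q))
    for q in range(Q):
        sl = slice(q * P, (q + 1) * P)
        B[:, sl, 2 * q] = g[:, sl] * design.x[:, None]
        B[:, sl, 2 * q + 1] = g[:, sl] * design.t[None, :]
    return B


def _working_sd(var, phi_q, P):
    """Working standard deviations sqrt(phi_q * v(mu)) of shape (N, PQ)."""
    return np.sqrt(var * np.repeat(phi_q, P)[None, :])


def estimating_function(beta, panel: ResponsePanel, design: DesignSet,
                        families, working: WorkingState) -> np.ndarray:
    """The GEE score U(beta) = sum_i D_i' Omega_i^{-1} (y_i - mu_i)."""
    Q, P = panel.n_responses, panel.n_occasions
    fams = _family_list(families, Q)
    _, mu, dmu, var = _moments(beta, design, fams, Q)
    s = _working_sd(var, working.phi_q, P)
    Cinv = np.linalg.inv(working.kron_correlation())
    B = _scaled_design(design, Q, dmu / s)
    resid = (panel.stacked() - mu) / s
    return np.einsum("npk,pq,nq->k", B, Cinv, resid)


def fisher_scoring_step(beta, panel: ResponsePanel, design: DesignSet,
                        families, working: WorkingState,
                        return_parts: bool = False):
    """One Fisher-scoring update of beta; optionally returns (info, score)."""
    Q, P = panel.n_responses, panel.n_occasions
    fams = _family_list(families, Q)
    _, mu, dmu, var = _moments(beta, design, fams, Q)
    s = _working_sd(var, working.phi_q, P)
    Cinv = np.linalg.inv(working.kron_correlation())
    B = _scaled_design(design, Q, dmu / s)
    resid = (panel.stacked() - mu) / s
    CB = np.matmul(Cinv[None, :, :], B)            # (N, PQ, KQ)
    info = np.einsum("npk,npl->kl", B, CB)
    score = np.einsum("npk,np->k", CB, resid)
    try:
        delta = np.linalg.solve(info, score)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular GEE information matrix; consider a ridge fallback or "
            "simpler working structure"
        ) from exc
    new_beta = np.asarray(beta, dtype=float) + delta
    if return_parts:
        return new_beta, info, score, (mu, dmu, var, s, B, Cinv, resid)
    return new_beta


def _init_beta(panel: ResponsePanel, design: DesignSet, fams) -> np.ndarray:
    """Per-response independence GLM starting values, stacked response-major."""
    N, Q, P = panel.values.shape
    Xr = np.column_stack([
        np.repeat(design.x, P),
        np.tile(design.t, N),
    ])  # (N*P, 2) rows ordered individual-major, occasion-fast
    beta = np.zeros(2 * Q)
    for q, fam in enumerate(fams):
        yq = panel.values[:, q, :].reshape(-1)
        if fam.name == GAUSSIAN:
            b, *_ = np.linalg.lstsq(Xr, yq, rcond=None)
        elif fam.name == "poisson":
            b, *_ = np.linalg.lstsq(Xr, np.log(yq + 0.5), rcond=None)
        else:  # bernoulli: a few ridge-IRLS steps
            b = np.zeros(2)
            for _ in range(8):
                p = 1.0 / (1.0 + np.exp(-np.clip(Xr @ b, -30, 30)))
                w = np.clip(p * (1 - p), 1e-6, None)
                z = Xr @ b + (yq - p) / w
                XtW = Xr.T * w
                b = np.linalg.solve(XtW @ Xr + 1e-8 * np.eye(2), XtW @ z)
        beta[2 * q: 2 * q + 2] = b
    return beta


_RESID_CLIP = 5.0  # standardized residuals winsorized before correlation moments


def _update_nuisance(resid_raw, var, fams, P, within_kind, n_cov=2):
    """Refresh (phi_q, alpha, rho) from current residuals.

    Standardized residuals are winsorized at +/- 5 before the correlation
    moments: near-degenerate discrete coordinates (fitted probabilities close
    to 0/1, tiny count means) otherwise produce isolated huge Pearson
    residuals that can pin the correlation estimates at the clip boundary.
    Returns the working state pieces plus the global scale estimate.
    """
    N = resid_raw.shape[0]
    Q = len(fams)
    pearson = resid_raw / np.sqrt(var)              # (N, PQ)
    r3 = pearson.reshape(N, Q, P)
    phi_q = np.ones(Q)
    for q, fam in enumerate(fams):
        if fam.canonical_dispersion:
            df = N * P - n_cov
            phi_q[q] = max(np.sum(r3[:, q, :] ** 2) / df, 1e-12)
    rstd = r3 / np.sqrt(phi_q)[None, :, None]
    rstd = np.clip(rstd, -_RESID_CLIP, _RESID_CLIP)
    if within_kind == INDEPENDENCE:
        alpha = np.zeros(Q * (Q - 1) // 2)
        rho = 0.0
        R_alpha, R_rho = np.eye(Q), np.eye(P)
        phi_global = estimate_phi(pearson, n_cov * Q)
        return phi_q, alpha, rho, R_alpha, R_rho, phi_global
    alpha = moment_estimate_alpha(rstd) if Q > 1 else np.empty(0)
    R_alpha = shrink_to_pd(corr_between_un(alpha)) if Q > 1 else np.eye(1)
    if P > 1:
        rho = moment_estimate_rho(rstd, within_kind)
        if within_kind == EX and P > 1:
            rho = float(np.clip(rho, -1.0 / (P - 1) + 1e-3, 0.99))
    else:
        rho = 0.0
    R_rho = corr_within(within_kind, P, rho)
    phi_global = estimate_phi(pearson, n_cov * Q)
    return phi_q, alpha, rho, R_alpha, R_rho, phi_global


@dataclass
class GroupFit:
    """Fitted multivariate GEE for one population."""

    beta: np.ndarray
    families: tuple
    Q: int
    P: int
    working: WorkingState
    alpha: np.ndarray
    rho: float
    phi: float                      # global scale, sum r^2 / (NPQ - KQ)
    converged: bool
    n_iter: int
    n_obs: int
    sandwich: np.ndarray | None = None
    t: np.ndarray | None = None

    def fitted_means(self, design: DesignSet) -> np.ndarray:
        """mu-hat (N, PQ) for (possibly new) individuals' covariates."""
        fams = _family_list(self.families, self.Q)
        _, mu, _, _ = _moments(self.beta, design, fams, self.Q)
        return mu

    def omega_factors(self, design: DesignSet):
        """Return (mu, s, C) with Omega_i = diag(s_i) C diag(s_i): the
        working sd is evaluated at each individual's own fitted means
        (mean-dependent-variance families get individual covariances), the
        correlation kernel is R(alpha) kron R(rho)."""
        fams = _family_list(self.families, self.Q)
        _, mu, _, var = _moments(self.beta, design, fams, self.Q)
        s = _working_sd(var, self.working.phi_q, self.P)
        return mu, s, self.working.kron_correlation()

    def omega_for(self, design: DesignSet) -> np.ndarray:
        """Dense working covariances (N, PQ, PQ)."""
        _, s, C = self.omega_factors(design)
        return s[:, :, None] * C[None, :, :] * s[:, None, :]


def fit_mgee(panel: ResponsePanel, design: DesignSet, families=None,
             within_kind: str = AR1, tol: float = 1e-6,
             max_iter: int = 100, compute_sandwich: bool = True) -> GroupFit:
    """Fit the multivariate GEE for a single group.

    Alternates one Fisher-scoring step for ``beta`` with moment updates of
    the dispersion and correlation parameters until ``max |delta beta| <
    tol`` or ``max_iter``; non-convergence is flagged, not raised.
    """
    families = panel.families if families is None else tuple(families)
    Q, P, N = panel.n_responses, panel.n_occasions, panel.n_individuals
    fams = _family_list(families, Q)
    Y = panel.stacked()

    beta = _init_beta(panel, design, fams)
    # nuisance from the initialization residuals
    _, mu, _, var = _moments(beta, design, fams, Q)
    phi_q, alpha, rho, R_alpha, R_rho, phi_g = _update_nuisance(
        Y - mu, var, fams, P, within_kind
    )
    working = WorkingState(R_alpha, R_rho, phi_q, within_kind)

    converged = False
    it = 0
    max_step = 5.0  # damp Fisher steps; guards against separation blow-up
    for it in range(1, max_iter + 1):
        new_beta, info, score, parts = fisher_scoring_step(
            beta, panel, design, families, working, return_parts=True
        )
        delta = new_beta - beta
        step = float(np.max(np.abs(delta)))
        if step > max_step:
            delta *= max_step / step
        beta = beta + delta
        _, mu, _, var = _moments(beta, design, fams, Q)
        phi_q, alpha, rho, R_alpha, R_rho, phi_g = _update_nuisance(
            Y - mu, var, fams, P, within_kind
        )
        working = WorkingState(R_alpha, R_rho, phi_q, within_kind)
        if step < tol:
            converged = True
            break

    fit = GroupFit(
        beta=beta, families=families, Q=Q, P=P, working=working,
        alpha=alpha, rho=rho, phi=phi_g, converged=converged, n_iter=it,
        n_obs=N, t=design.t.copy(),
    )
    if compute_sandwich:
        fit.sandwich = sandwich_cov(fit, panel, design)
    return fit


def sandwich_cov(fit: GroupFit, panel: ResponsePanel, design: DesignSet) -> np.ndarray:
    """Robust covariance of beta-hat: bread * meat * bread with empirical meat."""
    Q, P = fit.Q, fit.P
    fams = _family_list(fit.families, Q)
    _, mu, dmu, var = _moments(fit.beta, design, fams, Q)
    s = _working_sd(var, fit.working.phi_q, P)
    Cinv = np.linalg.inv(fit.working.kron_correlation())
    B = _scaled_design(design, Q, dmu / s)
    resid = (panel.stacked() - mu) / s
    CB = np.matmul(Cinv[None, :, :], B)
    info = np.einsum("npk,npl->kl", B, CB)
    u = np.einsum("npk,np->nk", CB, resid)          # per-individual scores
    meat = u.T @ u
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular bread matrix") from exc
    S = bread @ meat @ bread
    return 0.5 * (S + S.T)


def fitted_means(fit: GroupFit, design: DesignSet) -> np.ndarray:
    """Blockwise inverse-link means for the given covariates (N, PQ)."""
    return fit.fitted_means(design)


class MultivariateGEE(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_mgee` for one group.

    Parameters
    ----------
    families : sequence of str or None
        Per-response family tags; ``None`` uses the panel's tags.
    within : {"ar1", "ex"}
        Within-response working correlation structure.
    tol, max_iter : float, int
        Fisher-scoring convergence controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray (KQ,) -- response-major regression estimates.
    dispersion_ : float -- global scale estimate.
    dispersion_per_response_ : ndarray (Q,).
    alpha_, rho_ : working correlation estimates.
    sandwich_cov_ : ndarray (KQ, KQ).
    converged_, n_iter_ : convergence diagnostics.
    """

    def __init__(self, families=None, within: str = AR1, tol: float = 1e-6,
                 max_iter: int = 100):
        self.families = families
        self.within = within
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, panel: ResponsePanel, design: DesignSet):
        fit = fit_mgee(panel, design, families=self.families,
                       within_kind=self.within, tol=self.tol,
                       max_iter=self.max_iter)
        self.result_ = fit
        self.coef_ = fit.beta
        self.dispersion_ = fit.phi
        self.dispersion_per_response_ = fit.working.phi_q
        self.alpha_ = fit.alpha
        self.rho_ = fit.rho
        self.sandwich_cov_ = fit.sandwich
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self

    def predict(self, design: DesignSet) -> np.ndarray:
        """Fitted mean vectors (N, PQ) for the given covariates."""
        return self.result_.fitted_means(design)
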