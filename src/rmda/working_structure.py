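"""Kronecker-product working covariance: construction and moment estimation.

The working covariance for one individual is

    Omega_i = phi * A_i^{1/2} (R(alpha) kron R(rho)) A_i^{1/2}

with ``A_i`` the diagonal of marginal variances ``v(mu_ipq)``, ``R(alpha)``
the unstructured Q x Q between-response correlation and ``R(rho)`` the
P x P within-response correlation (exchangeable or AR(1)).  The Kronecker
order matches the response-major stacking: response index slow, occasion
fast, so entry ((q,p),(q',p')) couples as R(alpha)[q,q'] * R(rho)[p,p'].

Correlation parameters are estimated from Pearson residuals by standard
cross-product moment estimators.
"""

from __future__ import annotations

import numpy as np

EX = "ex"
AR1 = "ar1"
_CLIP = 0.99  # estimated correlations clipped into (-0.99, 0.99)


def corr_within(kind: str, P: int, rho: float) -> np.ndarray:
    """Within-response correlation matrix: EX (compound symmetry) or AR(1)."""
    kind = kind.lower()
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if kind == AR1:
        idx = np.arange(P)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if kind == EX:
        if P > 1 and rho <= -1.0 / (P - 1):
            raise ValueError(
                f"exchangeable correlation with rho={rho} is not positive "
                f"definite for P={P}"
            )
        R = np.full((P, P), float(rho))
        np.fill_diagonal(R, 1.0)
        return R
    raise ValueError(f"unknown within-response structure {kind!r}")


def corr_between_un(alpha: np.ndarray, require_pd: bool = False) -> np.ndarray:
    """Unstructured Q x Q correlation from its strict lower triangle.

    ``alpha`` fills the strict lower triangle in row-major order, i.e.
    (2,1), (3,1), (3,2), (4,1), ... (one-based).  If the result is not
    positive definite it is returned as-is unless ``require_pd``; callers
    that need PD use :func:`shrink_to_pd`.
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    if np.any(np.abs(alpha) >= 1):
        raise ValueError("between-response correlations must lie in (-1, 1)")
    m = alpha.size
    Q = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if Q * (Q - 1) // 2 != m:
        raise ValueError(f"alpha length {m} is not a triangular number")
    R = np.eye(Q)
    rows, cols = np.tril_indices(Q, k=-1)
    R[rows, cols] = alpha
    R[cols, rows] = alpha
    if require_pd and np.linalg.eigvalsh(R)[0] <= 0:
        raise ValueError("between-response correlation matrix is not PD")
    return R


def lower_triangle(R: np.ndarray) -> np.ndarray:
    """Row-major strict lower triangle of a square matrix (inverse of fill)."""
    rows, cols = np.tril_indices(R.shape[0], k=-1)
    return np.asarray(R)[rows, cols]


def is_pd(M: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(M)[0] > tol)


def shrink_to_pd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Shrink a correlation matrix toward the identity until min eig >= floor.

    Uses the smallest convex weight w such that (1-w) R + w I has minimum
    eigenvalue at least ``floor``; keeps the unit diagonal exactly.
    """
    lam = np.linalg.eigvalsh(R)[0]
    if lam >= floor:
        return R
    w = (floor - lam) / (1.0 - lam)
    w = min(max(w, 0.0), 1.0)
    out = (1 - w) * R + w * np.eye(R.shape[0])
    np.fill_diagonal(out, 1.0)
    return out


def assemble_omega(A_diag: np.ndarray, R_alpha: np.ndarray, R_rho: np.ndarray,
                   phi: float = 1.0) -> np.ndarray:
    """phi * diag(A)^1/2 (R_alpha kron R_rho) diag(A)^1/2, response-major order."""
    A_diag = np.asarray(A_diag, dtype=float).ravel()
    if np.any(A_diag <= 0):
        raise ValueError("marginal variances must be strictly positive")
    if phi <= 0:
        raise ValueError("phi must be positive")
    s = np.sqrt(A_diag)
    C = np.kron(R_alpha, R_rho)
    return phi * (s[:, None] * C * s[None, :])


def estimate_phi(pearson_residuals: np.ndarray, n_params: int) -> float:
    """Scale parameter: sum of squared Pearson residuals over residual df."""
    r = np.asarray(pearson_residuals, dtype=float)
    df = r.size - n_params
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    return float(np.sum(r * r) / df)


def moment_estimate_rho(std_residuals: np.ndarray, kind: str) -> float:
    """Within-response correlation from standardized residuals (N, Q, P).

    AR(1): mean over individuals, responses and adjacent occasion pairs of
    r_{.,p} r_{.,p+1}; EX: mean over all distinct within-response occasion
    pairs.  Clipped to (-0.99, 0.99).
    """
    r = np.asarray(std_residuals, dtype=float)
    if r.ndim != 3:
        raise ValueError("residuals must have shape (N, Q, P)")
    P = r.shape[2]
    if P < 2:
        raise ValueError("need at least two occasions to estimate rho")
    kind = kind.lower()
    if kind == AR1:
        est = float(np.mean(r[:, :, :-1] * r[:, :, 1:]))
    elif kind == EX:
        # sum over all ordered pairs = (sum_p r)^2 - sum_p r^2; halve for unordered
        tot = r.sum(axis=2)
        est = float(np.mean((tot * tot - (r * r).sum(axis=2)) / (P * (P - 1))))
    else:
        raise ValueError(f"unknown within-response structure {kind!r}")
    return float(np.clip(est, -_CLIP, _CLIP))


def moment_estimate_alpha(std_residuals: np.ndarray) -> np.ndarray:
    """Between-response correlations from standardized residuals (N, Q, P).

    For each unordered response pair (q, q'), the mean over individuals and
    occasions of r_{iqp} r_{iq'p}; returned in row-major lower-triangle order.
    """
    r = np.asarray(std_residuals, dtype=float)
    if r.ndim != 3:
        raise ValueError("residuals must have shape (N, Q, P)")
    Q = r.shape[1]
    if Q < 2:
        raise ValueError("need at least two responses to estimate alpha")
    # (Q, Q) average same-occasion cross products
    C = np.einsum("iqp,irp->qr", r, r) / (r.shape[0] * r.shape[2])
    return np.clip(lower_triangle(C), -_CLIP, _CLIP)
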