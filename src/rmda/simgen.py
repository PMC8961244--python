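"""Synthetic multivariate longitudinal data for the simulation study.

Three data cases are generated for two populations:

* ``normal`` -- Q jointly normal responses with identity-link means
  ``mu_ipq = beta_q1 x_i + beta_q2 t_p``, a common marginal variance of 60
  and Kronecker correlation ``R(alpha) kron R(rho)``.
* ``poisson`` -- correlated counts with log-link means ``log mu_ipq =
  beta_q1 x_i + beta_q2 log t_p``, joint dependence induced by a Gaussian
  copula on the latent correlation ``R(alpha) kron R(rho)`` (NORTA: counts
  are Poisson quantiles of the latent normal CDF values).  The achieved
  count correlation is attenuated relative to the latent one; no
  Cario-Nelson matching is applied.
* ``mixed`` -- the normal case with the last response converted to a
  Bernoulli variable by NORTA thresholding: success probability
  ``p_ipq = logistic(beta_q1 x_i + beta_q2 t_p)`` and ``y = 1`` iff the
  standardized latent normal exceeds its ``(1 - p)`` quantile, which
  preserves the latent correlation linkage.

The between-response correlation matrices (keyed by Q and the
within-response coefficient rho) and the true coefficient vectors for both
populations are the study's printed configuration; population 2's
coefficients are 2x population 1's for the normal/mixed rows and 3x for the
Poisson rows.  Covariance heterogeneity multiplies population 1's
generating covariance by 3 (normal/mixed only -- a copula carries no scale,
so for counts the heterogeneous arm differs only through the group
coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import BERNOULLI, GAUSSIAN, POISSON, DesignSet, ResponsePanel
from .working_structure import AR1, EX, corr_within

COMMON_VARIANCE = 60.0
_MU_MAX = 1e6

#: Unstructured between-response correlation matrices keyed by (Q, rho).
BETWEEN_CORR = {
    (3, 0.3): np.array([
        [1.00, 0.15, 0.30],
        [0.15, 1.00, 0.45],
        [0.30, 0.45, 1.00],
    ]),
    (3, 0.7): np.array([
        [1.00, 0.65, 0.66],
        [0.65, 1.00, 0.70],
        [0.66, 0.70, 1.00],
    ]),
    (5, 0.3): np.array([
        [1.00, 0.28, 0.25, 0.28, 0.28],
        [0.28, 1.00, 0.30, 0.40, 0.23],
        [0.25, 0.30, 1.00, 0.24, 0.24],
        [0.28, 0.40, 0.24, 1.00, 0.37],
        [0.28, 0.23, 0.24, 0.37, 1.00],
    ]),
    (5, 0.7): np.array([
        [1.00, 0.70, 0.79, 0.64, 0.70],
        [0.70, 1.00, 0.73, 0.65, 0.74],
        [0.79, 0.73, 1.00, 0.63, 0.62],
        [0.64, 0.65, 0.63, 1.00, 0.62],
        [0.70, 0.74, 0.62, 0.62, 1.00],
    ]),
}

#: Population-1 coefficient vectors, response-major (beta_q1, beta_q2) pairs,
#: and the population-2 multiplier.
_TRUE_BETA_1 = {
    ("normal", 3): np.array([0.3, 1, 2, 0.1, 1, 1.5]),
    ("normal", 5): np.array([0.2, 1, 2, 1.5, 1, 0.4, 0.7, 3, 1.2, 0.8]),
    ("poisson", 3): np.array([0.3, 0.1, 0.2, 0.1, 0.3, 0.5]),
    ("poisson", 5): np.array([0.3, 0.1, 0.4, 0.1, 0.45, 0.6, 0.2, 0.15, 0.3, 0.4]),
}
_POP2_FACTOR = {"normal": 2.0, "poisson": 3.0}

DISTRIBUTIONS = ("normal", "poisson", "mixed")


def true_beta(distribution: str, Q: int, group: int) -> np.ndarray:
    """True coefficient vector for one population (mixed uses the normal row)."""
    key = "normal" if distribution in ("normal", "mixed") else distribution
    if (key, Q) not in _TRUE_BETA_1:
        raise ValueError(f"no coefficients for distribution={distribution!r}, Q={Q}")
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    b = _TRUE_BETA_1[(key, Q)].astype(float)
    return b if group == 1 else _POP2_FACTOR[key] * b


@dataclass(frozen=True)
class SimCondition:
    """One simulation sub-condition of the Monte Carlo grid."""

    distribution: str
    Q: int
    P: int
    N: int
    n1: int
    n2: int
    within_kind: str = AR1
    rho: float = 0.3
    heterogeneity: float = 1.0  # population-1 covariance scale (1 or 3)
    #: interpolation of the group mean contrast: population-2 coefficients are
    #: beta_1 + separation_scale * (beta_2 - beta_1).  1 is the study design;
    #: 0 makes the groups identically distributed (a chance-level control).
    separation_scale: float = 1.0

    def __post_init__(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.n1 + self.n2 != self.N:
            raise ValueError("group sizes must sum to N")
        if (self.Q, self.rho) not in BETWEEN_CORR:
            raise ValueError(f"no between-response matrix for (Q={self.Q}, rho={self.rho})")


def group_sizes(N: int, ratio: str) -> tuple[int, int]:
    """Group sizes for a '1:1' or '2:3' split of N (e.g. N=80, 2:3 -> (32, 48))."""
    if ratio == "1:1":
        return N // 2, N - N // 2
    if ratio == "2:3":
        n1 = int(round(N * 2 / 5))
        return n1, N - n1
    raise ValueError(f"unknown ratio {ratio!r}")


def latent_correlation(cond: SimCondition) -> np.ndarray:
    """R(alpha) kron R(rho) in response-major order."""
    R_alpha = BETWEEN_CORR[(cond.Q, cond.rho)]
    R_rho = corr_within(cond.within_kind, cond.P, cond.rho)
    return np.kron(R_alpha, R_rho)


def condition_beta(cond: SimCondition, group: int) -> np.ndarray:
    """Generating coefficients for one group under a condition (including the
    separation-scale interpolation)."""
    b1 = true_beta(cond.distribution, cond.Q, 1)
    if group == 1:
        return b1
    b2 = true_beta(cond.distribution, cond.Q, 2)
    return b1 + cond.separation_scale * (b2 - b1)


def _labels_and_x(cond: SimCondition, rng):
    labels = np.repeat([1, 2], [cond.n1, cond.n2])
    x = rng.standard_normal(cond.N)
    return labels, x


def _mean_matrix(cond: SimCondition, x, t_design, link_exp: bool):
    """(N, PQ) means per individual given each one's own group coefficients."""
    eta = np.empty((cond.N, cond.Q * cond.P))
    for g, sl in ((1, slice(0, cond.n1)), (2, slice(cond.n1, cond.N))):
        b = condition_beta(cond, g)
        b1, b2 = b[0::2], b[1::2]
        e = x[sl, None, None] * b1[None, :, None] + (b2[:, None] * t_design[None, :])[None]
        eta[sl] = e.reshape(-1, cond.Q * cond.P)
    return np.exp(eta) if link_exp else eta


def gen_normal(cond: SimCondition, seed) -> tuple[ResponsePanel, DesignSet]:
    """Multivariate normal panels with common variance 60."""
    if cond.distribution not in ("normal", "mixed"):
        raise ValueError("gen_normal requires a normal/mixed condition")
    rng = np.random.default_rng(seed)
    labels, x = _labels_and_x(cond, rng)
    t = np.arange(1, cond.P + 1, dtype=float)
    mu = _mean_matrix(cond, x, t, link_exp=False)
    C = latent_correlation(cond)
    L = np.linalg.cholesky(COMMON_VARIANCE * C)
    z = rng.standard_normal((cond.N, cond.Q * cond.P))
    eps = z @ L.T
    scale = np.where(labels == 1, np.sqrt(cond.heterogeneity), 1.0)
    y = mu + scale[:, None] * eps
    panel = ResponsePanel(y.reshape(cond.N, cond.Q, cond.P),
                          [GAUSSIAN] * cond.Q, group_label=labels)
    return panel, DesignSet(x=x, t=t)


def gen_poisson(cond: SimCondition, seed) -> tuple[ResponsePanel, DesignSet]:
    """Gaussian-copula (NORTA) multivariate Poisson panels; log-link means
    with log time as the time-varying covariate."""
    if cond.distribution != "poisson":
        raise ValueError("gen_poisson requires a poisson condition")
    rng = np.random.default_rng(seed)
    labels, x = _labels_and_x(cond, rng)
    t_design = np.log(np.arange(1, cond.P + 1, dtype=float))
    mu = _mean_matrix(cond, x, t_design, link_exp=True)
    if np.any(mu > _MU_MAX):
        raise OverflowError(
            f"Poisson mean exceeds {_MU_MAX:g} under condition {cond}"
        )
    C = latent_correlation(cond)
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((cond.N, cond.Q * cond.P)) @ L.T
    u = stats.norm.cdf(z)
    y = stats.poisson.ppf(u, mu)
    panel = ResponsePanel(y.reshape(cond.N, cond.Q, cond.P),
                          [POISSON] * cond.Q, group_label=labels)
    return panel, DesignSet(x=x, t=t_design)


def gen_mixed(cond: SimCondition, seed) -> tuple[ResponsePanel, DesignSet]:
    """Normal panels with the last response NORTA-converted to Bernoulli."""
    if cond.distribution != "mixed":
        raise ValueError("gen_mixed requires a mixed condition")
    panel, design = gen_normal(cond, seed)
    N, Q, P = panel.values.shape
    labels = panel.group_label
    t = design.t
    # last response: the same linear predictor serves as the normal-scale
    # mean (for standardizing the latent draw) and the logit of the target
    # Bernoulli probability
    mu_last = np.empty((N, P))
    for g in (1, 2):
        m = labels == g
        b = condition_beta(cond, g)
        mu_last[m] = b[-2] * design.x[m, None] + b[-1] * t[None, :]
    p = 1.0 / (1.0 + np.exp(-mu_last))
    sd = np.sqrt(COMMON_VARIANCE * np.where(labels == 1, cond.heterogeneity, 1.0))
    z = (panel.values[:, -1, :] - mu_last) / sd[:, None]
    ybin = (z > stats.norm.ppf(1.0 - p)).astype(float)
    values = panel.values.copy()
    values[:, -1, :] = ybin
    families = [GAUSSIAN] * (Q - 1) + [BERNOULLI]
    return ResponsePanel(values, families, group_label=labels), design


def generate(cond: SimCondition, seed) -> tuple[ResponsePanel, DesignSet]:
    """Dispatch on the condition's distribution."""
    if cond.distribution == "normal":
        return gen_normal(cond, seed)
    if cond.distribution == "poisson":
        return gen_poisson(cond, seed)
    return gen_mixed(cond, seed)
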