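"""Linear and quadratic discriminant rules for repeated measures data.

Both rules compare an individual's stacked response vector ``y_i`` with the
group-specific mean vectors predicted at the individual's *own* covariates,
using the group covariance matrices evaluated at those fitted means (so
mean-dependent-variance families get individual-specific covariances).

Linear rule (pooled covariance ``Omega``): assign to group 1 iff

    (y - (mu1 + mu2)/2)' Omega^{-1} (mu1 - mu2) > log(pi2 / pi1).

Quadratic rule (group covariances ``Omega1, Omega2``): assign to group 1 iff

    (y - mu2)' Omega2^{-1} (y - mu2) - (y - mu1)' Omega1^{-1} (y - mu1)
        > log(|Omega1| / |Omega2|) + 2 log(pi2 / pi1).

Ties (score exactly 0 after moving the right-hand side over) go to group 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datamodel import GAUSSIAN, DesignSet, ResponsePanel
from .kron_mle import fit_gaussian_kron_mle
from .mgee import fit_mgee
from .working_structure import AR1

_COND_MAX = 1e10
_RIDGE_EPS = 1e-8

LINEAR = "linear"
QUADRATIC = "quadratic"


def _ridge_if_needed(Omega: np.ndarray) -> np.ndarray:
    """Stabilize a near-singular covariance: add eps * mean(diag) * I when the
    condition number exceeds 1e10."""
    if np.linalg.cond(Omega) > _COND_MAX:
        return Omega + _RIDGE_EPS * float(np.mean(np.diag(Omega))) * np.eye(len(Omega))
    return Omega


def pool_covariance(Omega1: np.ndarray, Omega2: np.ndarray,
                    n1: int, n2: int) -> np.ndarray:
    """((n1-1) Omega1 + (n2-1) Omega2) / (n1 + n2 - 2)."""
    if n1 + n2 <= 2:
        raise ValueError("pooling requires n1 + n2 > 2")
    return ((n1 - 1) * np.asarray(Omega1) + (n2 - 1) * np.asarray(Omega2)) / (
        n1 + n2 - 2
    )


def linear_score(y, mu1, mu2, Omega, pi1, pi2) -> float:
    """Group-1 linear discriminant score; positive means 'group 1'."""
    y, mu1, mu2 = (np.asarray(v, dtype=float).ravel() for v in (y, mu1, mu2))
    Omega = _ridge_if_needed(np.atleast_2d(np.asarray(Omega, dtype=float)))
    w = np.linalg.solve(Omega, mu1 - mu2)
    return float((y - 0.5 * (mu1 + mu2)) @ w - np.log(pi2 / pi1))


def quadratic_score(y, mu1, mu2, Omega1, Omega2, pi1, pi2) -> float:
    """Group-1 quadratic discriminant score; positive means 'group 1'.

    Log-determinants come from ``slogdet`` (stable factorization).
    """
    y, mu1, mu2 = (np.asarray(v, dtype=float).ravel() for v in (y, mu1, mu2))
    Omega1 = _ridge_if_needed(np.atleast_2d(np.asarray(Omega1, dtype=float)))
    Omega2 = _ridge_if_needed(np.atleast_2d(np.asarray(Omega2, dtype=float)))
    d2 = y - mu2
    d1 = y - mu1
    q2 = float(d2 @ np.linalg.solve(Omega2, d2))
    q1 = float(d1 @ np.linalg.solve(Omega1, d1))
    s1, ld1 = np.linalg.slogdet(Omega1)
    s2, ld2 = np.linalg.slogdet(Omega2)
    if s1 <= 0 or s2 <= 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite")
    return float(q2 - q1 - (ld1 - ld2) - 2.0 * np.log(pi2 / pi1))


@dataclass
class DiscriminantRule:
    """A fitted two-group classification rule.

    ``fit1``/``fit2`` expose ``fitted_means(design)`` and
    ``omega_factors(design)`` (GEE group fits or ML group views).
    """

    kind: str
    fit1: object
    fit2: object
    pi1: float
    pi2: float
    n1: int
    n2: int
    labels: tuple = (1, 2)

    def __post_init__(self):
        if not (self.pi1 > 0 and self.pi2 > 0):
            raise ValueError("priors must be positive")
        if abs(self.pi1 + self.pi2 - 1.0) > 1e-12:
            raise ValueError("priors must sum to one")
        if self.kind not in (LINEAR, QUADRATIC):
            raise ValueError(f"unknown rule kind {self.kind!r}")

    # -- batched scoring ---------------------------------------------------
    def scores(self, panel: ResponsePanel, design: DesignSet) -> np.ndarray:
        """Group-1 score for every individual (positive => group 1)."""
        Y = panel.stacked()
        mu1, s1, C1 = self.fit1.omega_factors(design)
        mu2, s2, C2 = self.fit2.omega_factors(design)
        log_prior = np.log(self.pi2 / self.pi1)
        const_s = _rows_constant(s1) and _rows_constant(s2)

        if self.kind == QUADRATIC:
            q1, ld1 = _quad_forms(Y, mu1, s1, C1)
            q2, ld2 = _quad_forms(Y, mu2, s2, C2)
            return q2 - q1 - (ld1 - ld2) - 2.0 * log_prior

        # linear: pooled per-individual covariance
        if const_s:
            O1 = _assemble(s1[0], C1)
            O2 = _assemble(s2[0], C2)
            Op = _ridge_if_needed(pool_covariance(O1, O2, self.n1, self.n2))
            w = np.linalg.solve(Op, (mu1 - mu2).T).T        # (N, PQ)
        else:
            O1 = s1[:, :, None] * C1[None] * s1[:, None, :]
            O2 = s2[:, :, None] * C2[None] * s2[:, None, :]
            Op = pool_covariance(O1, O2, self.n1, self.n2)
            w = np.linalg.solve(Op, (mu1 - mu2)[:, :, None])[:, :, 0]
        return np.einsum("np,np->n", Y - 0.5 * (mu1 + mu2), w) - log_prior

    def predict(self, panel: ResponsePanel, design: DesignSet) -> np.ndarray:
        sc = self.scores(panel, design)
        return np.where(sc > 0, self.labels[0], self.labels[1])


def _rows_constant(s):
    return bool(np.all(s == s[0]))


def _assemble(s_row, C):
    return s_row[:, None] * C * s_row[None, :]


def _quad_forms(Y, mu, s, C):
    """Mahalanobis forms (y-mu)' Omega^{-1} (y-mu) and log|Omega| for
    Omega_i = diag(s_i) C diag(s_i), batched over individuals."""
    C = _ridge_if_needed(C)
    Cinv = np.linalg.inv(C)
    sgn, ldC = np.linalg.slogdet(C)
    if sgn <= 0:
        raise np.linalg.LinAlgError("correlation kernel is not positive definite")
    Z = (Y - mu) / s
    q = np.einsum("np,pq,nq->n", Z, Cinv, Z)
    ld = ldC + 2.0 * np.sum(np.log(s), axis=1)
    return q, ld


def classify_individual(rule: DiscriminantRule, panel: ResponsePanel,
                        design: DesignSet, i: int):
    """Label for individual ``i`` of the panel (ties go to group 2)."""
    if not 0 <= i < panel.n_individuals:
        raise IndexError(f"individual index {i} out of range")
    mask = np.zeros(panel.n_individuals, dtype=bool)
    mask[i] = True
    return rule.predict(panel.subset(mask), design.subset(mask))[0]


def resub_accuracy(rule: DiscriminantRule, panel: ResponsePanel,
                   design: DesignSet):
    """Resubstitution accuracy: (overall, {label: group-conditional})."""
    if panel.n_individuals == 0:
        raise ValueError("empty panel")
    if panel.group_label is None:
        raise ValueError("panel has no group labels")
    pred = rule.predict(panel, design)
    truth = panel.group_label
    overall = float(np.mean(pred == truth))
    per_group = {
        lab: float(np.mean(pred[truth == lab] == lab)) for lab in rule.labels
    }
    return overall, per_group


def build_rule(panel: ResponsePanel, design: DesignSet, estimator: str = "gee",
               rule: str = LINEAR, within: str = AR1, tol: float = 1e-6,
               max_iter: int = 100) -> DiscriminantRule:
    """Fit group models and assemble a discriminant rule from labelled data.

    ``estimator="gee"`` fits a multivariate GEE per group (group-specific
    means, dispersions and working correlations).  ``estimator="mle"`` fits
    the Gaussian covariance-pattern comparator: group-specific means with a
    single Kronecker-structured covariance ML-estimated from the pooled
    residuals of both groups (so its linear and quadratic rules coincide).
    """
    labels = np.unique(panel.group_label)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    m1 = panel.group_label == labels[0]
    m2 = ~m1
    n1, n2 = int(m1.sum()), int(m2.sum())
    if estimator == "gee":
        f1 = fit_mgee(panel.subset(m1), design.subset(m1), within_kind=within,
                      tol=tol, max_iter=max_iter, compute_sandwich=False)
        f2 = fit_mgee(panel.subset(m2), design.subset(m2), within_kind=within,
                      tol=tol, max_iter=max_iter, compute_sandwich=False)
        if not (f1.converged and f2.converged):
            raise ConvergenceError("GEE group fit did not converge")
    elif estimator == "mle":
        fam = [GAUSSIAN] * panel.n_responses
        gauss_panel = ResponsePanel(panel.values, fam, panel.group_label)
        mfit = fit_gaussian_kron_mle(gauss_panel, design, within_kind=within,
                                     tol=tol, groups=panel.group_label)
        f1 = mfit.group_view(labels[0])
        f2 = mfit.group_view(labels[1])
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    N = n1 + n2
    return DiscriminantRule(kind=rule, fit1=f1, fit2=f2, pi1=n1 / N,
                            pi2=n2 / N, n1=n1, n2=n2,
                            labels=(labels[0], labels[1]))


class ConvergenceError(RuntimeError):
    """A group model failed to converge; the replicate should be dropped."""


# ---------------------------------------------------------------------------
# scikit-learn front end
# ---------------------------------------------------------------------------

def matrix_from_panel(panel: ResponsePanel, design: DesignSet) -> np.ndarray:
    """Flatten panel + covariate into the (N, Q*P + 1) feature matrix used by
    :class:`RepeatedMeasuresClassifier`: response-major stacked responses
    followed by the time-invariant covariate ``x`` as the last column."""
    return np.column_stack([panel.stacked(), design.x])


def panel_from_matrix(X: np.ndarray, Q: int, P: int, families, t,
                      y=None) -> tuple[ResponsePanel, DesignSet]:
    """Inverse of :func:`matrix_from_panel`."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != Q * P + 1:
        raise ValueError(f"expected {Q * P + 1} columns (Q*P responses + x)")
    values = X[:, : Q * P].reshape(-1, Q, P)
    panel = ResponsePanel(values, families, group_label=y)
    return panel, DesignSet(x=X[:, -1], t=np.asarray(t, dtype=float))


class RepeatedMeasuresClassifier(ClassifierMixin, BaseEstimator):
    """Two-group repeated measures discriminant analysis.

    Features are the response-major stacked longitudinal responses (``Q * P``
    columns, occasion fastest) followed by one time-invariant covariate; the
    occasion times are a model parameter.  Group mean trajectories and a
    Kronecker-structured covariance are estimated either by multivariate GEE
    (group-specific working covariances) or by Gaussian ML (covariance
    pattern model with one pooled structured covariance), and individuals are
    assigned by the linear or quadratic discriminant rule with proportional
    priors.

    Parameters
    ----------
    n_responses, n_occasions : int
        Panel dimensions Q and P.
    families : str or sequence of str, default "gaussian"
        Marginal family per response ("gaussian", "poisson", "bernoulli");
        a single string is broadcast to all responses.
    estimator : {"gee", "mle"}, default "gee"
    rule : {"linear", "quadratic"}, default "linear"
    within : {"ar1", "ex"}, default "ar1"
        Within-response working correlation structure.
    occasion_times : array-like of length P, optional
        Time covariate values; default ``1..P``.
    tol, max_iter : Fisher-scoring controls for the GEE fits.

    Examples
    --------
    >>> clf = RepeatedMeasuresClassifier(n_responses=3, n_occasions=3)
    >>> clf.fit(X, y).predict(X)          # doctest: +SKIP
    """

    def __init__(self, n_responses: int = 1, n_occasions: int = 1,
                 families="gaussian", estimator: str = "gee",
                 rule: str = LINEAR, within: str = AR1,
                 occasion_times=None, tol: float = 1e-6, max_iter: int = 100):
        self.n_responses = n_responses
        self.n_occasions = n_occasions
        self.families = families
        self.estimator = estimator
        self.rule = rule
        self.within = within
        self.occasion_times = occasion_times
        self.tol = tol
        self.max_iter = max_iter

    def _families(self):
        if isinstance(self.families, str):
            return [self.families] * self.n_responses
        return list(self.families)

    def _times(self):
        if self.occasion_times is None:
            return np.arange(1, self.n_occasions + 1, dtype=float)
        return np.asarray(self.occasion_times, dtype=float)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        panel, design = panel_from_matrix(
            X, self.n_responses, self.n_occasions, self._families(),
            self._times(), y=y,
        )
        self.rule_ = build_rule(panel, design, estimator=self.estimator,
                                rule=self.rule, within=self.within,
                                tol=self.tol, max_iter=self.max_iter)
        return self

    def decision_function(self, X):
        """Score of membership in the *first* class (``classes_[0]``);
        positive values predict ``classes_[0]``."""
        check_is_fitted(self, "rule_")
        X = check_array(X)
        panel, design = panel_from_matrix(
            X, self.n_responses, self.n_occasions, self._families(),
            self._times(),
        )
        return self.rule_.scores(panel, design)

    def predict(self, X):
        sc = self.decision_function(X)
        return np.where(sc > 0, self.classes_[0], self.classes_[1])

    def score_groups(self, X, y):
        """Overall and group-conditional resubstitution-style accuracy."""
        pred = self.predict(X)
        overall = float(np.mean(pred == y))
        per = {c: float(np.mean(pred[y == c] == c)) for c in self.classes_}
        return overall, per
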