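"""Core containers and index conventions for multivariate repeated measures data.

A dataset holds ``N`` individuals, each observed on ``Q`` response variables
at ``P`` common occasions.  Everywhere in the package the ``PQ``-vector for
one individual is stacked *response-major, occasion-fastest*: coordinate
``(q, p)`` (zero-based) sits at position ``q * P + p``.  The regression
coefficient vector follows the same convention, ``beta = (beta_1', ...,
beta_Q')'`` with ``beta_q`` of length ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

GAUSSIAN = "gaussian"
POISSON = "poisson"
BERNOULLI = "bernoulli"
FAMILIES = (GAUSSIAN, POISSON, BERNOULLI)

_ETA_MAX = 30.0  # exp overflow guard for the log link
_P_EPS = 1e-6    # fitted Bernoulli probabilities clipped to (eps, 1-eps)


class FormatError(ValueError):
    """A long-format table is missing required columns."""


class CompletenessError(ValueError):
    """The (id, response, occasion) crossing has holes; complete data required."""


@dataclass(frozen=True)
class FamilySpec:
    """Marginal family: inverse link, its derivative and variance function."""

    name: str
    link_name: str
    inverse_link: Callable[[np.ndarray], np.ndarray]
    dmu_deta: Callable[[np.ndarray], np.ndarray]
    variance: Callable[[np.ndarray], np.ndarray]
    canonical_dispersion: bool  # True if the dispersion is free (gaussian)


def _logistic(eta):
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


_FAMILY_SPECS = {
    GAUSSIAN: FamilySpec(
        GAUSSIAN, "identity",
        inverse_link=lambda eta: eta,
        dmu_deta=lambda eta: np.ones_like(eta),
        variance=lambda mu: np.ones_like(mu),
        canonical_dispersion=True,
    ),
    POISSON: FamilySpec(
        POISSON, "log",
        inverse_link=lambda eta: np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX)),
        dmu_deta=lambda eta: np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX)),
        variance=lambda mu: np.maximum(mu, 1e-6),
        canonical_dispersion=False,
    ),
    BERNOULLI: FamilySpec(
        BERNOULLI, "logit",
        inverse_link=_logistic,
        dmu_deta=lambda eta: (lambda p: p * (1.0 - p))(_logistic(eta)),
        variance=lambda mu: np.clip(mu, _P_EPS, 1 - _P_EPS)
        * (1.0 - np.clip(mu, _P_EPS, 1 - _P_EPS)),
        canonical_dispersion=False,
    ),
}


def family_spec(name: str) -> FamilySpec:
    try:
        return _FAMILY_SPECS[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected one of {FAMILIES}")


@dataclass
class ResponsePanel:
    """Observed responses: ``values[i, q, p]`` with per-response family tags.

    Parameters
    ----------
    values : ndarray of shape (N, Q, P)
        Complete response array; no missing values are allowed.
    families : sequence of str
        One family tag per response, each in ``{"gaussian", "poisson",
        "bernoulli"}``.
    group_label : ndarray of shape (N,), optional
        Population label per individual, ``1`` or ``2``.
    """

    values: np.ndarray
    families: Sequence[str]
    group_label: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (N, Q, P)")
        if not np.all(np.isfinite(self.values)):
            raise CompletenessError("panel contains missing/non-finite values")
        self.families = tuple(self.families)
        if len(self.families) != self.values.shape[1]:
            raise ValueError("need one family tag per response")
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")
        if self.group_label is not None:
            self.group_label = np.asarray(self.group_label)
            if self.group_label.shape != (self.values.shape[0],):
                raise ValueError("group_label must have length N")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_responses(self) -> int:
        return self.values.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[2]

    def stacked(self) -> np.ndarray:
        """All individuals stacked response-major: shape (N, P*Q)."""
        n, q, p = self.values.shape
        return self.values.reshape(n, q * p)

    def subset(self, mask: np.ndarray) -> "ResponsePanel":
        lab = None if self.group_label is None else self.group_label[mask]
        return ResponsePanel(self.values[mask], self.families, lab)


@dataclass
class DesignSet:
    """Per-individual covariates: time-invariant ``x`` and shared occasion times.

    ``t`` holds the time covariate values actually entering the design (e.g.
    ``log`` occasion times for a log-linear count model); ``K = 2`` covariates
    per response throughout: row 1 of ``X_i*`` is ``x_i`` repeated ``P``
    times, row 2 is ``t``.
    """

    x: np.ndarray
    t: np.ndarray
    K: int = 2

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.t = np.asarray(self.t, dtype=float).ravel()
        if self.K != 2:
            raise ValueError("this design supports exactly K=2 covariates")

    @property
    def n_individuals(self) -> int:
        return self.x.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.t.shape[0]

    def subset(self, mask: np.ndarray) -> "DesignSet":
        return DesignSet(self.x[mask], self.t, self.K)


def stack_individual(panel: ResponsePanel, i: int) -> np.ndarray:
    """Return ``y_i`` as the response-major PQ-vector ``(y_i1', ..., y_iQ')'``."""
    if not 0 <= i < panel.n_individuals:
        raise IndexError(f"individual index {i} out of range")
    return panel.values[i].reshape(-1).copy()


def unstack_individual(y: np.ndarray, Q: int, P: int) -> np.ndarray:
    """Inverse of :func:`stack_individual`: PQ-vector back to a (Q, P) array."""
    y = np.asarray(y, dtype=float)
    if y.size != Q * P:
        raise ValueError("length mismatch")
    return y.reshape(Q, P).copy()


def design_block(design: DesignSet, i: int) -> np.ndarray:
    """The K x P per-response block ``X_i*`` for individual ``i``."""
    if not 0 <= i < design.n_individuals:
        raise IndexError(f"individual index {i} out of range")
    P = design.n_occasions
    return np.vstack([np.full(P, design.x[i]), design.t])


def build_design(design: DesignSet, i: int, Q: int) -> np.ndarray:
    """Block-diagonal ``X_i = I_Q (kron) X_i*`` of shape (K*Q, P*Q)."""
    return np.kron(np.eye(Q), design_block(design, i))


def linear_predictor(beta: np.ndarray, design: DesignSet, Q: int) -> np.ndarray:
    """Vectorized eta[i, q*P + p] = beta_{q1} x_i + beta_{q2} t_p for all i.

    ``beta`` is the KQ-vector in response-major (beta_q1, beta_q2) pairs.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != 2 * Q:
        raise ValueError("beta must have length 2*Q")
    b1 = beta[0::2]  # (Q,) coefficients on x
    b2 = beta[1::2]  # (Q,) coefficients on t
    P = design.n_occasions
    # (N, Q, P) -> (N, PQ)
    eta = design.x[:, None, None] * b1[None, :, None] + (b2[:, None] * design.t[None, :])[None]
    return eta.reshape(design.n_individuals, Q * P)


def load_long_table(path) -> tuple[ResponsePanel, DesignSet]:
    """Read a long-format delimited table into a panel and design.

    Expects columns ``id, group, occasion, response, value, x`` and a complete
    ``id x response x occasion`` crossing.  Occasion values become the time
    covariate ``t`` (sorted ascending); responses are ordered by first
    appearance unless named ``y1..yQ`` style sortable labels are used, in
    which case lexicographic order applies.
    """
    df = pd.read_csv(path)
    required = {"id", "group", "occasion", "response", "value", "x"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    if not np.issubdtype(np.asarray(df["value"]).dtype, np.number):
        try:
            df["value"] = pd.to_numeric(df["value"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric response value: {exc}") from exc

    ids = list(pd.unique(df["id"]))
    responses = sorted(pd.unique(df["response"]))
    occasions = sorted(pd.unique(df["occasion"]))
    n, q, p = len(ids), len(responses), len(occasions)
    if len(df) != n * q * p or df.duplicated(["id", "response", "occasion"]).any():
        raise CompletenessError(
            f"expected complete crossing of {n} ids x {q} responses x {p} occasions "
            f"({n * q * p} rows), got {len(df)} rows"
        )
    pivot = df.set_index(["id", "response", "occasion"])["value"]
    values = pivot.loc[[(i, r, o) for i in ids for r in responses for o in occasions]]
    values = np.asarray(values, dtype=float).reshape(n, q, p)

    per_id = df.drop_duplicates("id").set_index("id")
    x = per_id.loc[ids, "x"].to_numpy(dtype=float)
    group = per_id.loc[ids, "group"].to_numpy()
    fam = df.attrs.get("families")
    families = fam if fam is not None else [GAUSSIAN] * q
    panel = ResponsePanel(values, families, group_label=group)
    design = DesignSet(x=x, t=np.asarray(occasions, dtype=float))
    return panel, design


def write_long_table(path, panel: ResponsePanel, design: DesignSet,
                     response_names: Sequence[str] | None = None) -> None:
    """Write panel + design as the long-format CSV read by :func:`load_long_table`."""
    n, q, p = panel.values.shape
    if response_names is None:
        response_names = [f"y{j + 1}" for j in range(q)]
    grp = panel.group_label if panel.group_label is not None else np.ones(n, dtype=int)
    rows = {
        "id": np.repeat(np.arange(1, n + 1), q * p),
        "group": np.repeat(grp, q * p),
        "response": np.tile(np.repeat(response_names, p), n),
        "occasion": np.tile(design.t, n * q),
        "value": panel.values.reshape(-1),
        "x": np.repeat(design.x, q * p),
    }
    pd.DataFrame(rows)[["id", "group", "occasion", "response", "value", "x"]].to_csv(
        path, index=False
    )
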