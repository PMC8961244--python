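"""Monte Carlo engine: replicate the simulation grid and aggregate accuracy.

A *cell* is one row of the summary tables: (distribution, Q, P, estimator,
rule, structure).  Each cell averages over a secondary sub-grid that the
tables collapse -- N in {80, 140, 200} x group ratio {1:1, 2:3} x rho in
{0.3, 0.7} x covariance heterogeneity {equal, 3x} -- with ``reps``
replicates per sub-condition, equally weighted.  Every replicate generates
a fresh dataset, fits both groups with the chosen estimator, builds the
linear or quadratic rule and records resubstitution accuracy; replicates
whose group fits fail to converge are dropped and counted.

Seeding: per-replicate seeds derive from ``SeedSequence([master, *condition
key integers, replicate])`` so that any cell or replicate is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminant import ConvergenceError, build_rule, resub_accuracy
from .simgen import SimCondition, generate, group_sizes
from .working_structure import AR1, EX

log = logging.getLogger("rmda")

#: tables' structure labels -> within-response working/generating structure
STRUCTURES = {"unar": AR1, "uncs": EX}
SUB_N = (80, 140, 200)
SUB_RATIOS = ("1:1", "2:3")
SUB_RHO = (0.3, 0.7)
SUB_HET = (1.0, 3.0)

_DIST_CODE = {"normal": 1, "poisson": 2, "mixed": 3}
_WITHIN_CODE = {AR1: 1, EX: 2}


def sub_conditions(distribution: str, Q: int, P: int, structure: str):
    """The 24 collapsed sub-conditions of one table cell."""
    within = STRUCTURES[structure.lower()]
    for N, ratio, rho, het in product(SUB_N, SUB_RATIOS, SUB_RHO, SUB_HET):
        n1, n2 = group_sizes(N, ratio)
        yield SimCondition(distribution=distribution, Q=Q, P=P, N=N,
                           n1=n1, n2=n2, within_kind=within, rho=rho,
                           heterogeneity=het)


def replicate_seed(master_seed: int, cond: SimCondition, rep: int) -> np.random.SeedSequence:
    key = [int(master_seed), _DIST_CODE[cond.distribution], cond.Q, cond.P,
           cond.N, cond.n1, _WITHIN_CODE[cond.within_kind],
           int(round(cond.rho * 10)), int(cond.heterogeneity), rep]
    return np.random.SeedSequence(key)


def run_replicate(cond: SimCondition, estimator: str, rule: str, seed) -> float | None:
    """One simulate-fit-classify cycle; ``None`` marks a dropped replicate."""
    panel, design = generate(cond, seed)
    try:
        r = build_rule(panel, design, estimator=estimator, rule=rule,
                       within=cond.within_kind)
        acc, _ = resub_accuracy(r, panel, design)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        log.warning("dropped replicate (%s): %s", cond, exc)
        return None
    return acc


@dataclass
class CellResult:
    """Aggregated accuracy for one table cell."""

    distribution: str
    Q: int
    P: int
    estimator: str
    rule: str
    structure: str
    n_replicates: int
    mean_accuracy: float
    se: float
    n_dropped: int
    accuracies: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "distribution": self.distribution, "Q": self.Q, "P": self.P,
            "estimator": self.estimator, "rule": self.rule,
            "structure": self.structure, "n_replicates": self.n_replicates,
            "mean_accuracy": self.mean_accuracy, "se": self.se,
            "n_dropped": self.n_dropped,
        }


def run_cell(distribution: str, Q: int, P: int, estimator: str, rule: str,
             structure: str, reps: int, base_seed: int,
             conditions=None) -> CellResult:
    """Average ``reps`` replicates over the 24-point sub-grid of one cell.

    ``conditions`` optionally restricts the sub-grid to an explicit list of
    :class:`~rmda.simgen.SimCondition` (e.g. a single sub-condition).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    accs = []
    dropped = 0
    if conditions is None:
        conditions = sub_conditions(distribution, Q, P, structure)
    for cond in conditions:
        for rep in range(reps):
            seed = replicate_seed(base_seed, cond, rep)
            acc = run_replicate(cond, estimator, rule, seed)
            if acc is None:
                dropped += 1
            else:
                accs.append(acc)
    if not accs:
        raise RuntimeError(f"all replicates dropped for cell "
                           f"({distribution}, Q={Q}, P={P}, {estimator}, {rule}, {structure})")
    a = np.asarray(accs)
    se = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
    return CellResult(distribution, Q, P, estimator, rule, structure,
                      n_replicates=a.size, mean_accuracy=float(a.mean()),
                      se=se, n_dropped=dropped, accuracies=a)


DEFAULT_GRID = {
    "distributions": ["normal", "poisson", "mixed"],
    "Q": [3, 5],
    "P": [3, 5],
    "estimators": ["gee", "mle"],
    "rules": ["linear", "quadratic"],
    "structures": ["unar", "uncs"],
    "reps": 500,
    "seed": 12345,
}


def run_grid(config: dict | str | Path, out_path) -> pd.DataFrame:
    """Run every cell of a config and write one CSV row per cell.

    ``config`` is a mapping (or path to a YAML file) with the keys of
    ``DEFAULT_GRID``; missing keys take the defaults.  Rows are appended to
    ``out_path`` as each cell finishes, and cells already present in an
    existing output file are skipped, so an interrupted run resumes.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_GRID, **config}
    out_path = Path(out_path)
    key_cols = ["distribution", "Q", "P", "estimator", "rule", "structure"]
    done = set()
    if out_path.exists():
        prev = pd.read_csv(out_path)
        done = {tuple(row) for row in prev[key_cols].itertuples(index=False)}
    cells = list(product(cfg["distributions"], cfg["Q"], cfg["P"],
                         cfg["estimators"], cfg["rules"], cfg["structures"]))
    for dist, Q, P, est, rule, struct in cells:
        key = (dist, Q, P, est, rule, struct)
        if key in done:
            log.info("skipping completed cell %s", key)
            continue
        res = run_cell(dist, Q, P, est, rule, struct,
                       reps=int(cfg["reps"]), base_seed=int(cfg["seed"]))
        log.info("cell %s: accuracy %.3f (se %.3f), %d dropped",
                 key, res.mean_accuracy, res.se, res.n_dropped)
        row = pd.DataFrame([res.to_row()])
        row.to_csv(out_path, mode="a", header=not out_path.exists(), index=False)
    return pd.read_csv(out_path)
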