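"""Full-simulation benchmark: simulate studies, fit logistic models, Wald-test.

This module is the empirical yardstick for the two analytic estimators.  A
study is simulated in full (covariates and outcomes), the logistic model is
fitted by Newton-Raphson/IRLS, and the two-sided Wald test of the genotype
coefficient is applied; the rejection rate over independent replicates is
the empirical power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import _core
from .covariate_space import CovariateDesign, _as_rng, _sample_matrix
from .exceptions import InvalidParameterError
from .results import EmpiricalPowerResult
from .scenarios import scenario
from .trait_model import CovariateSampler, StudyDesign, TraitModel, resolve

_IRLS_MAX_ITER = 50
_IRLS_GTOL = 1e-8
_SEPARATION_BETA = 30.0

DEFAULT_N_GRID = (600, 1000, 2000, 3000, 4000, 5000, 6000, 8000, 10_000)


@dataclass(frozen=True, eq=False)
class SimulatedStudy:
    """One simulated dataset of n subjects with covariates and outcome."""

    data: pd.DataFrame
    design_mode: str
    n: int
    seed: object = None

    def design_matrix(self) -> np.ndarray:
        cov = self.data.drop(columns="Y").to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n), cov])

    def outcome(self) -> np.ndarray:
        return self.data["Y"].to_numpy(dtype=float)


@dataclass(frozen=True, eq=False)
class LogisticFit:
    """MLE of a logistic regression with its observed information."""

    beta: np.ndarray
    information: np.ndarray
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class WaldResult:
    """Two-sided Wald test of the genotype coefficient."""

    beta_hat: tuple[float, ...]
    statistic: float
    p_value: float
    reject: bool
    alpha: float


def _simulate_xy(rm, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Covariate rows (G, E...) and outcomes for one replicate."""
    if rm.design.mode == "prospective":
        rows = _sample_matrix(rm.design_cov, n, rng)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-rm.eta(rows, effective=False)))).astype(
            float
        )
        return rows, y
    n_case = int(round(rm.design.case_fraction * n))
    sampler = CovariateSampler(rm)
    rows = np.vstack(
        [
            sampler.sample_outcome_matrix(1, n_case, rng),
            sampler.sample_outcome_matrix(0, n - n_case, rng),
        ]
    )
    y = np.concatenate([np.ones(n_case), np.zeros(n - n_case)])
    perm = rng.permutation(n)
    return rows[perm], y[perm]


def simulate_study(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
    seed=None,
) -> SimulatedStudy:
    """Simulate a complete study of size n under the given design.

    Prospective: covariates from F_x, outcomes Bernoulli(expit(eta)).
    Retrospective: exactly round(phi * n) cases drawn from P(x | Y=1) and the
    remainder from P(x | Y=0).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rm = resolve(design_cov, trait, design)
    rng = _as_rng(seed)
    rows, y = _simulate_xy(rm, n, rng)
    data = pd.DataFrame(rows, columns=rm.design_cov.column_names())
    data["Y"] = y
    return SimulatedStudy(data=data, design_mode=design.mode, n=n, seed=seed)


def _irls(x: np.ndarray, y: np.ndarray) -> LogisticFit:
    beta = np.zeros(x.shape[1])
    converged = False
    it = 0
    for it in range(1, _IRLS_MAX_ITER + 1):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        if np.linalg.norm(grad) < _IRLS_GTOL:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hess = (x * w[:, None]).T @ x
        try:
            beta = beta + np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta)) > _SEPARATION_BETA:  # (quasi-)separation
            break
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    w = mu * (1.0 - mu)
    information = (x * w[:, None]).T @ x
    return LogisticFit(beta=beta, information=information, converged=converged, n_iter=it)


def fit_logistic(study) -> LogisticFit:
    """Newton-Raphson MLE of the logistic model for a simulated study.

    Accepts a :class:`SimulatedStudy` or an ``(X, y)`` pair where ``X``
    already carries the intercept column.  Non-convergence or separation is
    flagged on the returned fit rather than raised, so that simulation loops
    can count and drop failed replicates.
    """
    if isinstance(study, SimulatedStudy):
        x, y = study.design_matrix(), study.outcome()
    else:
        x, y = study
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    return _irls(x, y)


def wald_test(fit: LogisticFit, alpha: float = 0.05) -> WaldResult:
    """Two-sided Wald test of H0: beta_G = 0 at level alpha."""
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    v = _core.solve_variance(fit.information)
    t = float(fit.beta[_core.GENO_IDX] ** 2 / v)
    p = float(chi2.sf(t, df=1))
    return WaldResult(
        beta_hat=tuple(fit.beta.tolist()),
        statistic=t,
        p_value=p,
        reject=bool(p < alpha),
        alpha=alpha,
    )


def empirical_power(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
    alpha: float = 0.05,
    replicates: int = 1000,
    seed=None,
) -> EmpiricalPowerResult:
    """Rejection rate of the simulate-fit-test pipeline over replicates.

    One master seed spawns independent per-replicate streams, so each
    replicate's data does not depend on the total number of replicates.
    Failed fits (separation/non-convergence) are dropped and counted; more
    than 5% failures triggers a warning.
    """
    if replicates < 100:
        raise InvalidParameterError(
            f"replicates must be >= 100, got {replicates}"
        )
    rm = resolve(design_cov, trait, design)
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = master.spawn(replicates)
    rejections = 0
    failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        x_rows, y = _simulate_xy(rm, n, rng)
        fit = _irls(np.column_stack([np.ones(n), x_rows]), y)
        if not fit.converged:
            failed += 1
            continue
        if wald_test(fit, alpha).reject:
            rejections += 1
    used = replicates - failed
    if failed > 0.05 * replicates:
        warnings.warn(
            f"{failed}/{replicates} replicates failed to fit and were dropped",
            UserWarning,
            stacklevel=2,
        )
    p_hat = rejections / used if used else float("nan")
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / used)) if used else float("nan")
    return EmpiricalPowerResult(
        power=p_hat,
        se=se,
        n=n,
        alpha=alpha,
        replicates=used,
        n_failed=failed,
    )


@dataclass(frozen=True, eq=False)
class BenchmarkResult:
    """Accuracy benchmark of the SS and RD methods against empirical power."""

    scenario: str
    per_n: pd.DataFrame
    summary: pd.DataFrame
    replicates: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "replicates": self.replicates,
            "alpha": self.alpha,
            "per_n": self.per_n.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
        }


def benchmark_table1(
    scenario_id: str,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    replicates: int = 1000,
    seed=None,
    b: int = 10_000,
    alpha: float = 0.05,
) -> BenchmarkResult:
    """Benchmark the SS and RD power against the empirical oracle.

    For each n in the grid the SS power (shared covariate draw of size b),
    the RD power and the empirical power are computed; the absolute errors
    |computed - empirical| are aggregated into per-method averages and
    maxima.
    """
    from .power_ss import power_ss, unit_information_ss
    from .power_rd import power_rd

    design_cov, trait, design = scenario(scenario_id)
    master = np.random.SeedSequence(seed)
    ui_seed, emp_seed = master.spawn(2)
    ui = unit_information_ss(
        design_cov, trait, design, b=b, seed=np.random.default_rng(ui_seed)
    )
    emp_children = emp_seed.spawn(len(n_grid))
    rows = []
    for n, child in zip(n_grid, emp_children):
        p_ss = power_ss(design_cov, trait, design, n, alpha=alpha, unit_info=ui).power
        p_rd = power_rd(design_cov, trait, design, n, alpha=alpha).power
        emp = empirical_power(
            design_cov,
            trait,
            design,
            n,
            alpha=alpha,
            replicates=replicates,
            seed=child,
        )
        rows.append(
            {
                "n": n,
                "power_ss": p_ss,
                "power_rd": p_rd,
                "power_empirical": emp.power,
                "empirical_se": emp.se,
                "ae_ss": abs(p_ss - emp.power),
                "ae_rd": abs(p_rd - emp.power),
            }
        )
    per_n = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "method": "P1.SS",
                "scenario": scenario_id,
                "average_ae": per_n["ae_ss"].mean(),
                "maximum_ae": per_n["ae_ss"].max(),
            },
            {
                "method": "P2.RD",
                "scenario": scenario_id,
                "average_ae": per_n["ae_rd"].mean(),
                "maximum_ae": per_n["ae_rd"].max(),
            },
        ]
    )
    return BenchmarkResult(
        scenario=scenario_id,
        per_n=per_n,
        summary=summary,
        replicates=replicates,
        alpha=alpha,
    )
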